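"""Exception hierarchy for the Eugene interpreter.

Every error raised while processing a source program carries an optional
``location`` (file, line, column) so the CLI can print ``file:line:col``
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SourceLocation:
    """Position of a token or statement in a source file."""

    file: str = "<string>"
    line: int = 0
    column: int = 0

    def __str__(self) -> str:  # pragma: no cover - trivial formatting
        return f"{self.file}:{self.line}:{self.column}"


class EugeneError(Exception):
    """Base class for all interpreter errors."""

    def __init__(self, message: str, location: SourceLocation | None = None):
        self.location = location
        if location is not None:
            message = f"{location}: {message}"
        super().__init__(message)


class EugeneSyntaxError(EugeneError):
    """Lexical or grammatical error in source text."""


class EugeneNameError(EugeneError):
    """Unknown identifier, or redefinition of an existing one."""


class EugeneTypeError(EugeneError):
    """Value kind does not match the declared property kind."""


class EugeneIncludeError(EugeneError):
    """Missing or cyclic header file."""


class EugeneAssertionError(EugeneError):
    """A hard (asserted) rule was violated by a declared device."""


class EugeneExportError(EugeneError):
    """Serialization failure, e.g. a leaf part without a Sequence."""
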