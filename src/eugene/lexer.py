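"""Lexer for Eugene source text.

Hand-written scanner producing a flat token stream. Comments run from
``//`` to end of line and are discarded; string literals keep embedded
whitespace; statements are terminated by ``;``. Keywords and identifiers
are case-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EugeneSyntaxError, SourceLocation

KEYWORDS = frozenset(
    {
        "Property",
        "Part",
        "Device",
        "Rule",
        "Assert",
        "Note",
        "include",
        "permute",
        "print",
        "txt",
        "num",
        "boolean",
        "true",
        "false",
        "BEFORE",
        "CONTAINS",
        "NOTCONTAINS",
        "WITH",
        "NOTWITH",
        "NOTMORETHAN",
        "AND",
        "OR",
        "once",
    }
)

PUNCTUATION = frozenset("()[],;.")


@dataclass(frozen=True)
class Token:
    category: str  # keyword | identifier | number | string | punctuation | operator
    lexeme: str
    location: SourceLocation

    def is_kw(self, *words: str) -> bool:
        return self.category == "keyword" and self.lexeme in words

    def is_punct(self, ch: str) -> bool:
        return self.category == "punctuation" and self.lexeme == ch


def tokenize(source: str, filename: str = "<string>") -> list[Token]:
    """Scan ``source`` into tokens, raising :class:`EugeneSyntaxError` with
    line/column on unterminated strings or illegal characters."""
    tokens: list[Token] = []
    i, line, col = 0, 1, 1
    n = len(source)

    def loc() -> SourceLocation:
        return SourceLocation(filename, line, col)

    while i < n:
        ch = source[i]
        if ch == "\n":
            i, line, col = i + 1, line + 1, 1
            continue
        if ch in " \t\r":
            i, col = i + 1, col + 1
            continue
        if source.startswith("//", i):
            while i < n and source[i] != "\n":
                i += 1
            continue
        start = loc()
        if ch == '"':
            j = i + 1
            while j < n and source[j] not in '"\n':
                j += 1
            if j >= n or source[j] != '"':
                raise EugeneSyntaxError("unterminated string literal", start)
            tokens.append(Token("string", source[i + 1 : j], start))
            col += j + 1 - i
            i = j + 1
            continue
        if ch.isdigit() or (ch == "." and i + 1 < n and source[i + 1].isdigit()):
            j = i
            seen_dot = False
            while j < n and (source[j].isdigit() or (source[j] == "." and not seen_dot)):
                if source[j] == ".":
                    # a trailing '.' not followed by a digit belongs to the next token
                    if j + 1 >= n or not source[j + 1].isdigit():
                        break
                    seen_dot = True
                j += 1
            tokens.append(Token("number", source[i:j], start))
            col += j - i
            i = j
            continue
        if ch.isalpha() or ch == "_":
            j = i
            while j < n and (source[j].isalnum() or source[j] == "_"):
                j += 1
            word = source[i:j]
            category = "keyword" if word in KEYWORDS else "identifier"
            tokens.append(Token(category, word, start))
            col += j - i
            i = j
            continue
        if ch == "=":
            tokens.append(Token("operator", "=", start))
            i, col = i + 1, col + 1
            continue
        if ch in PUNCTUATION:
            tokens.append(Token("punctuation", ch, start))
            i, col = i + 1, col + 1
            continue
        raise EugeneSyntaxError(f"illegal character {ch!r}", start)
    return tokens
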