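"""Header-file resolution: splice ``include`` statements into one tree.

Search order is the directory of the including file first, then any
user-supplied include paths, first hit wins. Each file is loaded at most
once per run (repeat includes are ignored); include cycles are an error.
"""

from __future__ import annotations

from pathlib import Path

from .errors import EugeneIncludeError
from .parser import parse
from .syntax import Include, Statement, SyntaxTree


def resolve_includes(
    tree: SyntaxTree,
    search_paths: list[str | Path] | None = None,
    current_dir: str | Path = ".",
) -> SyntaxTree:
    """Return ``tree`` with every include statement replaced by the parsed
    statements of the named header files, spliced in listed order."""
    loaded: set[Path] = set()
    statements = _splice(tree, [Path(p) for p in (search_paths or [])],
                         Path(current_dir), loaded, in_progress=[])
    return SyntaxTree(tuple(statements))


def _locate(name: str, current_dir: Path, search_paths: list[Path],
            location) -> Path:
    candidates = [current_dir] + search_paths
    for base in candidates:
        path = base / name
        if path.is_file():
            return path.resolve()
    searched = ", ".join(str(c) for c in candidates)
    raise EugeneIncludeError(f"header file {name!r} not found (searched: {searched})", location)


def _splice(tree: SyntaxTree, search_paths: list[Path], current_dir: Path,
            loaded: set[Path], in_progress: list[Path]) -> list[Statement]:
    out: list[Statement] = []
    for stmt in tree.statements:
        if not isinstance(stmt, Include):
            out.append(stmt)
            continue
        for name in stmt.paths:
            path = _locate(name, current_dir, search_paths, stmt.location)
            if path in in_progress:
                cycle = " -> ".join(p.name for p in in_progress + [path])
                raise EugeneIncludeError(f"cyclic include: {cycle}", stmt.location)
            if path in loaded:
                continue
            loaded.add(path)
            sub = parse(path.read_text(), filename=str(path))
            in_progress.append(path)
            out.extend(_splice(sub, search_paths, path.parent, loaded, in_progress))
            in_progress.pop()
    return out


def load_program(path: str | Path, search_paths: list[str | Path] | None = None) -> SyntaxTree:
    """Parse a main file and resolve all of its includes."""
    path = Path(path)
    tree = parse(path.read_text(), filename=str(path))
    return resolve_includes(tree, search_paths, current_dir=path.parent)
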