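"""Syntax tree node types and the canonical pretty-printer.

Node equality ignores source locations, so ``parse(pretty_print(tree))``
compares equal to ``tree`` -- the round-trip invariant the test suite
checks for every fixture program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import SourceLocation
from . import rules as _rules


@dataclass(frozen=True)
class Literal:
    """A primitive literal: txt, num, or boolean."""

    kind: str  # txt | num | boolean
    value: Union[str, int, float, bool]

    def pretty(self) -> str:
        if self.kind == "txt":
            return f'"{self.value}"'
        if self.kind == "boolean":
            return "true" if self.value else "false"
        return repr(self.value) if isinstance(self.value, float) else str(self.value)


@dataclass(frozen=True)
class ListLiteral:
    items: tuple[Literal, ...]

    def pretty(self) -> str:
        return "[" + ", ".join(i.pretty() for i in self.items) + "]"


@dataclass(frozen=True)
class NameRef:
    name: str

    def pretty(self) -> str:
        return self.name


@dataclass(frozen=True)
class IndexRef:
    """0-based element access: ``num_array[0]`` or ``BBa_1[0]``."""

    name: str
    index: Union[Literal, NameRef]

    def pretty(self) -> str:
        return f"{self.name}[{self.index.pretty()}]"


Expr = Union[Literal, ListLiteral, NameRef, IndexRef]


@dataclass(frozen=True)
class Statement:
    location: SourceLocation = field(compare=False, kw_only=True, default=SourceLocation())


@dataclass(frozen=True)
class Include(Statement):
    paths: tuple[str, ...] = ()

    def pretty(self) -> str:
        return f"include {', '.join(self.paths)};"


@dataclass(frozen=True)
class PropertyDef(Statement):
    name: str = ""
    kind: str = ""

    def pretty(self) -> str:
        return f"Property {self.name}({self.kind});"


@dataclass(frozen=True)
class PartDef(Statement):
    name: str = ""
    property_names: tuple[str, ...] = ()

    def pretty(self) -> str:
        return f"Part {self.name}({', '.join(self.property_names)});"


@dataclass(frozen=True)
class PartDecl(Statement):
    """``Promoter P1(1, "TATATA", 30);`` or ``Promoter P2(.ID("x"));`` or ``P3();``"""

    part_type: str = ""
    name: str = ""
    positional: Optional[tuple[Expr, ...]] = None
    named: Optional[tuple[tuple[str, Expr], ...]] = None

    def pretty(self) -> str:
        if self.named is not None:
            body = ", ".join(f".{prop}({expr.pretty()})" for prop, expr in self.named)
        elif self.positional:
            body = ", ".join(e.pretty() for e in self.positional)
        else:
            body = ""
        return f"{self.part_type} {self.name}({body});"


@dataclass(frozen=True)
class DeviceDecl(Statement):
    name: str = ""
    #: (optional type annotation, component name), in 5'->3' order
    components: tuple[tuple[Optional[str], str], ...] = ()

    def pretty(self) -> str:
        body = ", ".join(f"{ann} {n}" if ann else n for ann, n in self.components)
        return f"Device {self.name}({body});"


@dataclass(frozen=True)
class RuleDecl(Statement):
    name: str = ""
    expr: "_rules.RuleExpr" = None

    def pretty(self) -> str:
        return f"Rule {self.name}({_rules.pretty_expr(self.expr)});"


@dataclass(frozen=True)
class AssertStmt(Statement):
    rule_names: tuple[str, ...] = ()

    def pretty(self) -> str:
        return f"Assert({' AND '.join(self.rule_names)});"


@dataclass(frozen=True)
class NoteStmt(Statement):
    rule_names: tuple[str, ...] = ()

    def pretty(self) -> str:
        return f"Note({' AND '.join(self.rule_names)});"


@dataclass(frozen=True)
class PermuteCall(Statement):
    device_name: str = ""

    def pretty(self) -> str:
        return f"permute({self.device_name});"


@dataclass(frozen=True)
class PrintCall(Statement):
    arg: Expr = None

    def pretty(self) -> str:
        return f"print({self.arg.pretty()});"


@dataclass(frozen=True)
class VarDecl(Statement):
    """``num n1, n2;`` / ``txt s = "x";`` / ``num[] a = [1, 2];``"""

    kind: str = ""
    declarations: tuple[tuple[str, Optional[Expr]], ...] = ()

    def pretty(self) -> str:
        parts = [f"{n} = {e.pretty()}" if e is not None else n for n, e in self.declarations]
        return f"{self.kind} {', '.join(parts)};"


@dataclass(frozen=True)
class Assignment(Statement):
    target: str = ""
    expr: Expr = None

    def pretty(self) -> str:
        return f"{self.target} = {self.expr.pretty()};"


@dataclass(frozen=True)
class ExprStmt(Statement):
    """A bare expression statement, e.g. ``BBa_1[0];`` or ``BBa1_2;``."""

    expr: Expr = None

    def pretty(self) -> str:
        return f"{self.expr.pretty()};"


@dataclass(frozen=True)
class SyntaxTree:
    statements: tuple[Statement, ...] = ()

    def pretty(self) -> str:
        return "\n".join(s.pretty() for s in self.statements) + ("\n" if self.statements else "")


def pretty_print(tree: SyntaxTree) -> str:
    """Canonical source text for ``tree``; re-parsing yields an equal tree."""
    return tree.pretty()
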