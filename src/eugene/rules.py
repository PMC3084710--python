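"""Rule expressions and their evaluation against concrete devices.

A rule is a named boolean constraint over part-instance *presence*
(CONTAINS / NOTCONTAINS), *order* (BEFORE), *co-occurrence*
(WITH / NOTWITH), and *multiplicity* (NOTMORETHAN), composed with
AND / OR. Asserted rules are hard constraints used to prune design
spaces; noted rules only emit warnings.

Operator semantics (the truth table the whole pruning workflow rests on):

``CONTAINS x``
    x occurs somewhere in the device's flattened part list.
``NOTCONTAINS x``
    x does not occur.
``x BEFORE y``
    if both occur, the first occurrence of x precedes the first of y;
    vacuously true when either is absent.
``x WITH y``
    *conditional* co-occurrence: if x is present then y must be present;
    vacuously true when x is absent. The conditional reading is load
    bearing -- with a symmetric "both present" reading, disjunctive
    selector rules would wipe out every device lacking the antecedent
    part, and the staged pruning counts of the cell-surface-display
    case study could not be reproduced.
``x NOTWITH y``
    x and y must not both be present.
``x NOTMORETHAN n``
    x occurs at most n times (``once`` is the word form of 1).

BEFORE with a multiply-occurring instance compares first occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

from .errors import EugeneNameError
from .model import Device


@dataclass(frozen=True)
class Before:
    x: str
    y: str


@dataclass(frozen=True)
class With:
    x: str
    y: str


@dataclass(frozen=True)
class NotWith:
    x: str
    y: str


@dataclass(frozen=True)
class Contains:
    x: str
    #: optional device scope, from the form ``Rule R2(BBa_1 CONTAINS P1)``;
    #: a scoped leaf always evaluates against its named device.
    scope: Optional[str] = None


@dataclass(frozen=True)
class NotContains:
    x: str
    scope: Optional[str] = None


@dataclass(frozen=True)
class NotMoreThan:
    x: str
    n: int


@dataclass(frozen=True)
class And:
    left: "RuleExpr"
    right: "RuleExpr"


@dataclass(frozen=True)
class Or:
    left: "RuleExpr"
    right: "RuleExpr"


RuleExpr = Union[Before, With, NotWith, Contains, NotContains, NotMoreThan, And, Or]


@dataclass(frozen=True)
class Rule:
    """A named rule expression, optionally scoped to one device."""

    name: str
    expr: RuleExpr

    def scope(self) -> Optional[str]:
        scopes = [leaf.scope for leaf in iter_leaves(self.expr)
                  if isinstance(leaf, (Contains, NotContains)) and leaf.scope]
        return scopes[0] if scopes else None


@dataclass
class RuleSet:
    """Asserted (hard) and noted (warning-only) rules, each at most once."""

    asserted: list[Rule]
    noted: list[Rule]

    def __init__(self, asserted=(), noted=()):
        self.asserted = []
        self.noted = []
        for r in asserted:
            self.assert_rule(r)
        for r in noted:
            self.note_rule(r)

    def _names(self) -> set[str]:
        return {r.name for r in self.asserted} | {r.name for r in self.noted}

    def assert_rule(self, rule: Rule) -> None:
        if rule.name in self._names():
            raise EugeneNameError(f"rule {rule.name!r} already asserted or noted")
        self.asserted.append(rule)

    def note_rule(self, rule: Rule) -> None:
        if rule.name in self._names():
            raise EugeneNameError(f"rule {rule.name!r} already asserted or noted")
        self.noted.append(rule)


def iter_leaves(expr: RuleExpr):
    if isinstance(expr, (And, Or)):
        yield from iter_leaves(expr.left)
        yield from iter_leaves(expr.right)
    else:
        yield expr


def operand_names(expr: RuleExpr) -> set[str]:
    names: set[str] = set()
    for leaf in iter_leaves(expr):
        if isinstance(leaf, (Before, With, NotWith)):
            names.update((leaf.x, leaf.y))
        else:
            names.add(leaf.x)
    return names


def occurrences(device: Device, instance_name: str) -> list[int]:
    """0-based positions of ``instance_name`` in the device's flattened
    (sub-devices expanded, 5'->3') leaf part list."""
    return [i for i, leaf in enumerate(device.leaves()) if leaf.name == instance_name]


DeviceLookup = Callable[[str], Device]


def evaluate(
    expr: RuleExpr,
    device: Device,
    lookup: Optional[DeviceLookup] = None,
    known_instances: Optional[set[str]] = None,
) -> bool:
    """Evaluate a rule expression against ``device``.

    ``lookup`` resolves the named device of scoped CONTAINS leaves;
    ``known_instances``, when given, validates operand names against the
    set of registered part instances.
    """
    if known_instances is not None:
        unknown = operand_names(expr) - known_instances
        if unknown:
            raise EugeneNameError(
                "rule references unknown part instance(s): " + ", ".join(sorted(unknown))
            )

    def target(leaf) -> Device:
        scope = getattr(leaf, "scope", None)
        if scope is None:
            return device
        if lookup is None:
            raise EugeneNameError(f"no device lookup available to resolve scope {scope!r}")
        return lookup(scope)

    def ev(e: RuleExpr) -> bool:
        if isinstance(e, And):
            return ev(e.left) and ev(e.right)
        if isinstance(e, Or):
            return ev(e.left) or ev(e.right)
        if isinstance(e, Contains):
            return bool(occurrences(target(e), e.x))
        if isinstance(e, NotContains):
            return not occurrences(target(e), e.x)
        if isinstance(e, Before):
            px, py = occurrences(device, e.x), occurrences(device, e.y)
            if not px or not py:
                return True
            return px[0] < py[0]
        if isinstance(e, With):
            return (not occurrences(device, e.x)) or bool(occurrences(device, e.y))
        if isinstance(e, NotWith):
            return not (occurrences(device, e.x) and occurrences(device, e.y))
        if isinstance(e, NotMoreThan):
            return len(occurrences(device, e.x)) <= e.n
        raise TypeError(f"not a rule expression: {e!r}")  # pragma: no cover

    return ev(expr)


@dataclass(frozen=True)
class RemovalRecord:
    """One pruning step: how many devices a rule removed and how many remain."""

    rule: str
    removed: int
    remaining: int


def prune(space, rules: list[Rule], lookup: Optional[DeviceLookup] = None,
          known_instances: Optional[set[str]] = None):
    """Filter a design space, keeping devices satisfying every rule.

    Returns ``(pruned_space, records)``. Each removed device is attributed
    to the first rule (in ``rules`` order) it violates, which reproduces
    sequential per-rule removal accounting; the surviving set itself is
    order-independent (a conjunction).
    """
    surviving = list(space.entries)
    records: list[RemovalRecord] = []
    for rule in rules:
        kept = []
        removed = 0
        for ordinal, device in surviving:
            if evaluate(rule.expr, device, lookup, known_instances):
                kept.append((ordinal, device))
            else:
                removed += 1
        surviving = kept
        records.append(RemovalRecord(rule.name, removed, len(surviving)))
    return space.replace_entries(surviving), records


def note(rules: RuleSet, device: Device, lookup: Optional[DeviceLookup] = None) -> list[str]:
    """Warning messages for noted rules violated by ``device`` (never fatal)."""
    return [
        f"{rule.name} violated by {device.name}"
        for rule in rules.noted
        if not evaluate(rule.expr, device, lookup)
    ]


def pretty_expr(expr: RuleExpr) -> str:
    """Render a rule expression in source syntax (sub-expressions of AND/OR
    parenthesized, matching the style of published rule listings)."""
    def p(e: RuleExpr, top: bool) -> str:
        if isinstance(e, (And, Or)):
            op = "AND" if isinstance(e, And) else "OR"
            s = f"{p(e.left, False)} {op} {p(e.right, False)}"
            return s if top else f"({s})"
        if isinstance(e, Contains):
            return f"{e.scope} CONTAINS {e.x}" if e.scope else f"CONTAINS {e.x}"
        if isinstance(e, NotContains):
            return f"{e.scope} NOTCONTAINS {e.x}" if e.scope else f"NOTCONTAINS {e.x}"
        if isinstance(e, Before):
            return f"{e.x} BEFORE {e.y}"
        if isinstance(e, With):
            return f"{e.x} WITH {e.y}"
        if isinstance(e, NotWith):
            return f"{e.x} NOTWITH {e.y}"
        if isinstance(e, NotMoreThan):
            return f"{e.x} NOTMORETHAN {'once' if e.n == 1 else e.n}"
        raise TypeError(f"not a rule expression: {e!r}")  # pragma: no cover

    return p(expr, True)
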