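"""Sequential interpreter: executes a resolved syntax tree statement by
statement, populating the global symbol table, expanding design spaces,
and applying Assert/Note rule semantics.

Execution model
---------------
Statements run top to bottom; every name must be defined before use and
redefinition is an error. ``permute`` expands a template device into its
design space, constrained by the rules asserted so far. ``Assert`` makes
rules hard constraints: they immediately prune every existing design
space (silently, with per-rule removal accounting) and are checked
against concrete declared devices -- where a violation is fatal. A device
that has been permuted is treated as a *template*, i.e. a generator of
its design space rather than a design commitment, so asserted rules
filter its space instead of halting on the template itself. Devices
declared after an Assert are checked at declaration time. ``Note`` rules
are evaluated at the same points but only ever append warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import rules as R
from . import syntax as S
from .combinatorics import DesignSpace, PartLibrary, permute
from .errors import (
    EugeneAssertionError,
    EugeneNameError,
    EugeneTypeError,
    SourceLocation,
)
from .includes import load_program
from .model import (
    Device,
    PartDefinition,
    PartInstance,
    PrimitiveValue,
    PropertyDefinition,
    SymbolTable,
    UNSET,
)


@dataclass
class Variable:
    """A primitive variable; ``value`` is UNSET until first assignment."""

    name: str
    kind: str
    value: object = UNSET


@dataclass(frozen=True)
class PruneStep:
    """One pruning record: which rule removed how many devices from which space."""

    template: str
    rule: str
    removed: int
    remaining: int


@dataclass
class InterpreterResult:
    symbols: SymbolTable
    design_spaces: dict[str, DesignSpace] = field(default_factory=dict)
    output: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    prune_log: list[PruneStep] = field(default_factory=list)

    @property
    def emitted_text(self) -> str:
        return "\n".join(self.output) + ("\n" if self.output else "")

    def surviving_devices(self) -> list[Device]:
        """All devices surviving in all design spaces, in creation order."""
        out: list[Device] = []
        for space in self.design_spaces.values():
            out.extend(space.devices)
        return out

    def stats_table(self) -> str:
        """Tab-separated pruning report: template, rule, removed, remaining."""
        lines = ["template\trule\tremoved\tremaining"]
        for step in self.prune_log:
            lines.append(f"{step.template}\t{step.rule}\t{step.removed}\t{step.remaining}")
        return "\n".join(lines) + "\n"


class Interpreter:
    def __init__(self) -> None:
        self.symbols = SymbolTable()
        self.result = InterpreterResult(self.symbols)
        self.asserted: list[R.Rule] = []
        self.noted: list[R.Rule] = []
        self._permuted: set[str] = set()

    # -- helpers --------------------------------------------------------
    def _lookup_device(self, name: str) -> Device:
        obj = self.symbols.lookup(name)
        if not isinstance(obj, Device):
            raise EugeneNameError(f"{name!r} is not a Device")
        return obj

    def _known_instances(self) -> set[str]:
        return {inst.name for inst in self.symbols.of_type(PartInstance)}

    def _evaluate_rule(self, rule: R.Rule, device: Device) -> bool:
        return R.evaluate(rule.expr, device, self._lookup_device, self._known_instances())

    def _declared_concrete_devices(self) -> list[Device]:
        """Declared devices that are design commitments (not permute templates)."""
        return [d for d in self.symbols.of_type(Device) if d.name not in self._permuted]

    # -- entry point ----------------------------------------------------
    def execute(self, tree: S.SyntaxTree) -> InterpreterResult:
        for stmt in tree.statements:
            try:
                self._execute_statement(stmt)
            except EugeneAssertionError:
                raise
            except (EugeneNameError, EugeneTypeError) as err:
                if err.location is None:
                    raise type(err)(str(err), stmt.location) from err
                raise
        return self.result

    def _execute_statement(self, stmt: S.Statement) -> None:
        handler = {
            S.Include: self._exec_include,
            S.PropertyDef: self._exec_property_def,
            S.PartDef: self._exec_part_def,
            S.PartDecl: self._exec_part_decl,
            S.DeviceDecl: self._exec_device_decl,
            S.RuleDecl: self._exec_rule_decl,
            S.AssertStmt: self._exec_assert,
            S.NoteStmt: self._exec_note,
            S.PermuteCall: self._exec_permute,
            S.PrintCall: self._exec_print,
            S.VarDecl: self._exec_var_decl,
            S.Assignment: self._exec_assignment,
            S.ExprStmt: self._exec_expr_stmt,
        }[type(stmt)]
        handler(stmt)

    # -- statement handlers ---------------------------------------------
    def _exec_include(self, stmt: S.Include) -> None:
        raise EugeneNameError(
            "include statements must be resolved before interpretation "
            "(use includes.load_program or resolve_includes)",
            stmt.location,
        )

    def _exec_property_def(self, stmt: S.PropertyDef) -> None:
        self.symbols.define(stmt.name, PropertyDefinition(stmt.name, stmt.kind), stmt.location)

    def _exec_part_def(self, stmt: S.PartDef) -> None:
        for prop in stmt.property_names:
            obj = self.symbols.lookup(prop, stmt.location)
            if not isinstance(obj, PropertyDefinition):
                raise EugeneNameError(f"{prop!r} is not a Property", stmt.location)
        self.symbols.define(
            stmt.name, PartDefinition(stmt.name, stmt.property_names), stmt.location
        )

    def _property_kind(self, prop_name: str) -> str:
        return self.symbols.lookup(prop_name).kind  # type: ignore[union-attr]

    def _exec_part_decl(self, stmt: S.PartDecl) -> None:
        typedef = self.symbols.lookup(stmt.part_type, stmt.location)
        if not isinstance(typedef, PartDefinition):
            raise EugeneNameError(f"{stmt.part_type!r} is not a Part type", stmt.location)
        values: dict[str, PrimitiveValue] = {}
        if stmt.positional is not None:
            if len(stmt.positional) > len(typedef.property_names):
                raise EugeneTypeError(
                    f"{len(stmt.positional)} values for {len(typedef.property_names)} "
                    f"properties of Part {typedef.name}",
                    stmt.location,
                )
            for prop, expr in zip(typedef.property_names, stmt.positional):
                values[prop] = self._eval_primitive(expr, self._property_kind(prop), stmt.location)
        elif stmt.named is not None:
            for prop, expr in stmt.named:
                if prop not in typedef.property_names:
                    raise EugeneNameError(
                        f"Part {typedef.name} has no property {prop!r}", stmt.location
                    )
                values[prop] = self._eval_primitive(expr, self._property_kind(prop), stmt.location)
        instance = PartInstance(stmt.name, typedef.name, values)
        self.symbols.define(stmt.name, instance, stmt.location)

    def _exec_device_decl(self, stmt: S.DeviceDecl) -> None:
        components = []
        for annotation, comp_name in stmt.components:
            if comp_name == stmt.name:
                raise EugeneNameError(
                    f"Device {stmt.name} cannot contain itself", stmt.location
                )
            comp = self.symbols.lookup(comp_name, stmt.location)
            if isinstance(comp, PartInstance):
                if annotation is not None and annotation != comp.part_type:
                    raise EugeneTypeError(
                        f"component {comp_name} is a {comp.part_type}, "
                        f"annotation says {annotation}",
                        stmt.location,
                    )
            elif isinstance(comp, Device):
                if annotation is not None and annotation != "Device":
                    raise EugeneTypeError(
                        f"component {comp_name} is a Device, annotation says {annotation}",
                        stmt.location,
                    )
            else:
                raise EugeneNameError(
                    f"{comp_name!r} is not a Part instance or Device", stmt.location
                )
            components.append(comp)
        device = Device(stmt.name, tuple(components))
        self.symbols.define(stmt.name, device, stmt.location)
        self._check_device(device, stmt.location)

    def _check_device(self, device: Device, location: SourceLocation) -> None:
        """Hard-check asserted rules, warn for noted ones, on a concrete device."""
        for rule in self.asserted:
            if not self._evaluate_rule(rule, device):
                raise EugeneAssertionError(
                    f"asserted rule {rule.name} violated by device {device.name}", location
                )
        self.result.warnings.extend(R.note(R.RuleSet(noted=self.noted), device,
                                           self._lookup_device))

    def _exec_rule_decl(self, stmt: S.RuleDecl) -> None:
        self.symbols.define(stmt.name, R.Rule(stmt.name, stmt.expr), stmt.location)

    def _resolve_rules(self, names: tuple[str, ...], location) -> list[R.Rule]:
        out = []
        for name in names:
            obj = self.symbols.lookup(name, location)
            if not isinstance(obj, R.Rule):
                raise EugeneNameError(f"{name!r} is not a Rule", location)
            out.append(obj)
        return out

    def _exec_assert(self, stmt: S.AssertStmt) -> None:
        batch = self._resolve_rules(stmt.rule_names, stmt.location)
        for rule in batch:
            if any(r.name == rule.name for r in self.asserted):
                raise EugeneNameError(f"rule {rule.name} already asserted", stmt.location)
        # Scoped rules check their named device immediately; unscoped rules
        # check every concrete (non-template) device declared so far.
        for rule in batch:
            scope = rule.scope()
            targets = (
                [self._lookup_device(scope)] if scope else self._declared_concrete_devices()
            )
            for device in targets:
                if not self._evaluate_rule(rule, device):
                    raise EugeneAssertionError(
                        f"asserted rule {rule.name} violated by device {device.name}",
                        stmt.location,
                    )
        self.asserted.extend(batch)
        # Prune every existing design space with the newly asserted batch.
        known = self._known_instances()
        for template_name, space in list(self.result.design_spaces.items()):
            pruned, records = R.prune(space, batch, self._lookup_device, known)
            self.result.design_spaces[template_name] = pruned
            self.symbols.register_design_space(template_name, pruned)
            for rec in records:
                self.result.prune_log.append(
                    PruneStep(template_name, rec.rule, rec.removed, rec.remaining)
                )

    def _exec_note(self, stmt: S.NoteStmt) -> None:
        batch = self._resolve_rules(stmt.rule_names, stmt.location)
        for rule in batch:
            if any(r.name == rule.name for r in self.noted):
                raise EugeneNameError(f"rule {rule.name} already noted", stmt.location)
        self.noted.extend(batch)
        ruleset = R.RuleSet(noted=batch)
        for device in self._declared_concrete_devices():
            self.result.warnings.extend(R.note(ruleset, device, self._lookup_device))
        for space in self.result.design_spaces.values():
            for device in space.devices:
                self.result.warnings.extend(R.note(ruleset, device, self._lookup_device))

    def _exec_permute(self, stmt: S.PermuteCall) -> None:
        template = self._lookup_device(stmt.device_name)
        library = PartLibrary.from_symbols(self.symbols)
        space = permute(template, library)
        if self.asserted:
            space, records = R.prune(
                space, self.asserted, self._lookup_device, self._known_instances()
            )
            for rec in records:
                self.result.prune_log.append(
                    PruneStep(template.name, rec.rule, rec.removed, rec.remaining)
                )
        self.result.design_spaces[template.name] = space
        self.symbols.register_design_space(template.name, space)
        self._permuted.add(template.name)

    def _exec_print(self, stmt: S.PrintCall) -> None:
        value = self._eval_expr(stmt.arg, stmt.location)
        if isinstance(value, (PartInstance, Device)):
            self.result.output.append(value.render())
        elif isinstance(value, PrimitiveValue):
            text = value.value if value.kind == "txt" else value.render()
            self.result.output.append(str(text))
        else:  # pragma: no cover - defensive
            self.result.output.append(str(value))

    def _exec_var_decl(self, stmt: S.VarDecl) -> None:
        for name, expr in stmt.declarations:
            var = Variable(name, stmt.kind)
            if expr is not None:
                var.value = self._eval_primitive(expr, stmt.kind, stmt.location)
            self.symbols.define(name, var, stmt.location)

    def _exec_assignment(self, stmt: S.Assignment) -> None:
        var = self.symbols.lookup(stmt.target, stmt.location)
        if not isinstance(var, Variable):
            raise EugeneNameError(f"{stmt.target!r} is not an assignable variable", stmt.location)
        var.value = self._eval_primitive(stmt.expr, var.kind, stmt.location)

    def _exec_expr_stmt(self, stmt: S.ExprStmt) -> None:
        self._eval_expr(stmt.expr, stmt.location)  # forces name resolution

    # -- expression evaluation ------------------------------------------
    def _eval_expr(self, expr: S.Expr, location: SourceLocation):
        if isinstance(expr, S.Literal):
            return PrimitiveValue(expr.kind, expr.value)
        if isinstance(expr, S.ListLiteral):
            return self._eval_list(expr, None, location)
        if isinstance(expr, S.NameRef):
            obj = self.symbols.lookup(expr.name, location)
            if isinstance(obj, Variable):
                if obj.value is UNSET:
                    raise EugeneNameError(
                        f"variable {obj.name!r} used before assignment", location
                    )
                return obj.value
            return obj
        if isinstance(expr, S.IndexRef):
            base = self.symbols.lookup(expr.name, location)
            index = self._eval_index(expr.index, location)
            if isinstance(base, Device):
                return base[index]
            if isinstance(base, Variable):
                if base.value is UNSET:
                    raise EugeneNameError(
                        f"variable {base.name!r} used before assignment", location
                    )
                base = base.value
            if isinstance(base, PrimitiveValue):
                try:
                    return base[index]
                except EugeneTypeError as err:
                    raise EugeneTypeError(str(err), location) from err
            raise EugeneTypeError(f"{expr.name!r} is not indexable", location)
        raise EugeneTypeError(f"cannot evaluate {expr!r}", location)  # pragma: no cover

    def _eval_index(self, index, location: SourceLocation) -> int:
        value = self._eval_expr(index, location)
        if isinstance(value, PrimitiveValue) and value.kind == "num" and isinstance(
            value.value, int
        ):
            return value.value
        raise EugeneTypeError("index must be an integer", location)

    def _eval_list(self, expr: S.ListLiteral, expected: str | None, location) -> PrimitiveValue:
        kinds = {item.kind for item in expr.items}
        if not expr.items:
            kind = expected or "txt[]"
        elif kinds == {"txt"}:
            kind = "txt[]"
        elif kinds == {"num"}:
            kind = "num[]"
        else:
            raise EugeneTypeError("list literals must be homogeneous txt or num", location)
        return PrimitiveValue(kind, tuple(item.value for item in expr.items))

    def _eval_primitive(self, expr: S.Expr, expected_kind: str, location) -> PrimitiveValue:
        if isinstance(expr, S.ListLiteral):
            value = self._eval_list(expr, expected_kind, location)
        else:
            value = self._eval_expr(expr, location)
        if not isinstance(value, PrimitiveValue):
            raise EugeneTypeError(f"expected a {expected_kind} value", location)
        if value.kind != expected_kind:
            raise EugeneTypeError(
                f"kind mismatch: {value.kind} value where {expected_kind} expected", location
            )
        return value


def interpret(tree: S.SyntaxTree) -> InterpreterResult:
    """Execute a (include-resolved) syntax tree and return the final state."""
    return Interpreter().execute(tree)


def run_file(path: str | Path, include_paths: list[str | Path] | None = None) -> InterpreterResult:
    """Parse, resolve includes, and interpret a Eugene source file."""
    return interpret(load_program(path, include_paths))


def run_text(source: str, include_paths: list[str | Path] | None = None,
             current_dir: str | Path = ".") -> InterpreterResult:
    """Interpret Eugene source given as a string."""
    from .includes import resolve_includes
    from .parser import parse

    tree = resolve_includes(parse(source), include_paths, current_dir)
    return interpret(tree)
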