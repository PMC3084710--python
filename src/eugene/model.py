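"""Typed object model for genetic parts, devices, and the interpreter namespace.

The abstraction hierarchy mirrors common genetic design automation practice:

* a *Property* is a named, typed attribute (a DNA sequence, an identifier,
  a strength profile) attached to a class of parts;
* a *Part definition* fixes the ordered property slots of a part type
  (promoter, RBS, ORF, terminator, ...);
* a *Part instance* is a concrete part with some or all properties set;
* a *Device* is a named, 5'->3' ordered composition of part instances
  and/or sub-devices -- the composite unit of design.

Property values may legitimately be *unset* (a promoter whose inducibility
is unknown); unset is distinct from an empty string or zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Union

from .errors import EugeneNameError, EugeneTypeError, SourceLocation

#: Primitive kind keywords of the language.
PRIMITIVE_KINDS = ("txt", "num", "boolean", "txt[]", "num[]")

#: Sentinel distinguishing "never assigned" from any real payload.
UNSET = object()


@dataclass(frozen=True)
class PrimitiveValue:
    """A typed primitive payload: text, number, flag, or a list thereof.

    Numbers hold Python ``int`` or ``float`` exactly as parsed (the language
    has a single numeric kind covering both). List payloads are tuples of
    the scalar kind, indexed 0-based.
    """

    kind: str
    value: Union[str, int, float, bool, tuple]

    def __post_init__(self) -> None:
        if self.kind not in PRIMITIVE_KINDS:
            raise EugeneTypeError(f"unknown primitive kind {self.kind!r}")
        ok = {
            "txt": lambda v: isinstance(v, str),
            "num": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
            "boolean": lambda v: isinstance(v, bool),
            "txt[]": lambda v: isinstance(v, tuple) and all(isinstance(e, str) for e in v),
            "num[]": lambda v: isinstance(v, tuple)
            and all(isinstance(e, (int, float)) and not isinstance(e, bool) for e in v),
        }[self.kind]
        if not ok(self.value):
            raise EugeneTypeError(f"value {self.value!r} is not a {self.kind}")

    def __getitem__(self, index: int):
        if self.kind not in ("txt[]", "num[]"):
            raise EugeneTypeError(f"cannot index a {self.kind} value")
        if not 0 <= index < len(self.value):
            raise EugeneTypeError(
                f"index {index} out of range for list of length {len(self.value)}"
            )
        scalar = self.kind[:-2]
        return PrimitiveValue(scalar, self.value[index])

    def render(self) -> str:
        if self.kind in ("txt[]", "num[]"):
            inner = ", ".join(PrimitiveValue(self.kind[:-2], e).render() for e in self.value)
            return f"[{inner}]"
        if self.kind == "txt":
            return f'"{self.value}"'
        if self.kind == "boolean":
            return "true" if self.value else "false"
        return repr(self.value) if isinstance(self.value, float) else str(self.value)


@dataclass(frozen=True)
class PropertyDefinition:
    """A named property slot with a primitive kind, e.g. ``Sequence: txt``."""

    name: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in PRIMITIVE_KINDS:
            raise EugeneTypeError(f"unknown primitive kind {self.kind!r} for Property {self.name}")


@dataclass(frozen=True)
class PartDefinition:
    """A part type: an ordered list of property names.

    Order is significant -- positional instantiation assigns values by this
    order.
    """

    name: str
    property_names: tuple[str, ...]


class PartInstance:
    """A concrete part: a part type plus a (possibly partial) value map."""

    __slots__ = ("name", "part_type", "values")

    def __init__(self, name: str, part_type: str, values: dict[str, PrimitiveValue] | None = None):
        self.name = name
        self.part_type = part_type
        self.values: dict[str, PrimitiveValue] = dict(values or {})

    def get(self, prop: str):
        """Return the property value, or :data:`UNSET` if never assigned."""
        return self.values.get(prop, UNSET)

    def is_set(self, prop: str) -> bool:
        return prop in self.values

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PartInstance)
            and self.name == other.name
            and self.part_type == other.part_type
            and self.values == other.values
        )

    def __hash__(self) -> int:
        return hash((self.name, self.part_type))

    def render(self) -> str:
        body = ", ".join(f"{k}={v.render()}" for k, v in self.values.items())
        return f"{self.part_type} {self.name}({body})"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PartInstance {self.part_type} {self.name}>"


Component = Union[PartInstance, "Device"]


class Device:
    """A named, 5'->3' ordered composition of parts and sub-devices.

    ``provenance`` records, for devices generated by ``permute``, the
    template name and the 1-based permutation ordinal.
    """

    __slots__ = ("name", "components", "provenance")

    def __init__(
        self,
        name: str,
        components: tuple[Component, ...] | list[Component],
        provenance: tuple[str, int] | None = None,
    ):
        self.name = name
        self.components: tuple[Component, ...] = tuple(components)
        self.provenance = provenance
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        def walk(dev: "Device", seen: tuple) -> None:
            if dev.name in seen:
                raise EugeneNameError(f"Device {dev.name} contains itself")
            for c in dev.components:
                if isinstance(c, Device):
                    walk(c, seen + (dev.name,))

        walk(self, ())

    def __len__(self) -> int:
        return len(self.components)

    def __getitem__(self, index: int) -> Component:
        if not isinstance(index, int) or not 0 <= index < len(self.components):
            raise EugeneTypeError(
                f"component index {index} out of range for Device {self.name} "
                f"({len(self.components)} components)"
            )
        return self.components[index]

    def leaves(self) -> list[PartInstance]:
        """Flattened 5'->3' list of leaf part instances (sub-devices expanded)."""
        out: list[PartInstance] = []
        for c in self.components:
            if isinstance(c, Device):
                out.extend(c.leaves())
            else:
                out.append(c)
        return out

    def signature(self) -> tuple[str, ...]:
        """Ordered component names; the identity used when comparing layouts."""
        return tuple(c.name for c in self.components)

    def render(self) -> str:
        return f"Device {self.name}({', '.join(self.signature())})"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Device {self.name} {self.signature()}>"


class SymbolTable:
    """Single global namespace of the interpreter.

    Maps identifiers to property definitions, part definitions, part
    instances, devices, primitive variables, and rules. Redefining an
    existing name is an error; all names are globally visible.

    Devices generated by ``permute`` are bound lazily: looking up
    ``Template_k`` resolves ordinal ``k`` (1-based) in the template's
    design space via a resolver registered by the combinatorics layer.
    """

    def __init__(self) -> None:
        self._table: dict[str, object] = {}
        self._space_resolvers: dict[str, object] = {}

    def define(self, name: str, obj: object, location: SourceLocation | None = None) -> None:
        if name in self._table:
            raise EugeneNameError(f"redefinition of {name!r}", location)
        self._table[name] = obj

    def __contains__(self, name: str) -> bool:
        return name in self._table

    def lookup(self, name: str, location: SourceLocation | None = None) -> object:
        try:
            return self._table[name]
        except KeyError:
            pass
        resolved = self._resolve_permutation(name)
        if resolved is not None:
            return resolved
        raise EugeneNameError(f"unknown identifier {name!r}", location)

    def register_design_space(self, template_name: str, space) -> None:
        self._space_resolvers[template_name] = space

    def design_spaces(self) -> dict[str, object]:
        return dict(self._space_resolvers)

    def _resolve_permutation(self, name: str):
        head, sep, tail = name.rpartition("_")
        if not sep or not tail.isdigit():
            return None
        space = self._space_resolvers.get(head)
        if space is None:
            return None
        return space.device_at(int(tail))

    def items(self) -> Iterator[tuple[str, object]]:
        return iter(self._table.items())

    def of_type(self, cls) -> list:
        """All registered objects of one model class, in declaration order."""
        return [v for v in self._table.values() if isinstance(v, cls)]
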