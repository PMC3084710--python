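"""The ``permute`` engine: combinatorial expansion of template devices.

``permute`` replaces each part-instance slot of a template device with
every registered instance of that slot's part type, enumerating the full
cross product. Enumeration is in *odometer order*: the rightmost
(3'-most) slot varies fastest, instances in declaration order within
each type. Generated devices are named ``<template>_<k>`` with 1-based
ordinal ``k``, and the template's own slot assignment is always among
the results. Slots holding sub-devices are treated as fixed.

Design spaces keep their unconstrained ordinals through pruning, so
``Template_k`` always refers to the k-th raw permutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import prod

from .errors import EugeneNameError, EugeneTypeError
from .model import Device, PartInstance, SymbolTable


@dataclass
class PartLibrary:
    """Registered part instances grouped by part type, in declaration order."""

    by_type: dict[str, list[PartInstance]] = field(default_factory=dict)

    @classmethod
    def from_symbols(cls, symbols: SymbolTable) -> "PartLibrary":
        lib = cls()
        for inst in symbols.of_type(PartInstance):
            lib.add(inst)
        return lib

    def add(self, instance: PartInstance) -> None:
        bucket = self.by_type.setdefault(instance.part_type, [])
        if any(existing.name == instance.name for existing in bucket):
            raise EugeneNameError(f"instance {instance.name!r} already in library")
        bucket.append(instance)

    def instances_of(self, part_type: str) -> list[PartInstance]:
        return list(self.by_type.get(part_type, []))


@dataclass
class DesignSpace:
    """Ordered collection of concrete devices generated from one template.

    ``entries`` pairs each device with its 1-based permutation ordinal;
    after pruning, surviving devices keep their original ordinals.
    """

    template: Device
    entries: list[tuple[int, Device]]

    @property
    def devices(self) -> list[Device]:
        return [d for _, d in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def device_at(self, ordinal: int) -> Device:
        for k, d in self.entries:
            if k == ordinal:
                return d
        raise EugeneNameError(
            f"permutation {self.template.name}_{ordinal} does not exist "
            "(out of range or pruned)"
        )

    def replace_entries(self, entries: list[tuple[int, Device]]) -> "DesignSpace":
        return DesignSpace(self.template, list(entries))


def _slot_candidates(template: Device, library: PartLibrary) -> list[list]:
    candidates: list[list] = []
    for comp in template.components:
        if isinstance(comp, Device):
            candidates.append([comp])  # sub-devices are fixed slots
            continue
        pool = library.instances_of(comp.part_type)
        if not pool:
            raise EugeneTypeError(
                f"no registered instances of part type {comp.part_type!r} "
                f"for slot {comp.name!r} of template {template.name!r}"
            )
        candidates.append(pool)
    return candidates


def space_size(template: Device, library: PartLibrary) -> int:
    """Cardinality of the unconstrained space: product of slot pool sizes."""
    return prod(len(pool) for pool in _slot_candidates(template, library))


def permute(template: Device, library: PartLibrary) -> DesignSpace:
    """Expand ``template`` into its full design space.

    Deterministic: odometer order, 3'-most slot fastest, library
    (declaration) order within each slot.
    """
    candidates = _slot_candidates(template, library)
    entries = [
        (k, Device(f"{template.name}_{k}", combo, provenance=(template.name, k)))
        for k, combo in enumerate(itertools.product(*candidates), start=1)
    ]
    return DesignSpace(template, entries)


def constrained_permute(template: Device, library: PartLibrary, asserted, lookup=None,
                        known_instances=None) -> tuple[DesignSpace, list]:
    """``permute`` followed by rule filtering; surviving ordinals keep
    their unconstrained values. Returns the pruned space and the per-rule
    removal records."""
    from .rules import prune  # local import to keep module layering acyclic

    space = permute(template, library)
    return prune(space, list(asserted), lookup, known_instances)
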