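"""Rule operator truth table, Assert/Note semantics, and pruning algebra."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from eugene.combinatorics import DesignSpace
from eugene.errors import EugeneNameError
from eugene.model import Device
from eugene.rules import (
    And,
    Before,
    Contains,
    NotContains,
    NotMoreThan,
    NotWith,
    Or,
    Rule,
    RuleSet,
    With,
    evaluate,
    note,
    occurrences,
    prune,
)

from conftest import make_part


def device_of(*names: str, name: str = "D") -> Device:
    return Device(name, tuple(make_part(n, "T") for n in names))


class TestOccurrences:
    def test_positions_are_zero_based(self, simple_device):
        assert occurrences(simple_device, "P1") == [0]
        assert occurrences(simple_device, "GFP") == [1]

    def test_repeated_instance_reports_all_positions(self):
        # the two-nTag topology shape: the cleavage site CS occupies two slots
        d = device_of("P", "nTag", "CS", "OS", "nTag", "CS", "OS", "T")
        assert occurrences(d, "CS") == [2, 5]

    def test_absent_instance_yields_empty(self, simple_device):
        assert occurrences(simple_device, "P2") == []

    def test_positions_count_flattened_leaves(self, simple_device):
        outer = Device("Outer", (make_part("X", "T"), simple_device))
        assert occurrences(outer, "GFP") == [2]


class TestTruthTable:
    def test_contains_and_notcontains(self, simple_device):
        assert evaluate(Contains("P1"), simple_device)
        assert not evaluate(Contains("P2"), simple_device)
        assert evaluate(NotContains("P2"), simple_device)
        assert not evaluate(NotContains("P1"), simple_device)

    def test_before_compares_first_occurrences(self, simple_device):
        assert evaluate(Before("P1", "GFP"), simple_device)
        assert not evaluate(Before("GFP", "P1"), simple_device)
        d = device_of("x", "y", "x")
        assert evaluate(Before("x", "y"), d)  # first x at 0 precedes y at 1

    def test_before_is_vacuously_true_when_either_absent(self, simple_device):
        assert evaluate(Before("P1", "missing"), simple_device)
        assert evaluate(Before("missing", "GFP"), simple_device)

    def test_with_is_conditional_not_symmetric(self):
        both = device_of("x", "y")
        only_x = device_of("x", "z")
        neither = device_of("w", "z")
        assert evaluate(With("x", "y"), both)
        assert not evaluate(With("x", "y"), only_x)
        assert evaluate(With("x", "y"), neither)  # vacuous when x absent

    def test_notwith_forbids_co_occurrence(self):
        assert not evaluate(NotWith("x", "y"), device_of("x", "y"))
        assert evaluate(NotWith("x", "y"), device_of("x", "z"))
        assert evaluate(NotWith("x", "y"), device_of("w", "z"))

    def test_notmorethan_counts_occurrences(self):
        twice = device_of("a", "ctagX", "b", "ctagX")
        assert not evaluate(NotMoreThan("ctagX", 1), twice)
        assert evaluate(NotMoreThan("ctagX", 2), twice)
        assert evaluate(NotMoreThan("ctagX", 1), device_of("a", "ctagX"))

    def test_and_or_combinators(self, simple_device):
        assert evaluate(And(Contains("P1"), Contains("GFP")), simple_device)
        assert not evaluate(And(Contains("P1"), Contains("P2")), simple_device)
        assert evaluate(Or(Contains("P2"), Contains("GFP")), simple_device)

    def test_scoped_contains_evaluates_against_named_device(self, simple_device):
        other = device_of("A", "B", name="Other")
        lookup = {"BBa_1": simple_device, "Other": other}.__getitem__
        assert evaluate(Contains("P1", scope="BBa_1"), other, lookup)
        assert not evaluate(Contains("P1", scope="Other"), simple_device, lookup)

    def test_unknown_operand_with_validation(self, simple_device):
        with pytest.raises(EugeneNameError):
            evaluate(Contains("ghost"), simple_device, known_instances={"P1", "GFP"})


@settings(derandomize=True, max_examples=100)
@given(
    members=st.lists(st.sampled_from(["x", "y", "z", "w"]), max_size=4),
)
def test_notwith_demorgan_pair(members):
    """x NOTWITH y == not (CONTAINS x and CONTAINS y) for every device."""
    d = device_of(*members) if members else Device("D", ())
    lhs = evaluate(NotWith("x", "y"), d)
    rhs = not (evaluate(Contains("x"), d) and evaluate(Contains("y"), d))
    assert lhs == rhs


def space_of(layouts: list[tuple[str, ...]]) -> DesignSpace:
    template = Device("T", tuple(make_part(n, "T") for n in layouts[0]))
    entries = [
        (k, Device(f"T_{k}", tuple(make_part(n, "T") for n in layout),
                   provenance=("T", k)))
        for k, layout in enumerate(layouts, start=1)
    ]
    return DesignSpace(template, entries)


LAYOUTS = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "c"), ("a", "a")]
RULES = [
    Rule("NoA", NotContains("a")),
    Rule("BWithC", With("b", "c")),
    Rule("COnce", NotMoreThan("c", 1)),
]


class TestPrune:
    def test_survivors_and_accounting(self):
        space = space_of(LAYOUTS)
        pruned, records = prune(space, RULES)
        # NoA removes the three a-devices; BWithC removes (b,.) without c: none
        # left after NoA except (b,c) which has c; COnce removes (c,c).
        assert [d.signature() for d in pruned.devices] == [("b", "c")]
        assert [(r.rule, r.removed, r.remaining) for r in records] == [
            ("NoA", 3, 2),
            ("BWithC", 0, 2),
            ("COnce", 1, 1),
        ]

    def test_original_order_and_ordinals_preserved(self):
        pruned, _ = prune(space_of(LAYOUTS), [Rule("COnce", NotMoreThan("c", 1))])
        assert [k for k, _ in pruned.entries] == [1, 2, 3, 5]

    def test_idempotence(self):
        space = space_of(LAYOUTS)
        once, _ = prune(space, RULES)
        twice, records = prune(once, RULES)
        assert [d.name for d in twice.devices] == [d.name for d in once.devices]
        assert all(r.removed == 0 for r in records)

    @pytest.mark.parametrize("order", list(itertools.permutations(range(3))))
    def test_survivors_invariant_under_rule_order(self, order):
        space = space_of(LAYOUTS)
        baseline, _ = prune(space, RULES)
        shuffled, _ = prune(space, [RULES[i] for i in order])
        assert [d.name for d in shuffled.devices] == [d.name for d in baseline.devices]

    def test_empty_rule_set_is_identity(self):
        space = space_of(LAYOUTS)
        pruned, records = prune(space, [])
        assert records == []
        assert [d.name for d in pruned.devices] == [d.name for d in space.devices]

    def test_adding_a_rule_never_increases_survivors(self):
        space = space_of(LAYOUTS)
        for k in range(len(RULES)):
            fewer, _ = prune(space, RULES[:k])
            more, _ = prune(space, RULES[: k + 1])
            assert len(more) <= len(fewer)


class TestNote:
    def test_satisfied_rule_emits_nothing(self, simple_device):
        rs = RuleSet(noted=[Rule("R2", Contains("P1"))])
        assert note(rs, simple_device) == []

    def test_violated_rules_emit_in_declaration_order(self, simple_device):
        rs = RuleSet(noted=[Rule("R2", Contains("P9")), Rule("R3", NotContains("P1"))])
        assert note(rs, simple_device) == [
            "R2 violated by BBa_1",
            "R3 violated by BBa_1",
        ]

    def test_rule_cannot_be_both_asserted_and_noted(self):
        rule = Rule("R", Contains("x"))
        with pytest.raises(EugeneNameError):
            RuleSet(asserted=[rule], noted=[rule])
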