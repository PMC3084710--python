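"""Interpreter semantics: declarations, instantiation forms, printing,
permutation-name binding, and Assert/Note behavior."""

import pytest

from eugene import run_text
from eugene.errors import (
    EugeneAssertionError,
    EugeneNameError,
    EugeneTypeError,
)
from eugene.model import Device, PartInstance

HEADER = (
    "Property ID(num);\n"
    "Property sequence(txt);\n"
    "Property strength(num);\n"
    "Part Promoter(ID, sequence, strength);\n"
    "Part CDS(ID, sequence);\n"
)


def test_positional_and_named_instantiation_are_indistinguishable():
    positional = run_text(HEADER + 'Promoter P1(1, "TATATA", 30);\n')
    named = run_text(
        HEADER + "Promoter P1(.ID(1), .sequence(\"TATATA\"), .strength(30));\n"
    )
    assert positional.symbols.lookup("P1") == named.symbols.lookup("P1")


def test_empty_parentheses_create_fully_unset_instance():
    result = run_text(HEADER + "Promoter araP();\n")
    inst = result.symbols.lookup("araP")
    assert isinstance(inst, PartInstance)
    assert inst.values == {}


def test_partial_instantiation_leaves_rest_unset():
    result = run_text(HEADER + 'Promoter P1(.sequence("TATATA"));\n')
    inst = result.symbols.lookup("P1")
    assert inst.is_set("sequence") and not inst.is_set("strength")


@pytest.mark.parametrize(
    "stmt,error",
    [
        ('Promoter P1("TATATA", 1, 30);', EugeneTypeError),  # txt into num slot
        ('Promoter P1(1, "T", 30, 4);', EugeneTypeError),  # too many positionals
        ("Promoter P1(.Bogus(1));", EugeneNameError),  # unknown property
        ("Bogus P1();", EugeneNameError),  # unknown part type
        ("Promoter P1(); Promoter P1();", EugeneNameError),  # redefinition
    ],
)
def test_bad_instantiations(stmt, error):
    with pytest.raises(error):
        run_text(HEADER + stmt)


def test_device_declaration_preserves_order_and_annotations():
    result = run_text(
        HEADER
        + 'Promoter P1(1, "TATATA", 30);\nCDS GFP(2, "ATG");\n'
        + "Device BBa_1(Promoter P1, CDS GFP);\n"
    )
    device = result.symbols.lookup("BBa_1")
    assert device.signature() == ("P1", "GFP")


def test_annotation_mismatch_is_an_error():
    with pytest.raises(EugeneTypeError):
        run_text(HEADER + "Promoter P1();\nDevice D(CDS P1);\n")


def test_self_referencing_device_is_an_error():
    with pytest.raises(EugeneNameError):
        run_text("Device D(D);")


def test_use_before_definition_is_an_error():
    with pytest.raises(EugeneNameError):
        run_text("Part Promoter(ID);\nProperty ID(num);\n")


def test_array_indexing_and_print_emit_first_element():
    result = run_text("num[] a = [1, 2, 3, 4];\nnum x = a[0];\nprint(x);\n")
    assert result.output == ["1"]


def test_print_renders_part_with_unset_properties_omitted():
    result = run_text(HEADER + 'Promoter P1(.sequence("TATATA"));\nprint(P1);\n')
    assert result.output == ['Promoter P1(sequence="TATATA")']


def test_variable_declaration_then_assignment():
    result = run_text("num num1, num2;\nnum1 = 1.0;\nprint(num1);\n")
    assert result.output == ["1.0"]


def test_device_component_indexing_is_zero_based():
    result = run_text(
        HEADER
        + 'Promoter P1(1, "T", 1);\nCDS GFP(2, "A");\nDevice BBa_1(P1, GFP);\n'
        + "print(BBa_1[0]);\n"
    )
    assert result.output[0].startswith("Promoter P1(")


PERMUTE_PROGRAM = (
    HEADER
    + 'Promoter P1(1, "T", 1);\nPromoter P2(2, "A", 2);\nCDS GFP(3, "ATG");\n'
    + "Device BBa1(P1, GFP);\npermute(BBa1);\n"
)


def test_permutation_names_are_bound_one_based():
    result = run_text(PERMUTE_PROGRAM + "print(BBa1_2);\n")
    # second permutation: promoter slot varied to P2
    assert result.output == ["Device BBa1_2(P2, GFP)"]


def test_out_of_range_permutation_name_is_unknown():
    with pytest.raises(EugeneNameError):
        run_text(PERMUTE_PROGRAM + "BBa1_3;\n")


def test_asserted_rule_violation_on_declared_device_halts():
    with pytest.raises(EugeneAssertionError) as err:
        run_text(
            HEADER
            + 'Promoter P1(1, "T", 1);\nCDS GFP(2, "A");\nDevice BBa_1(P1, GFP);\n'
            + "Rule R(NOTCONTAINS P1);\nAssert(R);\n"
        )
    assert "R" in str(err.value)


def test_asserted_rule_checks_devices_declared_afterwards():
    source = (
        HEADER
        + 'Promoter P1(1, "T", 1);\nCDS GFP(2, "A");\n'
        + "Rule R(P1 BEFORE GFP);\nAssert(R);\nDevice BBa_1(GFP, P1);\n"
    )
    with pytest.raises(EugeneAssertionError):
        run_text(source)


def test_scoped_assert_checks_only_its_device():
    source = (
        HEADER
        + 'Promoter P1(1, "T", 1);\nCDS GFP(2, "A");\n'
        + "Device BBa_1(P1, GFP);\nDevice BBa_2(GFP);\n"
        + "Rule R2(BBa_1 CONTAINS P1);\nAssert(R2);\n"
    )
    run_text(source)  # BBa_2 lacks P1 but the rule is scoped to BBa_1


def test_noted_rule_warns_but_never_halts():
    result = run_text(
        HEADER
        + 'Promoter P1(1, "T", 1);\nCDS GFP(2, "A");\nDevice BBa_1(P1, GFP);\n'
        + "Rule R(NOTCONTAINS P1);\nNote(R);\n"
    )
    assert result.warnings == ["R violated by BBa_1"]
    assert isinstance(result.symbols.lookup("BBa_1"), Device)


def test_permuted_template_is_exempt_from_hard_checks():
    """A template that has been permuted is a space generator, not a design
    commitment: rules filter its space instead of halting on the template."""
    result = run_text(
        PERMUTE_PROGRAM + "Rule R(NOTCONTAINS P1);\nAssert(R);\n"
    )
    assert [d.signature() for d in result.surviving_devices()] == [("P2", "GFP")]


def test_determinism_identical_source_identical_state():
    r1 = run_text(PERMUTE_PROGRAM + "print(BBa1_1);\n")
    r2 = run_text(PERMUTE_PROGRAM + "print(BBa1_1);\n")
    assert r1.output == r2.output
    assert [d.signature() for d in r1.surviving_devices()] == [
        d.signature() for d in r2.surviving_devices()
    ]
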