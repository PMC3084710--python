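"""Fixture generators: library composition, determinism, shipped copies."""

import pytest

from eugene.errors import EugeneTypeError
from eugene.fixtures import (
    BUILDERS,
    CSD_DISPLAYERS,
    DEFAULT_SEED,
    J23116_SEQUENCE,
    SequenceGenerator,
    build_csd_fixture,
    build_pt_fixture,
    distinct_tag_assignments,
    packaged_fixture_dir,
    select_representatives,
    run_fixture,
)
from eugene.model import Device, PartInstance


class TestSequenceGenerator:
    def test_same_seed_same_sequences(self):
        a = SequenceGenerator(7)
        b = SequenceGenerator(7)
        assert [a.sequence() for _ in range(5)] == [b.sequence() for _ in range(5)]

    def test_lengths_within_declared_range(self):
        gen = SequenceGenerator(3, min_len=20, max_len=60)
        for _ in range(50):
            seq = gen.sequence()
            assert 20 <= len(seq) <= 60
            assert set(seq) <= set("ACGT")


@pytest.mark.parametrize("name", sorted(BUILDERS))
def test_builders_are_deterministic(name):
    assert BUILDERS[name](11).sources == BUILDERS[name](11).sources
    assert BUILDERS[name](11).sources != BUILDERS[name](12).sources


@pytest.mark.parametrize("name", sorted(BUILDERS))
def test_shipped_data_matches_default_seed_regeneration(name):
    """The packaged .eug/.h files are exactly what the generator writes at
    the default seed."""
    program = BUILDERS[name](DEFAULT_SEED)
    directory = packaged_fixture_dir(name)
    for filename, text in program.sources.items():
        assert (directory / filename).read_text() == text


class TestCsdLibrary:
    def test_library_sizes(self, csd_results):
        symbols = csd_results["expand"].symbols
        by_type = {}
        for inst in symbols.of_type(PartInstance):
            by_type.setdefault(inst.part_type, []).append(inst.name)
        assert {t: len(v) for t, v in by_type.items()} == {
            "Passenger": 6, "Spacer": 5, "Displayer": 15, "Terminator": 1,
        }

    def test_named_displayers_from_published_rules_present(self):
        for name in ("Disp_upaG", "Disp_Vta", "Disp_ehaB", "Disp_CPG6",
                     "Disp_AIDA", "Disp_cl", "Disp_Pcryo"):
            assert name in CSD_DISPLAYERS

    def test_template_space_sizes(self, csd_results):
        spaces = csd_results["expand"].design_spaces
        assert len(spaces["DeviceType1"]) == 450  # 6 * 5 * 15
        assert len(spaces["DeviceType2"]) == 90  # 6 * 15


class TestPtLibrary:
    def test_thirty_one_basic_parts(self, pt_results):
        parts = pt_results["expand"].symbols.of_type(PartInstance)
        assert len(parts) == 31
        by_type = {}
        for p in parts:
            by_type[p.part_type] = by_type.get(p.part_type, 0) + 1
        assert by_type == {"Promoter": 1, "NTag": 12, "CTag": 12, "CS": 1,
                           "OS": 2, "RSO": 2, "Terminator": 1}

    def test_groups_are_uniform_quadruples(self, pt_results):
        devices = pt_results["pruned"].surviving_devices()
        groups = distinct_tag_assignments(devices)
        assert all(len(members) == 4 for members in groups.values())
        assert 4 * len(groups) == len(devices)

    def test_projection_ignores_topology(self, pt_results):
        groups = distinct_tag_assignments(pt_results["pruned"].surviving_devices())
        for members in list(groups.values())[:10]:
            templates = {d.provenance[0] for d in members}
            assert templates == {"deviceTypeNN", "deviceTypeCC",
                                 "deviceTypeCN", "deviceTypeNC"}

    def test_representatives_are_deterministic(self, pt_results):
        groups = distinct_tag_assignments(pt_results["pruned"].surviving_devices())
        reps1 = [d.name for d in select_representatives(groups)]
        reps2 = [d.name for d in select_representatives(groups)]
        assert reps1 == reps2
        assert len(reps1) == len(groups)

    def test_non_topology_device_is_rejected(self):
        bogus = Device("X", tuple(PartInstance(f"p{i}", "CS") for i in range(8)))
        with pytest.raises(EugeneTypeError):
            distinct_tag_assignments([bogus])
        with pytest.raises(EugeneTypeError):
            distinct_tag_assignments([Device("Y", ())])


class TestRegistryProgram:
    def test_main_file_is_include_plus_single_declaration(self):
        program = BUILDERS["registry"]()
        main = program.sources["BBa_K112809.eug"]
        statements = [ln for ln in main.splitlines() if ln.strip()]
        assert len(statements) == 2
        assert statements[0].startswith("include ")
        assert statements[1].startswith("Device BBa_K112809(")

    def test_j23116_carries_published_sequence(self, registry_result):
        inst = registry_result.symbols.lookup("BBa_J23116")
        assert inst.get("Sequence").value == J23116_SEQUENCE
        assert len(J23116_SEQUENCE) == 41

    def test_inducible_left_unset_on_j23116(self, registry_result):
        assert not registry_result.symbols.lookup("BBa_J23116").is_set("Inducible")


class TestRepressilatorProgram:
    def test_twelve_components_in_declared_order(self, repressilator_result):
        device = repressilator_result.symbols.lookup("Repressilator")
        assert list(device.signature()) == BUILDERS["repressilator"]().expected["order"]

    def test_reordering_promoter_after_orf_trips_assertion(self, tmp_path):
        from eugene import run_text
        from eugene.errors import EugeneAssertionError

        program = BUILDERS["repressilator"]()
        source = program.sources["repressilator.eug"].replace(
            "Device Repressilator(araP, rbs1, DNAlac",
            "Device Repressilator(DNAlac, rbs1, araP",
        )
        with pytest.raises(EugeneAssertionError, match="promoterToCoding1"):
            run_text(source)
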