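"""Serialization: XML netlist round-trips, sequence flattening, junctions."""

from io import StringIO

import pytest
from Bio import SeqIO
from hypothesis import given, settings, strategies as st

from eugene import export
from eugene.errors import EugeneExportError
from eugene.fixtures import run_fixture, build_registry_fixture
from eugene.model import Device, PartInstance, PrimitiveValue
from eugene import run_text


def seq_part(name: str, sequence: str, orientation: str | None = None,
             part_type: str = "Part") -> PartInstance:
    values = {"Sequence": PrimitiveValue("txt", sequence)}
    if orientation is not None:
        values["Orientation"] = PrimitiveValue("txt", orientation)
    return PartInstance(name, part_type, values)


class TestFlattenSequence:
    def test_forward_concatenation(self):
        d = Device("D", (seq_part("a", "ACTG"), seq_part("b", "GG")))
        assert export.flatten_sequence(d) == "ACTGGG"

    def test_reverse_part_contributes_reverse_complement(self):
        d = Device("D", (seq_part("a", "ACTG", "Reverse"),))
        assert export.flatten_sequence(d) == "CAGT"

    def test_reverse_of_reverse_is_identity(self):
        fwd = Device("F", (seq_part("a", "GATTACA"),))
        rev_rev = Device(
            "R", (seq_part("a", export.flatten_sequence(
                Device("X", (seq_part("x", "GATTACA", "Reverse"),))), "Reverse"),)
        )
        assert export.flatten_sequence(rev_rev) == export.flatten_sequence(fwd)

    def test_unset_sequence_error_names_the_part(self):
        d = Device("D", (seq_part("ok", "AC"), PartInstance("bad", "Part")))
        with pytest.raises(EugeneExportError, match="bad"):
            export.flatten_sequence(d)

    def test_invalid_orientation_rejected(self):
        d = Device("D", (seq_part("a", "AC", "Sideways"),))
        with pytest.raises(EugeneExportError):
            export.flatten_sequence(d)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=20), min_size=1,
                    max_size=6))
    def test_length_additivity(self, seqs):
        parts = tuple(seq_part(f"p{i}", s) for i, s in enumerate(seqs))
        assert len(export.flatten_sequence(Device("D", parts))) == sum(map(len, seqs))

    def test_sub_devices_flattened_in_order(self):
        inner = Device("I", (seq_part("a", "AA"), seq_part("b", "CC")))
        outer = Device("O", (seq_part("p", "G"), inner))
        assert export.flatten_sequence(outer) == "GAACC"


class TestXml:
    def test_round_trip_reconstructs_order_and_values(self, registry_result):
        doc = export.to_xml(registry_result)
        back = export.from_xml(doc)
        (device,) = [d for d in back["devices"] if d[0] == "BBa_K112809"]
        assert [c[0] for c in device[1]] == build_registry_fixture().expected["order"]
        j23116 = dict((p[0], p[2]) for p in back["parts"])["BBa_J23116"]
        assert j23116["Sequence"] == ("txt", build_registry_fixture().expected["J23116_sequence"])

    def test_repressilator_device_has_twelve_ordered_children(self, repressilator_result):
        back = export.from_xml(export.to_xml(repressilator_result))
        (device,) = [d for d in back["devices"] if d[0] == "Repressilator"]
        assert len(device[1]) == 12
        assert device[1][0] == ("araP", "Promoter")

    def test_empty_program_gives_empty_dictionaries(self):
        back = export.from_xml(export.to_xml(run_text("")))
        assert back == {"properties": [], "partTypes": [], "parts": [], "devices": []}

    def test_list_valued_properties_round_trip(self):
        result = run_text(
            "Property Strength(num[]);\nPart T(Strength);\nT t1(.Strength([1, 2.5]));\n"
        )
        back = export.from_xml(export.to_xml(result))
        assert back["parts"][0][2]["Strength"] == ("num[]", ("1", "2.5"))

    def test_generated_devices_carry_provenance_attributes(self, csd_results):
        doc = export.to_xml(csd_results["expand"])
        assert 'template="DeviceType1" ordinal="1"' in doc


class TestSequenceFiles:
    def test_fasta_records_parse_back(self, repressilator_result):
        device = repressilator_result.symbols.lookup("Repressilator")
        text = export.fasta_text([device])
        (record,) = SeqIO.parse(StringIO(text), "fasta")
        assert record.id == "Repressilator"
        assert str(record.seq) == export.flatten_sequence(device)

    def test_genbank_features_tile_the_sequence(self, registry_result):
        device = registry_result.symbols.lookup("BBa_K112809")
        text = export.genbank_text([device])
        (record,) = SeqIO.parse(StringIO(text), "genbank")
        assert len(record.features) == 8
        spans = [(int(f.location.start), int(f.location.end)) for f in record.features]
        assert spans[0][0] == 0 and spans[-1][1] == len(record.seq)
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))  # contiguous


class TestJunctions:
    def test_k_part_device_has_k_minus_one_junctions(self):
        d = Device("D", tuple(seq_part(f"p{i}", "A") for i in range(8)))
        stats = export.junction_stats([d])
        assert stats.total == 7

    def test_multiplicity_and_uniqueness(self):
        d = Device("D1", (seq_part("a", "A"), seq_part("b", "C")))
        d2 = Device("D2", (seq_part("a", "A"), seq_part("b", "C")))
        stats = export.junction_stats([d, d2])
        assert (stats.total, stats.unique) == (2, 1)
        assert stats.table == ((("a", "b"), 2),)

    def test_unique_invariant_under_device_order(self, csd_results):
        devices = csd_results["rules_90"].surviving_devices()
        fwd = export.junction_stats(devices)
        rev = export.junction_stats(list(reversed(devices)))
        assert (fwd.total, fwd.unique) == (rev.total, rev.unique)
        assert fwd.table == rev.table
        assert fwd.unique <= fwd.total

    def test_tsv_table_is_lexicographically_sorted(self):
        d = Device("D", (seq_part("b", "A"), seq_part("a", "C"), seq_part("b", "G")))
        stats = export.junction_stats([d])
        lines = stats.to_tsv().splitlines()
        assert lines[1].startswith("a\tb") and lines[2].startswith("b\ta")
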