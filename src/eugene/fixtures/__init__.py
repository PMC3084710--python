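"""Runnable reconstructions of published genetic design case studies.

Four programs exercise the whole language surface:

* **registry** -- a T4 lysis device (``BBa_K112809``) built top-down,
  with property/part definitions and part declarations split across
  three header files and a main file holding the single device
  declaration. ``BBa_J23116`` carries its real 41-bp promoter sequence;
  the other parts carry synthetic DNA.
* **csd** -- the cell-surface-display design-space exploration: a
  library of 6 passenger domains, 5 structural spacers, 15 displayer
  domains and a terminator; two template devices (with and without a
  spacer slot) whose permutation yields 540 devices; and a staged rule
  ladder pruning the space to 135, 90, 61, 16 and finally 3 devices.
  Of the 15 displayers only 7 are named in the published listings; the
  other 8 are synthetic placeholders (``Disp_s08`` .. ``Disp_s15``).
* **pt** -- the protein-tagging system: 31 basic parts (1 promoter,
  12 nTags, 12 cTags, 1 shared protease cleavage site, 2 ORFs each in
  an OS and an RSO form, 1 terminator), four bi-cistronic topology
  templates expanding to 2304 devices, and tag-exclusion rules leaving
  2112, which project to 528 distinct per-cistron (ORF, tag)
  assignments.
* **repressilator** -- a lac-tet-ara oscillator declared as a single
  12-component device with BEFORE ordering rules asserted on it.

Sequences are synthetic: uniform random over {A,C,G,T}, lengths 20-60,
drawn from a fixed per-fixture seed, so every run regenerates identical
programs. Hyphens in published part names are normalized to underscores
(``SpacerGly_Ser``) because ``-`` is not an identifier character.
"""

from __future__ import annotations

import random
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ..errors import EugeneTypeError
from ..interpreter import InterpreterResult, run_file
from ..model import Device

#: Seed used for the fixture files shipped under ``fixtures/data``.
DEFAULT_SEED = 42

#: The published 41-bp sequence of promoter BBa_J23116.
J23116_SEQUENCE = "GATCTttgacagctagctcagtcctagggactatgctagcG"


@dataclass
class SequenceGenerator:
    """Deterministic synthetic-DNA source: uniform over {A,C,G,T}."""

    seed: int
    min_len: int = 20
    max_len: int = 60

    def __post_init__(self) -> None:
        self._rng = random.Random(self.seed)

    def sequence(self, length: int | None = None) -> str:
        if length is None:
            length = self._rng.randint(self.min_len, self.max_len)
        return "".join(self._rng.choice("ACGT") for _ in range(length))


@dataclass(frozen=True)
class FixtureProgram:
    """A named set of source files with staged entry points and the
    outcome record each stage is expected to reproduce."""

    name: str
    sources: dict[str, str]
    entry_points: dict[str, str]  # stage name -> main file name
    expected: dict = field(default_factory=dict)

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for filename, text in self.sources.items():
            (directory / filename).write_text(text)
        return directory

    def stages(self) -> list[str]:
        return list(self.entry_points)


def run_fixture(program: FixtureProgram, stage: str | None = None,
                workdir: str | Path | None = None) -> InterpreterResult:
    """Write the fixture's sources and interpret one stage's main file."""
    if stage is None:
        stage = next(iter(program.entry_points))
    entry = program.entry_points[stage]
    if workdir is not None:
        base = program.write(workdir)
        return run_file(base / entry)
    with tempfile.TemporaryDirectory() as tmp:
        base = program.write(tmp)
        return run_file(base / entry)


def packaged_fixture_dir(name: str) -> Path:
    """Directory of the shipped (seed-42) copy of a fixture program."""
    return Path(resources.files("eugene.fixtures") / "data" / name)


def _decl(part_type: str, name: str, gen: SequenceGenerator,
          extra: str = "", ident: str | None = None, sequence: str | None = None) -> str:
    seq = sequence if sequence is not None else gen.sequence()
    ident = ident if ident is not None else name
    return (f'{part_type} {name}(.ID("{ident}"), .Sequence("{seq}"){extra});')


# ---------------------------------------------------------------------------
# Cell surface display

CSD_PASSENGERS = ["PassAg4", "PassLeu", "PassCell", "PassNeedle", "PassStrep", "PassMgfp"]
CSD_SPACERS = ["SpacerINP", "SpacerGly_Ser", "SpacerGfp_Iva", "SpacerBeta_Roll",
               "SpacerBeta_Helix"]
CSD_DISPLAYERS = ["Disp_upaG", "Disp_Vta", "Disp_ehaB", "Disp_CPG6", "Disp_AIDA",
                  "Disp_cl", "Disp_Pcryo"] + [f"Disp_s{i:02d}" for i in range(8, 16)]

_CSD_BLOCK1 = [
    "Rule NoAg4(NOTCONTAINS PassAg4);",
    "Rule NoLeu(NOTCONTAINS PassLeu);",
    "Rule NoCell(NOTCONTAINS PassCell);",
    *[f"Rule NeedleSpacers{i + 1}(PassNeedle NOTWITH {sp});"
      for i, sp in enumerate(CSD_SPACERS)],
    *[f"Rule StrepSpacers{i + 1}(PassStrep NOTWITH {sp});"
      for i, sp in enumerate(CSD_SPACERS[1:])],  # all spacers but the INP repeats
    "Assert(NoAg4 AND NoLeu AND NoCell AND NeedleSpacers1 AND NeedleSpacers2 AND "
    "NeedleSpacers3 AND NeedleSpacers4 AND NeedleSpacers5 AND StrepSpacers1 AND "
    "StrepSpacers2 AND StrepSpacers3 AND StrepSpacers4);",
]

_CSD_BLOCK2 = [
    "Rule MgfpSpacers1(PassMgfp NOTWITH SpacerGly_Ser);",
    "Rule MgfpSpacers2(PassMgfp NOTWITH SpacerGfp_Iva);",
    "Rule StrepSpacers5(PassStrep NOTWITH SpacerINP);",
    "Assert(MgfpSpacers1 AND MgfpSpacers2 AND StrepSpacers5);",
]

_CSD_RULE1 = ("Rule Rule1((PassMgfp WITH SpacerBeta_Roll) OR "
              "(PassMgfp WITH SpacerBeta_Helix) OR (PassMgfp WITH SpacerINP));")
_CSD_RULE2 = ("Rule Rule2((PassStrep WITH Disp_Vta) OR (PassStrep WITH Disp_ehaB) OR "
              "(PassStrep WITH Disp_CPG6) OR (PassStrep WITH Disp_AIDA));")
_CSD_RULE3 = ("Rule Rule3((PassNeedle NOTWITH Disp_cl) AND (PassNeedle NOTWITH Disp_Pcryo) "
              "AND (PassNeedle NOTWITH Disp_CPG6));")

_CSD_BLOCK3 = [_CSD_RULE1, _CSD_RULE2, _CSD_RULE3, "Assert(Rule1 AND Rule2 AND Rule3);"]

# Rule4 replaces Rule1: prune the whole PassMgfp half of the space instead.
_CSD_BLOCK4 = [_CSD_RULE2, _CSD_RULE3, "Rule Rule4(NOTCONTAINS PassMgfp);",
               "Assert(Rule4 AND Rule2 AND Rule3);"]

_CSD_BLOCK5 = [
    "Rule Rule5((PassStrep WITH Disp_CPG6) OR (PassStrep WITH Disp_AIDA));",
    "Rule Rule6(PassNeedle WITH Disp_upaG);",
    "Assert(Rule5 AND Rule6);",
]

_CSD_STAGES: dict[str, list[list[str]]] = {
    "expand": [],
    "rules_135": [_CSD_BLOCK1],
    "rules_90": [_CSD_BLOCK1, _CSD_BLOCK2],
    "rules_61": [_CSD_BLOCK1, _CSD_BLOCK2, _CSD_BLOCK3],
    "rules_16": [_CSD_BLOCK1, _CSD_BLOCK2, _CSD_BLOCK4],
    "rules_3": [_CSD_BLOCK1, _CSD_BLOCK2, _CSD_BLOCK4, _CSD_BLOCK5],
}


def build_csd_fixture(seed: int = DEFAULT_SEED) -> FixtureProgram:
    """The cell-surface-display design-space exploration, staged so each
    pruning checkpoint (540 / 135 / 90 / 61 / 16 / 3) runs separately."""
    gen = SequenceGenerator(seed)
    header = [
        "Property ID(txt);",
        "Property Sequence(txt);",
        "Property Orientation(txt);",
        "Part Passenger(ID, Sequence, Orientation);",
        "Part Spacer(ID, Sequence, Orientation);",
        "Part Displayer(ID, Sequence, Orientation);",
        "Part Terminator(ID, Sequence, Orientation);",
    ]
    for name in CSD_PASSENGERS:
        header.append(_decl("Passenger", name, gen))
    for name in CSD_SPACERS:
        header.append(_decl("Spacer", name, gen))
    for name in CSD_DISPLAYERS:
        header.append(_decl("Displayer", name, gen))
    header.append(_decl("Terminator", "T01", gen))

    preamble = [
        "include csd_parts.h;",
        "Device DeviceType1(PassNeedle, SpacerINP, Disp_upaG, T01);",
        "permute(DeviceType1);",
        "Device DeviceType2(PassNeedle, Disp_upaG, T01);",
        "permute(DeviceType2);",
    ]
    sources = {"csd_parts.h": "\n".join(header) + "\n"}
    entry_points = {}
    for stage, blocks in _CSD_STAGES.items():
        lines = list(preamble)
        for block in blocks:
            lines.extend(block)
        filename = f"csd_{stage}.eug"
        sources[filename] = "\n".join(lines) + "\n"
        entry_points[stage] = filename

    expected = {
        "library_sizes": {"Passenger": 6, "Spacer": 5, "Displayer": 15, "Terminator": 1},
        "survivors": {"expand": 540, "rules_135": 135, "rules_90": 90,
                      "rules_61": 61, "rules_16": 16, "rules_3": 3},
        "template_sizes": {"DeviceType1": 450, "DeviceType2": 90},
        "removals": {"NoAg4": 90, "NoLeu": 90, "NoCell": 90,
                     "NeedleSpacers": 75, "StrepSpacers1_4": 60,
                     "MgfpAndStrep5": 45, "Rule1": 15, "Rule2": 11, "Rule3": 3},
    }
    return FixtureProgram("csd", sources, entry_points, expected)


# ---------------------------------------------------------------------------
# Protein tagging

PT_ANTIBODIES = [f"{i:02d}" for i in range(1, 13)]


def build_pt_fixture(seed: int = DEFAULT_SEED) -> FixtureProgram:
    """The protein-tagging system: 31 basic parts, four bi-cistronic
    topologies (2304 devices), and per-antibody tag-exclusion rules
    (2112 devices)."""
    gen = SequenceGenerator(seed)
    header = [
        "Property ID(txt);",
        "Property Sequence(txt);",
        "Part Promoter(ID, Sequence);",
        "Part NTag(ID, Sequence);",
        "Part CTag(ID, Sequence);",
        "Part CS(ID, Sequence);",
        "Part OS(ID, Sequence);",
        "Part RSO(ID, Sequence);",
        "Part Terminator(ID, Sequence);",
        _decl("Promoter", "P1", gen),
    ]
    for ab in PT_ANTIBODIES:
        header.append(_decl("NTag", f"ntag{ab}", gen, ident=f"Ab{ab}"))
    for ab in PT_ANTIBODIES:
        header.append(_decl("CTag", f"ctag{ab}", gen, ident=f"Ab{ab}"))
    header.append(_decl("CS", "cs1", gen))
    # The same two ORFs exist in an OS form (for N-terminal tagging) and an
    # RSO form (for C-terminal tagging); the shared ID links the two forms.
    for i in (1, 2):
        header.append(_decl("OS", f"osORF{i}", gen, ident=f"ORF{i}"))
    for i in (1, 2):
        header.append(_decl("RSO", f"rsoORF{i}", gen, ident=f"ORF{i}"))
    header.append(_decl("Terminator", "T1", gen))

    preamble = [
        "include pt_parts.h;",
        "Device deviceTypeNN(P1, ntag01, cs1, osORF1, ntag02, cs1, osORF2, T1);",
        "Device deviceTypeCC(P1, rsoORF1, cs1, ctag01, rsoORF2, cs1, ctag02, T1);",
        "Device deviceTypeCN(P1, rsoORF1, cs1, ctag01, ntag01, cs1, osORF1, T1);",
        "Device deviceTypeNC(P1, ntag01, cs1, osORF1, rsoORF1, cs1, ctag01, T1);",
        "permute(deviceTypeNN);",
        "permute(deviceTypeCC);",
        "permute(deviceTypeCN);",
        "permute(deviceTypeNC);",
    ]
    rule_lines = []
    rule_names = []
    for ab in PT_ANTIBODIES:
        rule_lines.append(f"Rule r1a_{ab}(ctag{ab} NOTWITH ntag{ab});")
        rule_lines.append(f"Rule r1b_{ab}(ctag{ab} NOTMORETHAN once);")
        rule_lines.append(f"Rule r1c_{ab}(ntag{ab} NOTMORETHAN once);")
        rule_names.extend([f"r1a_{ab}", f"r1b_{ab}", f"r1c_{ab}"])
    rule_lines.append(f"Assert({' AND '.join(rule_names)});")

    sources = {
        "pt_parts.h": "\n".join(header) + "\n",
        "pt_expand.eug": "\n".join(preamble) + "\n",
        "pt_pruned.eug": "\n".join(preamble + rule_lines) + "\n",
    }
    entry_points = {"expand": "pt_expand.eug", "pruned": "pt_pruned.eug"}
    expected = {
        "basic_parts": 31,
        "survivors": {"expand": 2304, "pruned": 2112},
        "distinct_tag_assignments": 528,
        "group_size": 4,
        "junctions_per_device": 7,
        "total_junctions_528": 3696,
    }
    return FixtureProgram("pt", sources, entry_points, expected)


#: Cistron layouts by middle-part type triple: maps to (orf index, tag index).
_CISTRON_LAYOUTS = {
    ("NTag", "CS", "OS"): (2, 0),
    ("RSO", "CS", "CTag"): (0, 2),
}


def _part_label(part) -> str:
    value = part.values.get("ID")
    return str(value.value) if value is not None else part.name


def distinct_tag_assignments(devices: list[Device]) -> dict[tuple, list[Device]]:
    """Group protein-tagging devices by their ordered per-cistron
    (ORF, tag) assignment, ignoring terminus and topology.

    Each 8-part device is promoter + two tag/cleavage-site/ORF cistrons +
    terminator; a cistron projects to (ORF label, antibody label) via the
    parts' ID property, so the OS and RSO forms of the same ORF -- and the
    nTag and cTag forms of the same antibody -- coincide."""
    groups: dict[tuple, list[Device]] = {}
    for device in devices:
        leaves = device.leaves()
        if len(leaves) != 8:
            raise EugeneTypeError(
                f"device {device.name!r} has {len(leaves)} parts, expected 8"
            )
        key = []
        for triple in (leaves[1:4], leaves[4:7]):
            layout = _CISTRON_LAYOUTS.get(tuple(p.part_type for p in triple))
            if layout is None:
                raise EugeneTypeError(
                    f"device {device.name!r} does not match any tagging topology"
                )
            orf_i, tag_i = layout
            key.append((_part_label(triple[orf_i]), _part_label(triple[tag_i])))
        groups.setdefault(tuple(key), []).append(device)
    return groups


def select_representatives(groups: dict[tuple, list[Device]]) -> list[Device]:
    """One device per tag-assignment group, chosen deterministically
    (smallest (template, ordinal) provenance)."""
    def sort_key(device: Device):
        return device.provenance if device.provenance is not None else (device.name, 0)

    return [min(members, key=sort_key) for members in groups.values()]


# ---------------------------------------------------------------------------
# Repressilator

_REPRESSILATOR_ORDER = ["araP", "rbs1", "DNAlac", "term1", "lacP", "rbs2", "DNAtet",
                        "term2", "tetP", "rbs3", "DNAara", "term3"]


def build_repressilator_fixture(seed: int = DEFAULT_SEED) -> FixtureProgram:
    """A lac-tet-ara oscillator: three promoter/RBS/ORF/terminator
    cistrons in one 12-component device, with a BEFORE ordering rule per
    promoter-ORF pair asserted before the device is declared."""
    gen = SequenceGenerator(seed)
    lines = [
        "Property Sequence(txt);",
        "Property Neg35StartEnd(txt);",
        "Property Neg10StartEnd(txt);",
        "Property OperatorSites(txt[]);",
        "Property OperatorSiteLocations(txt[]);",
        "Property CorrespondingProtein(txt);",
        "Property ProteinBindingInfo(txt);",
        "Part Promoter(Sequence, Neg35StartEnd, Neg10StartEnd, OperatorSites, "
        "OperatorSiteLocations);",
        "Part RBS(Sequence);",
        "Part CodingDNA(Sequence, CorrespondingProtein, ProteinBindingInfo);",
        "Part Terminator(Sequence);",
    ]
    for prom in ("araP", "lacP", "tetP"):
        lines.append(f'Promoter {prom}(.Sequence("{gen.sequence()}"));')
    for rbs in ("rbs1", "rbs2", "rbs3"):
        lines.append(f'RBS {rbs}(.Sequence("{gen.sequence()}"));')
    for dna, protein in (("DNAlac", "LacI"), ("DNAtet", "TetR"), ("DNAara", "AraC")):
        lines.append(
            f'CodingDNA {dna}(.Sequence("{gen.sequence()}"), '
            f'.CorrespondingProtein("{protein}"));'
        )
    for term in ("term1", "term2", "term3"):
        lines.append(f'Terminator {term}(.Sequence("{gen.sequence()}"));')
    lines += [
        "Rule promoterToCoding1(araP BEFORE DNAlac);",
        "Rule promoterToCoding2(lacP BEFORE DNAtet);",
        "Rule promoterToCoding3(tetP BEFORE DNAara);",
        "Assert(promoterToCoding1 AND promoterToCoding2 AND promoterToCoding3);",
        f"Device Repressilator({', '.join(_REPRESSILATOR_ORDER)});",
    ]
    sources = {"repressilator.eug": "\n".join(lines) + "\n"}
    expected = {"components": 12, "order": list(_REPRESSILATOR_ORDER)}
    return FixtureProgram("repressilator", sources, {"main": "repressilator.eug"}, expected)


# ---------------------------------------------------------------------------
# Registry device (BBa_K112809)

_REGISTRY_PARTS = [
    # (type, name, extra dot-fields)
    ("Promoter", "BBa_I0500", ', .Inducible(true)'),
    ("ORF", "BBa_K112805", ", .CDS(true)"),
    ("ORF", "BBa_K112806", ", .CDS(true)"),
    ("Terminator", "BBa_B0010", ", .Strength([0.98])"),
    ("Terminator", "BBa_B0012", ", .Strength([0.84])"),
    ("Promoter", "BBa_J23116", ""),
    ("ORF", "BBa_K112807", ", .CDS(true)"),
]

_REGISTRY_DEVICE = (
    "Device BBa_K112809(Promoter BBa_I0500, ORF BBa_K112805, ORF BBa_K112806, "
    "Terminator BBa_B0010, Terminator BBa_B0012, Promoter BBa_J23116, "
    "ORF BBa_K112807, Terminator BBa_B0010);"
)


def build_registry_fixture(seed: int = DEFAULT_SEED) -> FixtureProgram:
    """Top-down construction of the T4 lysis device BBa_K112809: three
    header files carry the design library, the main file holds the single
    device declaration."""
    gen = SequenceGenerator(seed)
    prop_header = "\n".join([
        "Property ID(txt);",
        "Property Sequence(txt);",
        "Property Orientation(txt);",
        "Property CDS(boolean);",
        "Property Strength(num[]);",
        "Property Inducible(boolean);",
    ]) + "\n"
    part_header = "\n".join([
        "Part Promoter(ID, Sequence, Orientation, Inducible);",
        "Part ORF(ID, Sequence, Orientation, CDS);",
        "Part RBS(ID, Sequence, Orientation);",
        "Part Terminator(ID, Sequence, Orientation, Strength);",
    ]) + "\n"
    decls = []
    for part_type, name, extra in _REGISTRY_PARTS:
        sequence = J23116_SEQUENCE if name == "BBa_J23116" else gen.sequence()
        decls.append(
            f'{part_type} {name}(.ID("{name}"), .Sequence("{sequence}"), '
            f'.Orientation("Forward"){extra});'
        )
    main = "include PropertyDefinition.h, PartDefinition.h, PartDeclaration.h;\n" \
        + _REGISTRY_DEVICE + "\n"
    sources = {
        "PropertyDefinition.h": prop_header,
        "PartDefinition.h": part_header,
        "PartDeclaration.h": "\n".join(decls) + "\n",
        "BBa_K112809.eug": main,
    }
    expected = {
        "components": 8,
        "order": ["BBa_I0500", "BBa_K112805", "BBa_K112806", "BBa_B0010", "BBa_B0012",
                  "BBa_J23116", "BBa_K112807", "BBa_B0010"],
        "J23116_sequence": J23116_SEQUENCE,
    }
    return FixtureProgram("registry", sources, {"main": "BBa_K112809.eug"}, expected)


BUILDERS = {
    "registry": build_registry_fixture,
    "csd": build_csd_fixture,
    "pt": build_pt_fixture,
    "repressilator": build_repressilator_fixture,
}


def write_all_fixtures(directory: str | Path, seed: int = DEFAULT_SEED) -> list[Path]:
    """Regenerate every fixture program under ``directory`` (one
    subdirectory per fixture)."""
    directory = Path(directory)
    written = []
    for name, builder in BUILDERS.items():
        written.append(builder(seed).write(directory / name))
    return written
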