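"""Serialization of interpreter results.

Three interchange artifacts:

* an **XML netlist** -- the ordered component list of every device plus
  the property/part-type dictionaries, for downstream simulation tools;
* **flattened sequences** -- 5'->3' concatenation of leaf-part DNA, with
  reverse-complementation of parts whose ``Orientation`` is ``Reverse``,
  written as FASTA or annotated GenBank;
* **assembly-junction statistics** -- counts of adjacent part pairs,
  which determine physical assembly effort (a junction reused across
  devices only needs to be made once).

XML schema (stable; golden files in the test suite)::

    <run>
      <properties>  <property name=.. kind=../> ... </properties>
      <partTypes>   <partType name=..><property name=../>..</partType> ... </partTypes>
      <parts>       <part name=.. type=..><property name=.. kind=..>value</property>..</part> </parts>
      <devices>     <device name=.. [template=.. ordinal=..]>
                      <component name=.. type=../> ... </device> </devices>
    </run>

List-valued properties carry one ``<item>`` child per element.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import dataclass
from io import StringIO
from typing import Iterable

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import EugeneExportError
from .model import Device, PartDefinition, PartInstance, PrimitiveValue, PropertyDefinition
from .interpreter import InterpreterResult


# ---------------------------------------------------------------------------
# XML netlist


def _value_to_element(name: str, value: PrimitiveValue) -> ET.Element:
    el = ET.Element("property", name=name, kind=value.kind)
    if value.kind in ("txt[]", "num[]"):
        scalar = value.kind[:-2]
        for item in value.value:
            sub = ET.SubElement(el, "item")
            sub.text = _scalar_text(scalar, item)
    else:
        el.text = _scalar_text(value.kind, value.value)
    return el


def _scalar_text(kind: str, value) -> str:
    if kind == "boolean":
        return "true" if value else "false"
    return str(value)


def _device_element(device: Device) -> ET.Element:
    attrs = {"name": device.name}
    if device.provenance is not None:
        attrs["template"] = device.provenance[0]
        attrs["ordinal"] = str(device.provenance[1])
    el = ET.Element("device", **attrs)
    for comp in device.components:
        if isinstance(comp, Device):
            ET.SubElement(el, "component", name=comp.name, type="Device")
        else:
            ET.SubElement(el, "component", name=comp.name, type=comp.part_type)
    return el


def to_xml(result: InterpreterResult, include_spaces: bool = True) -> str:
    """Serialize the full interpreter state to the XML netlist format."""
    symbols = result.symbols
    root = ET.Element("run")
    props = ET.SubElement(root, "properties")
    for p in symbols.of_type(PropertyDefinition):
        ET.SubElement(props, "property", name=p.name, kind=p.kind)
    types = ET.SubElement(root, "partTypes")
    for t in symbols.of_type(PartDefinition):
        tel = ET.SubElement(types, "partType", name=t.name)
        for prop in t.property_names:
            ET.SubElement(tel, "property", name=prop)
    parts = ET.SubElement(root, "parts")
    for inst in symbols.of_type(PartInstance):
        pel = ET.SubElement(parts, "part", name=inst.name, type=inst.part_type)
        for prop, value in inst.values.items():
            pel.append(_value_to_element(prop, value))
    devices = ET.SubElement(root, "devices")
    for dev in symbols.of_type(Device):
        devices.append(_device_element(dev))
    if include_spaces:
        for space in result.design_spaces.values():
            for dev in space.devices:
                devices.append(_device_element(dev))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def from_xml(text: str) -> dict:
    """Parse a netlist document back into a structural dictionary
    (used for round-trip verification, not to rebuild interpreter state)."""
    root = ET.fromstring(text)

    def prop_value(el: ET.Element):
        kind = el.get("kind")
        items = el.findall("item")
        if kind in ("txt[]", "num[]"):
            return kind, tuple((item.text or "") for item in items)
        return kind, el.text or ""

    return {
        "properties": [
            (p.get("name"), p.get("kind")) for p in root.find("properties")
        ],
        "partTypes": [
            (t.get("name"), tuple(p.get("name") for p in t))
            for t in root.find("partTypes")
        ],
        "parts": [
            (
                p.get("name"),
                p.get("type"),
                {el.get("name"): prop_value(el) for el in p},
            )
            for p in root.find("parts")
        ],
        "devices": [
            (
                d.get("name"),
                tuple((c.get("name"), c.get("type")) for c in d),
            )
            for d in root.find("devices")
        ],
    }


# ---------------------------------------------------------------------------
# Flattened sequences


def flatten_sequence(device: Device) -> str:
    """Concatenate leaf-part sequences 5'->3'.

    A part whose ``Orientation`` is ``Reverse`` contributes the reverse
    complement of its ``Sequence``; unset orientation is treated as
    ``Forward``. A leaf without a set ``Sequence`` is an error naming the
    part.
    """
    chunks: list[str] = []
    for leaf in device.leaves():
        if not leaf.is_set("Sequence"):
            raise EugeneExportError(
                f"part {leaf.name!r} has no Sequence set; cannot flatten device {device.name!r}"
            )
        seq = str(leaf.get("Sequence").value)
        orientation = "Forward"
        if leaf.is_set("Orientation"):
            orientation = str(leaf.get("Orientation").value)
        if orientation == "Reverse":
            seq = str(Seq(seq).reverse_complement())
        elif orientation != "Forward":
            raise EugeneExportError(
                f"part {leaf.name!r} has Orientation {orientation!r}; "
                "expected 'Forward' or 'Reverse'"
            )
        chunks.append(seq)
    return "".join(chunks)


def _device_record(device: Device, with_features: bool) -> SeqRecord:
    seq = flatten_sequence(device)
    record = SeqRecord(Seq(seq), id=device.name, name=device.name[:16], description="")
    record.annotations["molecule_type"] = "DNA"
    if with_features:
        offset = 0
        for leaf in device.leaves():
            length = len(str(leaf.get("Sequence").value))
            strand = -1 if (
                leaf.is_set("Orientation") and leaf.get("Orientation").value == "Reverse"
            ) else 1
            record.features.append(
                SeqFeature(
                    FeatureLocation(offset, offset + length, strand=strand),
                    type="misc_feature",
                    qualifiers={"label": [leaf.name], "part_type": [leaf.part_type]},
                )
            )
            offset += length
    return record


def write_fasta(devices: Iterable[Device], handle_or_path) -> int:
    """Write flattened device sequences as FASTA; returns record count."""
    records = [_device_record(d, with_features=False) for d in devices]
    return SeqIO.write(records, handle_or_path, "fasta")


def write_genbank(devices: Iterable[Device], handle_or_path) -> int:
    """Write flattened device sequences as GenBank with one feature per
    leaf part (0-based half-open intervals converted to the format's
    1-based inclusive coordinates by the writer)."""
    records = [_device_record(d, with_features=True) for d in devices]
    return SeqIO.write(records, handle_or_path, "genbank")


def fasta_text(devices: Iterable[Device]) -> str:
    buf = StringIO()
    write_fasta(devices, buf)
    return buf.getvalue()


def genbank_text(devices: Iterable[Device]) -> str:
    buf = StringIO()
    write_genbank(devices, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Assembly junctions


@dataclass(frozen=True)
class JunctionStats:
    """Junction accounting over a set of devices.

    ``total`` counts every adjacent leaf pair (a k-part device has k-1);
    ``unique`` counts distinct ordered (left, right) part-name pairs --
    the number of junctions that physically need to be made.
    """

    total: int
    unique: int
    table: tuple[tuple[tuple[str, str], int], ...]  # lexicographically sorted

    def to_tsv(self) -> str:
        lines = ["left\tright\tcount"]
        for (left, right), count in self.table:
            lines.append(f"{left}\t{right}\t{count}")
        lines.append(f"# total\t{self.total}")
        lines.append(f"# unique\t{self.unique}")
        return "\n".join(lines) + "\n"


def junction_stats(devices: Iterable[Device]) -> JunctionStats:
    counter: Counter[tuple[str, str]] = Counter()
    total = 0
    for device in devices:
        names = [leaf.name for leaf in device.leaves()]
        for left, right in zip(names, names[1:]):
            counter[(left, right)] += 1
            total += 1
    table = tuple(sorted(counter.items()))
    return JunctionStats(total=total, unique=len(counter), table=table)
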