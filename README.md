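# eugene-dsl

An interpreter for **Eugene**, a declarative domain-specific language for
forward engineering of DNA-based devices. Eugene encapsulates the synthetic
biology abstraction hierarchy directly in its type system — DNA-level
information as typed **Properties**, non-reducible genetic elements
(promoters, RBSs, ORFs, terminators) as **Parts**, and 5′→3′-ordered
compositions of parts and sub-devices as **Devices** — and pairs it with a
combinatorial **design space exploration** workflow:

* **expansion** — `permute(D)` replaces each part slot of a template device
  with every declared instance of that slot's part type, enumerating the
  full cross product (a template with slot pools of sizes
  *k₁, …, kₘ* yields ∏ᵢ kᵢ devices, named `D_1 … D_N` in odometer order,
  3′-most slot fastest);
* **pruning** — named boolean **Rules** over part-instance presence
  (`CONTAINS x` / `NOTCONTAINS x`), order (`x BEFORE y`), co-occurrence
  (`x WITH y`, conditional: x present ⇒ y present; `x NOTWITH y`:
  ¬(x ∧ y)), and multiplicity (`x NOTMORETHAN n`, with `once` ≡ 1),
  composed with `AND`/`OR`. `Assert(R)` makes a rule a hard constraint —
  it filters permuted design spaces and halts the run if a concrete
  declared device violates it; `Note(R)` only emits warnings.

The package is aimed at genetic design automation work: specifying
composite BioBrick-style devices with reusable header libraries, carving
functional sub-spaces out of combinatorial part libraries, and exporting
the results (XML netlists for simulation tools, flattened FASTA/GenBank
sequences, assembly-junction statistics) for downstream assembly planning.

## A small worked example

```text
Property ID(txt);
Property Sequence(txt);
Part Promoter(ID, Sequence);
Part CDS(ID, Sequence);
Part Terminator(ID, Sequence);
Promoter pWeak(.ID("pWeak"), .Sequence("TTGACA"));
Promoter pStrong(.ID("pStrong"), .Sequence("TTTACA"));
CDS gfp(.ID("gfp"), .Sequence("ATGAGT"));
CDS rfp(.ID("rfp"), .Sequence("ATGGCT"));
Terminator t1(.ID("t1"), .Sequence("TTATT"));
Device Reporter(pWeak, gfp, t1);
permute(Reporter);
Rule NoRfp(NOTCONTAINS rfp);
Assert(NoRfp);
print(Reporter_1);
print(Reporter_3);
```

```sh
$ eugene run demo.eug --stats report.tsv
Device Reporter_1(pWeak, gfp, t1)
Device Reporter_3(pStrong, gfp, t1)
```

`permute(Reporter)` enumerates 2 × 2 × 1 = 4 devices; asserting `NoRfp`
silently removes the two containing `rfp`. Survivors keep their
unconstrained ordinals, so the second surviving device is still
`Reporter_3`. The stats table records the pruning:

```text
template	rule	removed	remaining
Reporter	NoRfp	2	2
```

The same pipeline is available as a library:

```python
from eugene import run_file, export
result = run_file("demo.eug")
print(len(result.surviving_devices()))          # 2
print(export.flatten_sequence(result.symbols.lookup("Reporter")))
```

## Case-study programs

`eugene.fixtures` regenerates four complete case-study programs
(`eugene fixtures --out DIR`), with seeded synthetic part sequences:

* **registry** — top-down specification of a T4 lysis device
  (`BBa_K112809`, 8 parts) across three header files plus a one-line main
  program;
* **csd** — cell-surface-display design-space exploration: 6 passenger ×
  5 spacer × 15 displayer × 1 terminator libraries, two templates
  expanding to 540 devices, and a staged rule ladder pruning to 135, 90,
  61, 16 and finally 3 devices;
* **pt** — combinatorial protein tagging: 31 basic parts, four
  bi-cistronic topologies (2304 devices), tag-exclusion rules (2112),
  projecting to 528 distinct per-cistron (ORF, tag) assignments whose
  representatives carry 3696 part-part junctions;
* **repressilator** — a lac-tet-ara oscillator as a single 12-component
  device with `BEFORE` ordering rules asserted on it.

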