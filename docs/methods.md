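# Methods

This note documents the language semantics the interpreter implements,
the parameters and conventions that matter, what the fixture programs
emulate, and the design choices made where the language definition left
room.

## Language model

A program is a sequence of `;`-terminated statements executed top to
bottom in a **single global namespace**: property definitions, part
definitions, part declarations, device declarations, rules, primitive
variables, and permuted design spaces all share it, every name must be
defined before use, and redefinition is an error. Identifiers are
case-sensitive and consist of letters, digits and underscores, not
starting with a digit; comments run from `//` to end of line.

Primitives are `txt`, `num` (one numeric kind holding integers and
decimals exactly as parsed, no silent truncation), `boolean`, and the
arrays `txt[]`/`num[]` with 0-based indexing. A part instance may be
declared positionally (`Promoter P1(1, "TATATA", 30)`, values mapped by
the part definition's property order), by dot-field
(`.Sequence("...")`), or empty (`Promoter araP();`). Unassigned
properties are **unset** — a distinct state, not an empty/zero value —
because partially characterized parts are the norm in part libraries.
Type annotations in device declarations (`Device D(Promoter P1, ...)`)
are checked when present and may be omitted.

## Rule semantics

Rules name part *instances*, never part definitions. The operator truth
table, evaluated against a device's flattened (sub-devices expanded)
5′→3′ leaf list:

| expression | true iff |
|---|---|
| `CONTAINS x` | x occurs |
| `NOTCONTAINS x` | x does not occur |
| `x BEFORE y` | first occurrence of x precedes first of y; vacuous if either absent |
| `x WITH y` | x present ⇒ y present (vacuous when x absent) |
| `x NOTWITH y` | not (x present and y present) |
| `x NOTMORETHAN n` | x occurs ≤ n times (`once` = 1) |

`AND` binds tighter than `OR`, both left-associative, parentheses
honored (published rule listings parenthesize every mixed use, so
precedence is unobservable in them). The **conditional** reading of
`WITH` is forced by the staged pruning counts of the cell-surface-display
study: selector rules like
`(PassStrep WITH Disp_CPG6) OR (PassStrep WITH Disp_AIDA)` must leave
non-PassStrep devices untouched. Under the alternative symmetric
"both present" reading the final 16 → 3 pruning step yields 0 survivors
(the test suite carries this discriminating check). `BEFORE` on a
multiply-occurring instance compares first occurrences — a choice, since
no listing disambiguates it.

### Assert and Note

`Assert(R1 AND R2 ...)` turns declared rules into hard constraints, each
asserted at most once. Asserting:

1. immediately checks each rule against every **concrete** declared
   device (scoped rules such as `Rule R2(BBa_1 CONTAINS P1)` check only
   their named device); a violation halts the run;
2. prunes every existing design space, silently;
3. constrains later `permute` calls and hard-checks devices declared
   later, at declaration time.

A device that has been permuted is exempt from the hard check: it is a
*template* — a generator of its design space, not a design commitment —
and asserted rules filter its space instead. Without this distinction
the cell-surface-display program would be self-contradictory (its
type-1 template pairs PassNeedle with SpacerINP, a combination its own
rule ladder forbids). `Note(R)` evaluates at the same points but only
appends warnings (`"R violated by D"`), which the CLI prints to standard
error; noted devices are never removed.

Pruning removes a device iff it violates any asserted rule, so the
surviving set is order-independent, and pruning is idempotent. For
reporting, each removed device is attributed to the *first* violated
rule in assertion order, which reproduces sequential per-rule removal
accounting (the `--stats` table).

## permute

Slot pools are the registered instances of each slot's part type, in
declaration order; enumeration is odometer order with the 3′-most slot
varying fastest, so ordinals and golden files are reproducible.
Generated devices are named `Template_k`, 1-based, bound lazily: the
symbol table resolves `Template_k` against the design space on
reference, and surviving ordinals keep their unconstrained values after
pruning (`Reporter_3` stays `Reporter_3` even when `Reporter_2` is
pruned away). Sub-device slots are fixed (only part slots are
substituted); repeated slots of the same type vary independently — the
protein-tagging topologies need both conventions (a shared cleavage-site
instance in two slots; two independently varying tag slots of one type).
Enumeration is materialized eagerly; at the case-study scales (≤ 2304
devices) memory is trivial.

## Exporters

* **XML netlist** (root `run`, children `properties` / `partTypes` /
  `parts` / `devices`; one `device` element with ordered `component`
  children, `template`/`ordinal` attributes for generated devices;
  list-valued properties as `item` children). The schema is this
  package's own — stability is promised by the round-trip tests and the
  shipped fixture outputs, and `export.from_xml` gives a structural
  parse for verification.
* **Flattened sequences** — 5′→3′ concatenation of leaf `Sequence`
  properties; a part with `Orientation` = `Reverse` contributes its
  reverse complement; unset orientation is treated as `Forward`; an
  unset `Sequence` is an error naming the part. FASTA records use the
  device name as id; GenBank output adds one feature per leaf part over
  its half-open 0-based interval (converted by the writer to the
  format's 1-based inclusive coordinates).
* **Junction statistics** — junction identity is the *ordered pair of
  part-instance names* (not sequences), matching how assembly effort is
  counted: a k-part device has k−1 junctions, and a junction reused
  across devices is only made once, so `total` and `unique` are the two
  quantities of interest.

## Fixture programs: what they emulate, and what they do not

The four case-study programs are reconstructions from published
listings, not copies of wet-lab data:

* Library sizes are fixed by simultaneous consistency with every printed
  count. Cell-surface display: 6 passengers, 5 spacers, 15 displayers,
  1 terminator — the only sizes consistent with 540 = 6·5·15 + 6·15 and
  with every per-rule removal (90/90/90/75/60/45/15/11/3) down the
  135 → 90 → 61 → 16 → 3 ladder. Protein tagging: 31 basic parts as
  1 promoter + 12 nTags + 12 cTags + 1 cleavage site + 2 OS ORFs +
  2 RSO ORFs + 1 terminator, the only split reaching 2304 = 4·(12²·2²).
* Only 7 of the 15 displayers are named in the listings; the rest are
  synthetic placeholders (`Disp_s08`–`Disp_s15`). Hyphenated published
  part names are normalized to underscores (`SpacerGly_Ser`), since `-`
  is not an identifier character.
* Part DNA is synthetic: uniform random over {A,C,G,T}, lengths 20–60 bp
  (typical of the short functional elements involved), drawn from a
  per-fixture seed (default 42 for the shipped copies, which the test
  suite verifies byte-for-byte against regeneration). One real sequence
  is embedded: the 41-bp promoter BBa_J23116. Consequently sequence-level
  outputs (FASTA/GenBank, junction tables keyed by name) are structurally
  faithful but biologically meaningless; passing tests validate the
  combinatorial and rule semantics, not any wet-lab property.
* The protein-tagging projection to "distinct tag assignments" reads
  each device's two cistrons 5′→3′ and keys on the parts' `ID` property
  — `Ab01…Ab12` shared by the nTag/cTag forms of an antibody, `ORF1/ORF2`
  shared by the OS/RSO forms of an ORF — so terminus and topology are
  ignored. This yields 528 groups of exactly 4 (one per topology);
  528 × 7 = 3696 total junctions over one representative per group.
  Representatives are chosen deterministically (smallest
  (template, ordinal)); the published *unique*-junction figure depends on
  which physical representative was built per group, a selection not
  recoverable from the listings, so only the junction invariants are
  asserted, not a unique count.
* The repressilator program asserts its three promoter-before-ORF rules
  *before* declaring the device, exercising declaration-time checking;
  its regulatory behavior (simulation) is out of scope — only the
  netlist handoff is implemented.

## Numerical and degenerate-input choices

No arithmetic exists beyond literals, 0-based indexing, and assignment.
Degenerate inputs: an empty program yields an empty netlist; `permute`
of a slot with an empty pool is an error (not an empty space); an empty
`Assert` batch is impossible syntactically; pruning with no rules is the
identity; a device may reference the same instance in several slots
(required by the topologies), but may not contain itself directly or
transitively. `print` renders parts as `Type name(prop=value, ...)`
with unset properties omitted — an output format this package defines.

## Known limitations

Control flow (loops, conditionals), user-defined functions and variable
scoping, definition-scoped rules (constraints over all instances of a
part type), rules spanning multiple devices, a System level above
Device, and direct database connectivity are all out of scope. Header
files are ordinary source fragments; `include` splices them (each file
once, cycles rejected) with search order: including file's directory,
then user-supplied include paths.
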