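# brickmatch

Template-brick pattern matching, annotation and template-based construction
for SBGN Process Description (PD) maps.

Molecular network diagrams drawn in SBGN contain recurring higher-order
motifs — protein phosphorylations, catalysed metabolic reactions,
translocations, complex formations. `brickmatch` represents each such
concept as a **template brick**: a small SBGN pattern whose glyph labels are
written in a pattern language, organised together with GO/SBO/BKO terms in
a miniature **Bricks Ontology**. A brick can be used in both directions:

* **matching** — find every concrete occurrence (*instance brick*) of the
  pattern in a real PD map, and annotate the map with the biological terms
  the matched bricks represent;
* **construction** — generate a concrete map fragment from a brick by
  supplying variable bindings and repetition counts.

It is intended for curators and tool builders who need a semantic layer on
top of SBGN-ML files: counting which concepts a pathway map contains,
extracting each occurrence as a standalone submap, flagging events that are
only covered by generic patterns (candidate misrepresentations or missing
ontology terms), and checking a stored brick hierarchy against matcher
semantics.

## The formalism in brief

A template brick is a PD map whose glyph labels may contain:

| construct | example | matches |
|---|---|---|
| literal | `ERK` | exactly `ERK` (case-sensitive) |
| variable | `$LABEL$` | any non-empty string; all occurrences of one variable must bind the same string |
| optional | `P[@$RES$]` | `P` or `P@S221` (binding `RES = S221`) |
| disjunction | `cell—CELL` (or `cell\|CELL`) | `cell` or `CELL` |
| repetition | `{$SUBSTRATE_N$}` | whole glyph: greedily all remaining same-role glyphs, and no unmatched glyph with that role may remain |
| absence | `!ATP!` | whole glyph: no matching glyph may occupy that role |

Every plain template glyph must map to a *distinct* instance glyph of a
compatible class. Generic template glyphs generalise: the process glyph
matches every stoichiometric process class, the unspecified-entity glyph
matches every entity pool, and modulation arcs follow the hierarchy
modulation ⊇ {stimulation, inhibition} with stimulation ⊇ {catalysis,
necessary stimulation}. The macromolecule glyph matches only instances not
decorated with a material type other than `mt:prot`. Matches are then
**completed**: decorating auxiliary units, containing compartments, and all
consumption/production participants of matched processes are pulled in
recursively, so a phosphorylation instance includes its ATP/ADP even though
the template never mentions them. Two matches completing to the same
element set are one instance.

Bricks are associated with ontology terms through `main` / `narrow` /
`alternate` (plus `synonym` and `broad` for AF/ER bricks), and brick
subsumption (A ⊑ B iff every instance matched by A is matched by B) is both
recorded in the library and verifiable empirically.

## Worked example

```sh
$ brickmatch fixtures --name fig1 --out fig1.sbgn
wrote fig1.sbgn
$ brickmatch match --brick BKO:0000440 --map fig1.sbgn
BKO:0000440 matches 3 instance(s) in fig1
  [1] 8 elements  (LABEL=IRS1-4)
  [2] 12 elements  (LABEL=RSK, RES=S221)
  [3] 8 elements  (LABEL=c-Fos)
$ brickmatch annotate --map fig1.sbgn
map fig1: 19 instance(s)
  BKO:0000059  modulatory activity: 3
  BKO:0000075  stimulatory activity: 4
  BKO:0000438  protein phosphorylation: 3
  BKO:0000920  irreversible process: 4
  GO:0003824  catalytic activity: 2
  GO:0004672  protein kinase activity: 2
  SBO:0000177  non-covalent binding: 1
  generic-only instances: 5
```

The fixture is an Insulin/IGF signalling excerpt: the protein-phosphorylation
brick (BKO:0000440) finds the three phosphorylation events (of IRS1-4, of
RSK at residue S221 — note the variable binding — and of c-Fos); the second
instance has 12 elements because completion pulled in the ATP/ADP couple
with its arcs.
Annotation also reports, e.g., two protein-kinase activities (ERK and the
IGF/IGFR complex catalysing phosphorylations) and five generic-only
instances — events matched by a generic brick with no more specific brick
covering them, such as the stimulation of the c-Fos phosphorylation by RSK.

Template-based construction runs the other way:

```sh
$ brickmatch instantiate --brick BKO:0000440 --bind LABEL=RSK --bind RES=S221 --out rsk.sbgn
wrote rsk.sbgn (5 glyphs, 2 arcs)
```

Exit codes: 0 success, 1 usage error (unknown brick, AF map passed to the
PD matcher), 2 data error (malformed SBGN-ML, inconsistent library).

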