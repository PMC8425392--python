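# Methods

This note documents the semantics implemented by `brickmatch`, the choices
made where the formalism is genuinely open, and what the synthetic test-bed
does and does not establish.

## Map model and SBGN-ML handling

The in-memory model keeps only semantic content: glyph classes, labels,
state-variable value/variable pairs, containment (compartment references,
complex/decoration parent links), clone flags and arcs. Geometry is never
read into the model and is synthesized deterministically on write; this is
a hard design constraint, because matching must not depend on layout — the
only spatial facts that matter are the qualitative ones (inside a
compartment, decorating a glyph, subunit of a complex), and those are
modelled as references.

Reading accepts the SBGN-ML 0.2 and 0.3 namespaces; writing emits 0.2 with
elements sorted by id, so serialization is byte-stable and suitable for
snapshot comparison. Two normalisations happen at read time:

* ports are resolved to their owning glyph (the model has no port type; the
  writer emits arcs glyph-to-glyph, which is schema-valid in 0.2);
* consumption/production arcs drawn in the reverse orientation are flipped
  so that consumption always targets, and production always sources, the
  process. The matcher then reasons about a single orientation.

Compartment containment is taken from `compartmentRef` only; bounding boxes
are never used as a fallback, so maps without compartment references simply
contribute no containment facts. Glyphs nested inside a submap are retained
but flagged: a submap is an opaque single node to the matcher. Documents
declaring PD but using AF/ER classes are rejected with a language-mismatch
diagnostic distinct from the unknown-class error.

## Label pattern language

Patterns are parsed into an AST of literals, variables, optional groups and
two-literal disjunctions, with whole-label repetition (`{…}`) and absence
(`!…!`) modifiers. Decisions worth recording:

* **All solutions, not greedy.** `match_label` returns every binding under
  which the pattern consumes the text. Greediness belongs to glyph-set
  repetition (handled in the matcher), not to label matching; returning all
  label solutions is what keeps cross-glyph variable consistency complete
  (a greedy-only matcher would miss matches where an earlier glyph must
  take the shorter of two possible bindings).
* **Variables bind non-empty strings.** A slot that should also accept an
  empty label is written as an optional variable `[$X$]` — the bundled
  generic bricks use this for entity pools, since e.g. empty-set glyphs are
  unlabeled.
* **Case-sensitive, whitespace-exact.** The disjunction construct exists
  precisely because case matters (`cell—CELL`); no Unicode folding is done.
* **Disjunction spelling.** The typographic em dash and `|` are accepted as
  equivalents on input; `|` is canonical on output, because em dashes in
  hand-edited JSON are fragile.
* **No escaping.** Delimiter characters cannot occur literally inside
  patterns; a library file using them in pattern position fails to load.
  Instance labels, by contrast, are arbitrary strings.

An independent segmentation oracle (enumerate every way to cut the text
into as many parts as the flattened pattern has units) backs the matcher in
the test suite.

## Matching semantics

A match assigns every plain template glyph to a distinct instance glyph
(injectivity is what lets two same-labelled template glyphs force two
different pools — and, for the translocation brick, what forces the source
and destination compartments to differ). Constraints:

* **Class compatibility with generalisation.** A template glyph matches its
  own class plus descendants: the process glyph matches every
  stoichiometric process class but never phenotype; the unspecified-entity
  glyph matches every entity-pool class including multimers and the empty
  set; multimer template glyphs require the same multimer class. The
  macromolecule template glyph rejects instances carrying a
  material-type unit of information other than `mt:prot`, reflecting the
  convention that a bare macromolecule stands for a protein pool.
* **Arc compatibility.** Reflexive plus the modulation hierarchy
  (modulation accepts all five modulation-kind classes; stimulation accepts
  catalysis and necessary stimulation). Template arcs map injectively to
  instance arcs between the images of their endpoints.
* **Containment.** Template parent links and compartment references must map
  onto the instance ones. A template glyph with no compartment reference
  matches glyphs in any compartment or none.
* **States.** A template state variable carries two patterns (value,
  variable) matched against the instance state fields; an instance state
  variable with no value matches the empty value pattern — this is how one
  brick matches both the unphosphorylated (empty state) and phosphorylated
  (`P`/`P@S221`) forms.
* **Roles and negative constructs.** The role of a repetition/absence glyph
  is derived from its single anchor in the template: reactant-of,
  product-of, modulator-of (with arc class), subunit-of, or decoration-of.
  A repetition glyph greedily binds *all* remaining compatible glyphs in
  its role at the anchor's image; if an unmatched, incompatible glyph
  remains in that role the match fails (exclusivity). An absence glyph
  fails the match if any compatible glyph occupies its role. Variables
  local to a negative construct bind per candidate glyph and do not
  propagate (one `{$SUBSTRATE_N$}` matches several differently-labelled
  chemicals); globally bound variables are respected. Glyphs already
  matched by other template glyphs are not candidates for negative
  constructs — negation is about *unaccounted-for* glyphs in a role.
* **Clone markers** are ignored: cloning is a layout device, not a semantic
  distinction between pools.

**Completion.** Matched cores are closed recursively under three rules: add
auxiliary units decorating an included glyph (never complex subunits), add
the containing compartment, and for process-kind glyphs add every
consumption/production participant together with the arc. Completion is a
least fixpoint, hence idempotent. Modulators are deliberately *not* pulled
in: a phosphorylation instance includes its ATP, not its kinase — the
kinase belongs to the kinase-activity instance.

**Instance identity** is (brick id, completed element set). This makes
counts well defined when participants are interchangeable: a generic
process brick maps its reactant slot onto any of three substrates, but all
nine assignments complete to the same element set and count once.

**Search strategy.** Backtracking over plain template glyphs ordered by
ascending candidate-list size, with binding branching on label/state
solutions and constraint checks at each extension; negative constructs are
evaluated last. This is engineering, not semantics: correctness is defined
by (and tested against) an exhaustive oracle that enumerates every
injective assignment.

**Overlap.** Instances are independent matches; two instances may share
glyphs (a kinase-activity instance contains a phosphorylation instance),
and no cross-instance exclusion is applied.

## Template-based construction and subsumption

`instantiate` renders one glyph per plain template glyph, expands each
repetition glyph to *k* copies whose variables are looked up with suffixes
`_1…_k`, and skips absence glyphs. The round trip — every instantiation is
re-matched by its source brick — holds for all bundled bricks and is
enforced by tests.

`infer_subsumption(a, b)` tests whether b matches the canonical
instantiations of a (optionals all kept and all dropped × repetition counts
all 0 and all 2, fresh distinct literals per variable). It is sound but
incomplete: `subsumes` means b matched every variant; a variant matched by
a but not b is a concrete counterexample (`not-subsumes`); anything else is
`unknown`. The library's recorded pairs are additionally verified against
the matcher on every fixture map with the containment criterion: for each
A-instance there must be a B-instance whose elements are a subset — equality
is deliberately not required, since a specific instance may legitimately
span more elements (the enzyme and its catalysis arc) than the generic
instance of the same event.

## The bundled library

Eighteen terms and eighteen bricks covering phosphorylation, kinase
activity, metabolic catalysis, translation (canonical and an
mRNA-consuming variant kept for annotation compatibility, related by
`main`/`alternate`), translocation, influx, passive transport, one AF brick
(data-model only — matching is PD-only), and the generic set: irreversible
and reversible process, modulatory/stimulatory/inhibitory activity,
binding, stimulation of a phenotype, and the two catalytic-activity bricks.
Encoding choices that carry semantics:

* generic entity-pool slots are optional variables (`[$REACTANT$]`) so that
  unlabeled pools match;
* the reversible-process bricks pair two production arcs with an absence
  glyph `![$ANY$]!` in the reactant role — in PD a reversible process has
  production arcs on both sides and *no* consumption arc, and without the
  negative constraint the brick would match any irreversible process with
  two products;
* the translocation brick carries two compartment template glyphs, so
  injectivity forces an actual compartment change; influx and passive
  transport leave the source pool compartment-free (flux from an
  unrepresented outside) and are therefore not recorded as subclasses of
  translocation;
* the stimulatory-activity term keeps BKO:0000003 as an alternate id of
  BKO:0000075 (two printings exist in the source material for this term).

GO biological-process descendants are excluded from the term set by design
(a phenotype glyph with a free label covers them); leaf terms must carry at
least one brick unless explicitly marked unrepresentable.

The generic-only computation compares instances by *focal element* (the
process glyph for process-kind bricks, the matched modulation arc for
activity-kind bricks) rather than by whole element sets, for the same
reason as the subsumption check; "more specific" bricks are the non-generic
subclasses of the generic brick in question, so an event matched by two
generic bricks at once still counts as generic-only.

## Synthetic test-bed

`random_pd_map` plants brick instantiations with unique random labels
(4–8 lowercase letters, disjoint from reserved literals like `ATP`),
repetition counts 0–2, and optionals kept with probability ½ — small
instances because each planted instance is an independent unit and recall
is per instance. Decoys break exactly one rule each: a required arc class
replaced by an incompatible one, a forbidden `mt:psac` material type, one
occurrence of a shared variable relabelled, an extra same-role participant
against an exclusivity constraint, or the glyph an absence construct
forbids. Recall/precision are measured per brick with single-brick pools,
because a decoy for one brick may legitimately be matched by a more generic
brick.

What this does *not* show: real curated maps contain typos, style drift
(e.g. phosphorylation states written into labels), CellDesigner conversion
artefacts and much larger connected components. The generator demonstrates
correctness of the matching semantics, not robustness to curation noise;
the generic-only report is exactly the tool meant for triaging such noise
on real maps.

## Problem sizes and numerical choices

The test suite runs the matcher against the exhaustive oracle on 500 seeded
maps of roughly 6–14 glyphs (the oracle's cost grows factorially, the
production matcher's does not), recall/precision over 100 seeded maps, and
100 instantiation round trips; the acceptance script repeats these at
100/60/100 with the seed taken from the command line. All randomness flows
through explicit `random.Random(seed)` instances; there are no tolerances
anywhere — every compared quantity is discrete.

## Known limitations

* Matching is PD-only; AF/ER bricks are representable in the library but
  rejected by the matcher.
* Subsumption inference is incomplete by construction (canonical variants
  only); `unknown` is a possible honest answer.
* Repetition/absence glyphs must be role-anchored to exactly one plain
  template glyph; free-floating negation is rejected at library load.
* The library dialect is JSON, not OWL; no reasoner integration is
  provided, and no Cypher/graph-database export exists.
* Logic operators (and/or/not) and equivalence-arc semantics are outside
  the supported PD subset; documents using unsupported classes are rejected
  rather than silently ignored.
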