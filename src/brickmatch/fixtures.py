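"""Synthetic PD maps: figure transcriptions and seeded random maps.

``figure_fixture`` returns hand-transcribed worked examples (an Insulin/IGF
signalling map with a submap hiding the MAPK cascade, translation variants,
translocation/influx/transport examples, a multi-substrate metabolic
reaction). Only semantically relevant content is transcribed — classes,
labels, states, arcs and containment; geometry is synthesized on write.

``random_pd_map`` plants ground-truthed brick instantiations (and optional
near-miss decoys) into one map, deterministically in the seed, so matcher
recall and precision can be measured against a known truth.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import UsageError
from .matching import instantiate, required_variables
from .ontology import BrickOntology, TemplateBrick, default_library
from .patterns import Modifier
from .sbgn import (
    Arc,
    ArcClass,
    Glyph,
    GlyphClass,
    Language,
    SbgnMap,
    StateValue,
)


@dataclass(frozen=True)
class PlantRecord:
    """Ground truth for one planted instance."""

    brick: str
    bindings: Mapping[str, str]
    elements: frozenset[str]


# ---------------------------------------------------------------------------
# Figure fixtures
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self, map_id: str):
        self.map = SbgnMap(language=Language.PD, id=map_id)

    def glyph(self, gid, cls, label="", state=None, compartment=None, parent=None):
        self.map.add_glyph(
            Glyph(
                id=gid,
                cls=cls,
                label=label,
                state=state,
                compartment_ref=compartment,
                parent=parent,
            )
        )
        return gid

    def sv(self, gid, parent, value="", variable=""):
        return self.glyph(
            gid,
            GlyphClass.STATE_VARIABLE,
            state=StateValue(value=value, variable=variable),
            parent=parent,
        )

    def arc(self, aid, cls, source, target):
        self.map.add_arc(Arc(id=aid, cls=cls, source=source, target=target))

    def done(self) -> SbgnMap:
        self.map.validate()
        return self.map


def _fig1() -> SbgnMap:
    """Insulin/IGF pathway excerpt: ligand binding, three phosphorylations
    (two catalysed), a submap hiding the MAPK cascade, and a phenotype."""
    b = _Builder("fig1")
    G, A = GlyphClass, ArcClass
    b.glyph("extracellular", G.COMPARTMENT, "extracellular")
    b.glyph("cytosol", G.COMPARTMENT, "cytosol")
    b.glyph("nucleus", G.COMPARTMENT, "nucleus")
    # ligand binding: IGF + IGFR -> IGF/IGFR
    b.glyph("igf", G.MACROMOLECULE, "IGF", compartment="extracellular")
    b.glyph("igfr", G.MACROMOLECULE, "IGFR", compartment="extracellular")
    b.glyph("assoc1", G.ASSOCIATION)
    b.glyph("cplx", G.COMPLEX, "IGF/IGFR", compartment="extracellular")
    b.arc("a_igf", A.CONSUMPTION, "igf", "assoc1")
    b.arc("a_igfr", A.CONSUMPTION, "igfr", "assoc1")
    b.arc("a_cplx", A.PRODUCTION, "assoc1", "cplx")
    # phosphorylation of IRS1-4, catalysed by the receptor complex
    b.glyph("irs", G.MACROMOLECULE, "IRS1-4", compartment="cytosol")
    b.sv("irs_sv", "irs")
    b.glyph("irs_p", G.MACROMOLECULE, "IRS1-4", compartment="cytosol")
    b.sv("irs_p_sv", "irs_p", value="P")
    b.glyph("p1", G.PROCESS)
    b.arc("a_p1_cons", A.CONSUMPTION, "irs", "p1")
    b.arc("a_p1_prod", A.PRODUCTION, "p1", "irs_p")
    b.arc("a_p1_cat", A.CATALYSIS, "cplx", "p1")
    # the MAPK cascade is hidden inside a submap; its content is retained in
    # the model but opaque to matching
    b.glyph("mapk_sm", G.SUBMAP, "MAPK cascade", compartment="cytosol")
    b.glyph("sm_raf", G.MACROMOLECULE, "RAF", parent="mapk_sm")
    b.glyph("sm_mek", G.MACROMOLECULE, "MEK", parent="mapk_sm")
    b.sv("sm_mek_sv", "sm_mek")
    b.glyph("sm_mek_p", G.MACROMOLECULE, "MEK", parent="mapk_sm")
    b.sv("sm_mek_p_sv", "sm_mek_p", value="P")
    b.glyph("sm_p", G.PROCESS, parent="mapk_sm")
    b.arc("a_sm_cons", A.CONSUMPTION, "sm_mek", "sm_p")
    b.arc("a_sm_prod", A.PRODUCTION, "sm_p", "sm_mek_p")
    b.arc("a_sm_cat", A.CATALYSIS, "sm_raf", "sm_p")
    b.arc("a_stim_sm", A.STIMULATION, "irs_p", "mapk_sm")
    # phosphorylation of RSK, catalysed by ERK, consuming ATP
    b.glyph("erk", G.MACROMOLECULE, "ERK", compartment="cytosol")
    b.glyph("rsk", G.MACROMOLECULE, "RSK", compartment="cytosol")
    b.sv("rsk_sv", "rsk")
    b.glyph("rsk_p", G.MACROMOLECULE, "RSK", compartment="cytosol")
    b.sv("rsk_p_sv", "rsk_p", value="P", variable="S221")
    b.glyph("atp", G.SIMPLE_CHEMICAL, "ATP", compartment="cytosol")
    b.glyph("adp", G.SIMPLE_CHEMICAL, "ADP", compartment="cytosol")
    b.glyph("p2", G.PROCESS)
    b.arc("a_p2_cons", A.CONSUMPTION, "rsk", "p2")
    b.arc("a_p2_prod", A.PRODUCTION, "p2", "rsk_p")
    b.arc("a_p2_cat", A.CATALYSIS, "erk", "p2")
    b.arc("a_p2_atp", A.CONSUMPTION, "atp", "p2")
    b.arc("a_p2_adp", A.PRODUCTION, "p2", "adp")
    b.arc("a_stim_p2", A.STIMULATION, "mapk_sm", "p2")
    # phosphorylation of c-Fos, stimulated (not catalysed) by RSK-P
    b.glyph("cfos", G.MACROMOLECULE, "c-Fos", compartment="nucleus")
    b.sv("cfos_sv", "cfos")
    b.glyph("cfos_p", G.MACROMOLECULE, "c-Fos", compartment="nucleus")
    b.sv("cfos_p_sv", "cfos_p", value="P")
    b.glyph("p3", G.PROCESS)
    b.arc("a_p3_cons", A.CONSUMPTION, "cfos", "p3")
    b.arc("a_p3_prod", A.PRODUCTION, "p3", "cfos_p")
    b.arc("a_p3_stim", A.STIMULATION, "rsk_p", "p3")
    # proliferation phenotype
    b.glyph("phen", G.PHENOTYPE, "proliferation", compartment="nucleus")
    b.arc("a_phen", A.STIMULATION, "cfos_p", "phen")
    return b.done()


def _fig5a() -> SbgnMap:
    """Translation drawn canonically: mRNA necessarily stimulates production
    of the protein from an empty set."""
    b = _Builder("fig5a")
    G, A = GlyphClass, ArcClass
    b.glyph("mrna", G.NUCLEIC_ACID_FEATURE, "TP53")
    b.glyph("mrna_ct", G.UNIT_OF_INFORMATION, "ct:mRNA", parent="mrna")
    b.glyph("src", G.SOURCE_AND_SINK)
    b.glyph("prot", G.MACROMOLECULE, "TP53")
    b.glyph("p", G.PROCESS)
    b.arc("a_nec", A.NECESSARY_STIMULATION, "mrna", "p")
    b.arc("a_cons", A.CONSUMPTION, "src", "p")
    b.arc("a_prod", A.PRODUCTION, "p", "prot")
    return b.done()


def _fig5c() -> SbgnMap:
    """Translation in the mRNA-consuming style of CellDesigner imports."""
    b = _Builder("fig5c")
    G, A = GlyphClass, ArcClass
    b.glyph("mrna", G.NUCLEIC_ACID_FEATURE, "TP53")
    b.glyph("mrna_ct", G.UNIT_OF_INFORMATION, "ct:mRNA", parent="mrna")
    b.glyph("prot", G.MACROMOLECULE, "TP53")
    b.glyph("p", G.PROCESS)
    b.arc("a_cons", A.CONSUMPTION, "mrna", "p")
    b.arc("a_prod", A.PRODUCTION, "p", "prot")
    return b.done()


def _fig9b() -> SbgnMap:
    """Two translocations into the nucleus: one with a consistent entity
    label (ERK/ERK, matched) and one with inconsistent labels
    (ERK-cyt/ERK-nuc, not matched)."""
    b = _Builder("fig9b")
    G, A = GlyphClass, ArcClass
    b.glyph("cytosol", G.COMPARTMENT, "cytosol")
    b.glyph("nucleus", G.COMPARTMENT, "nucleus")
    b.glyph("erk_c", G.UNSPECIFIED_ENTITY, "ERK", compartment="cytosol")
    b.glyph("erk_n", G.UNSPECIFIED_ENTITY, "ERK", compartment="nucleus")
    b.glyph("p_top", G.PROCESS)
    b.arc("a_top_cons", A.CONSUMPTION, "erk_c", "p_top")
    b.arc("a_top_prod", A.PRODUCTION, "p_top", "erk_n")
    b.glyph("erkcyt", G.UNSPECIFIED_ENTITY, "ERK-cyt", compartment="cytosol")
    b.glyph("erknuc", G.UNSPECIFIED_ENTITY, "ERK-nuc", compartment="nucleus")
    b.glyph("p_bot", G.PROCESS)
    b.arc("a_bot_cons", A.CONSUMPTION, "erkcyt", "p_bot")
    b.arc("a_bot_prod", A.PRODUCTION, "p_bot", "erknuc")
    return b.done()


def _fig9c() -> SbgnMap:
    """RSK phosphorylation twice: plain state value P, and P at residue S221."""
    b = _Builder("fig9c")
    G, A = GlyphClass, ArcClass
    b.glyph("rsk1", G.MACROMOLECULE, "RSK")
    b.sv("rsk1_sv", "rsk1")
    b.glyph("rsk1_p", G.MACROMOLECULE, "RSK")
    b.sv("rsk1_p_sv", "rsk1_p", value="P")
    b.glyph("p_top", G.PROCESS)
    b.arc("a_top_cons", A.CONSUMPTION, "rsk1", "p_top")
    b.arc("a_top_prod", A.PRODUCTION, "p_top", "rsk1_p")
    b.glyph("rsk2", G.MACROMOLECULE, "RSK")
    b.sv("rsk2_sv", "rsk2")
    b.glyph("rsk2_p", G.MACROMOLECULE, "RSK")
    b.sv("rsk2_p_sv", "rsk2_p", value="P", variable="S221")
    b.glyph("p_bot", G.PROCESS)
    b.arc("a_bot_cons", A.CONSUMPTION, "rsk2", "p_bot")
    b.arc("a_bot_prod", A.PRODUCTION, "p_bot", "rsk2_p")
    return b.done()


def _fig9d() -> SbgnMap:
    """Influx into compartments labelled 'cell' and 'CELL' (disjunction)."""
    b = _Builder("fig9d")
    G, A = GlyphClass, ArcClass
    b.glyph("cell_lower", G.COMPARTMENT, "cell")
    b.glyph("cell_upper", G.COMPARTMENT, "CELL")
    b.glyph("ca_out", G.SIMPLE_CHEMICAL, "Ca2+")
    b.glyph("ca_in", G.SIMPLE_CHEMICAL, "Ca2+", compartment="cell_lower")
    b.glyph("p_ca", G.PROCESS)
    b.arc("a_ca_cons", A.CONSUMPTION, "ca_out", "p_ca")
    b.arc("a_ca_prod", A.PRODUCTION, "p_ca", "ca_in")
    b.glyph("na_out", G.SIMPLE_CHEMICAL, "Na+")
    b.glyph("na_in", G.SIMPLE_CHEMICAL, "Na+", compartment="cell_upper")
    b.glyph("p_na", G.PROCESS)
    b.arc("a_na_cons", A.CONSUMPTION, "na_out", "p_na")
    b.arc("a_na_prod", A.PRODUCTION, "p_na", "na_in")
    return b.done()


def _fig10a() -> SbgnMap:
    """A catalysed metabolic reaction with three substrates and three products."""
    b = _Builder("fig10a")
    G, A = GlyphClass, ArcClass
    b.glyph("enzyme", G.MACROMOLECULE, "E1")
    b.glyph("s1", G.SIMPLE_CHEMICAL, "S1")
    b.glyph("s2", G.SIMPLE_CHEMICAL, "S2")
    b.glyph("s3", G.SIMPLE_CHEMICAL, "S3")
    b.glyph("pr1", G.SIMPLE_CHEMICAL, "P1")
    b.glyph("pr2", G.SIMPLE_CHEMICAL, "P2")
    b.glyph("pr3", G.SIMPLE_CHEMICAL, "P3")
    b.glyph("p", G.PROCESS)
    b.arc("a_cat", A.CATALYSIS, "enzyme", "p")
    for i, s in enumerate(("s1", "s2", "s3"), 1):
        b.arc(f"a_cons{i}", A.CONSUMPTION, s, "p")
    for i, s in enumerate(("pr1", "pr2", "pr3"), 1):
        b.arc(f"a_prod{i}", A.PRODUCTION, "p", s)
    return b.done()


def _fig10b() -> SbgnMap:
    """Active transport of glucose into the cell, hydrolysing ATP."""
    b = _Builder("fig10b")
    G, A = GlyphClass, ArcClass
    b.glyph("cell", G.COMPARTMENT, "cell")
    b.glyph("glc_out", G.SIMPLE_CHEMICAL, "glucose")
    b.glyph("glc_in", G.SIMPLE_CHEMICAL, "glucose", compartment="cell")
    b.glyph("atp", G.SIMPLE_CHEMICAL, "ATP")
    b.glyph("adp", G.SIMPLE_CHEMICAL, "ADP")
    b.glyph("p", G.PROCESS)
    b.arc("a_cons", A.CONSUMPTION, "glc_out", "p")
    b.arc("a_prod", A.PRODUCTION, "p", "glc_in")
    b.arc("a_atp", A.CONSUMPTION, "atp", "p")
    b.arc("a_adp", A.PRODUCTION, "p", "adp")
    return b.done()


_FIGURES = {
    "fig1": _fig1,
    "fig5a": _fig5a,
    "fig5c": _fig5c,
    "fig9b": _fig9b,
    "fig9c": _fig9c,
    "fig9d": _fig9d,
    "fig10a": _fig10a,
    "fig10b": _fig10b,
}


def figure_names() -> list[str]:
    return sorted(_FIGURES)


def figure_fixture(name: str) -> SbgnMap:
    """A fresh copy of one of the transcribed worked-example maps."""
    try:
        builder = _FIGURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {', '.join(figure_names())}") from None
    return builder()


# ---------------------------------------------------------------------------
# Random planted maps
# ---------------------------------------------------------------------------

_RESERVED_LABELS = {"ATP", "ADP", "cell", "CELL", "ct:mRNA", "mt:prot", "mt:psac"}


class _LabelSource:
    """Unique lowercase labels, deterministic in the rng."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set(_RESERVED_LABELS)

    def fresh(self) -> str:
        while True:
            n = self.rng.randint(4, 8)
            label = "".join(self.rng.choice(string.ascii_lowercase) for _ in range(n))
            if label not in self.used:
                self.used.add(label)
                return label


def _merge(target: SbgnMap, sub: SbgnMap, prefix: str) -> dict[str, str]:
    """Copy ``sub`` into ``target`` with prefixed ids; return the id map."""
    idmap = {old: f"{prefix}{old}" for old in list(sub.glyphs) + list(sub.arcs)}
    for gid in sorted(sub.glyphs):
        g = sub.glyphs[gid]
        target.add_glyph(
            Glyph(
                id=idmap[gid],
                cls=g.cls,
                label=g.label,
                state=g.state,
                compartment_ref=idmap.get(g.compartment_ref) if g.compartment_ref else None,
                parent=idmap.get(g.parent) if g.parent else None,
                clone=g.clone,
            )
        )
    for aid in sorted(sub.arcs):
        a = sub.arcs[aid]
        target.add_arc(
            Arc(id=idmap[aid], cls=a.cls, source=idmap[a.source], target=idmap[a.target])
        )
    return idmap


def _applicable_decoys(brick: TemplateBrick) -> list[str]:
    kinds = ["wrong-arc-class"]
    label_vars: dict[str, int] = {}
    for g in brick.glyphs.values():
        if g.modifier is not Modifier.NONE:
            continue
        for v in g.label.variables(True):
            label_vars[v] = label_vars.get(v, 0) + 1
    if any(n >= 2 for n in label_vars.values()):
        kinds.append("variable-consistency")
    if any(
        g.cls is GlyphClass.MACROMOLECULE and g.modifier is Modifier.NONE
        for g in brick.glyphs.values()
    ):
        kinds.append("material-type")
    if any(
        g.modifier is Modifier.REPETITION and g.cls is not GlyphClass.UNSPECIFIED_ENTITY
        for g in brick.glyphs.values()
    ):
        kinds.append("extra-participant")
    if any(g.modifier is Modifier.ABSENCE for g in brick.glyphs.values()):
        kinds.append("forbidden-presence")
    return kinds


def _pick_mutation_arc(brick: TemplateBrick, smap: SbgnMap) -> tuple[str, ArcClass]:
    """Template arc whose instance counterpart the wrong-arc-class decoy breaks."""
    by_cls: dict[ArcClass, str] = {}
    for aid in sorted(brick.arcs):
        if aid in smap.arcs:  # arcs touching absence glyphs are never generated
            by_cls.setdefault(brick.arcs[aid].cls, aid)
    for cls in (ArcClass.PRODUCTION, ArcClass.CONSUMPTION, ArcClass.STIMULATION):
        if cls in by_cls:
            replacement = (
                ArcClass.INHIBITION if cls is ArcClass.STIMULATION else ArcClass.MODULATION
            )
            return by_cls[cls], replacement
    aid = sorted(by_cls.values())[0]
    return aid, ArcClass.MODULATION


def _make_decoy(
    brick: TemplateBrick, labels: _LabelSource, rng: random.Random
) -> SbgnMap:
    """A near-miss: instantiate minimally, then break exactly one rule."""
    names = sorted(required_variables(brick, False, {}))
    bindings = {n: labels.fresh() for n in names}
    smap = instantiate(brick, bindings, {}, keep_optionals=False)
    kind = rng.choice(sorted(_applicable_decoys(brick)))
    if kind == "wrong-arc-class":
        aid, replacement = _pick_mutation_arc(brick, smap)
        arc = smap.arcs[aid]
        smap.arcs[aid] = Arc(id=arc.id, cls=replacement, source=arc.source, target=arc.target)
    elif kind == "variable-consistency":
        # relabel the last glyph sharing a repeated variable
        counts: dict[str, list[str]] = {}
        for gid in sorted(brick.glyphs):
            g = brick.glyphs[gid]
            if g.modifier is not Modifier.NONE:
                continue
            for v in g.label.variables(True):
                counts.setdefault(v, []).append(gid)
        var, gids = next((v, gs) for v, gs in sorted(counts.items()) if len(gs) >= 2)
        victim = smap.glyphs[gids[-1]]
        victim.label = victim.label + "x"
    elif kind == "material-type":
        host = next(
            gid
            for gid in sorted(brick.glyphs)
            if brick.glyphs[gid].cls is GlyphClass.MACROMOLECULE
            and brick.glyphs[gid].modifier is Modifier.NONE
        )
        smap.add_glyph(
            Glyph(
                id=f"{host}_mt",
                cls=GlyphClass.UNIT_OF_INFORMATION,
                label="mt:psac",
                parent=host,
            )
        )
    elif kind == "extra-participant":
        rep = next(
            g
            for gid, g in sorted(brick.glyphs.items())
            if g.modifier is Modifier.REPETITION
        )
        from .ontology import _template_roles

        role_kind, anchor, _detail = _template_roles(brick, rep)[0]
        smap.add_glyph(Glyph(id="extra", cls=GlyphClass.MACROMOLECULE, label=labels.fresh()))
        if role_kind == "product":
            smap.add_arc(Arc(id="extra_arc", cls=ArcClass.PRODUCTION, source=anchor, target="extra"))
        else:
            smap.add_arc(Arc(id="extra_arc", cls=ArcClass.CONSUMPTION, source="extra", target=anchor))
    elif kind == "forbidden-presence":
        absent = next(
            g
            for gid, g in sorted(brick.glyphs.items())
            if g.modifier is Modifier.ABSENCE
        )
        from .ontology import _template_roles
        from .patterns import LabelPattern, render_label

        role_kind, anchor, _detail = _template_roles(brick, absent)[0]
        label = render_label(
            LabelPattern(tokens=absent.label.tokens, modifier=Modifier.NONE), {}, False
        )
        smap.add_glyph(Glyph(id="forbidden", cls=absent.cls, label=label))
        if role_kind == "product":
            smap.add_arc(
                Arc(id="forbidden_arc", cls=ArcClass.PRODUCTION, source=anchor, target="forbidden")
            )
        else:
            smap.add_arc(
                Arc(id="forbidden_arc", cls=ArcClass.CONSUMPTION, source="forbidden", target=anchor)
            )
    smap.validate()
    return smap


def random_pd_map(
    seed: int,
    n_instances: int,
    n_decoys: int,
    brick_pool: Iterable[str],
    library: BrickOntology | None = None,
) -> tuple[SbgnMap, list[PlantRecord]]:
    """Plant ``n_instances`` instantiations and ``n_decoys`` near-misses.

    Deterministic in ``seed``: the same seed always yields a byte-identical
    map. Labels are unique across the whole map so planted instances never
    bleed into each other. Decoys break exactly one matching rule each
    (wrong arc class, forbidden material type, inconsistent variable use, an
    extra same-role participant, or a glyph a ``!...!`` construct forbids).
    """
    pool = sorted(set(brick_pool))
    if n_instances > 0 and not pool:
        raise UsageError("an empty brick pool cannot plant instances")
    o = library if library is not None else default_library()
    for bid in pool:
        if bid not in o.bricks:
            raise UsageError(f"unknown brick {bid!r} in pool")
    rng = random.Random(seed)
    labels = _LabelSource(rng)
    out = SbgnMap(language=Language.PD, id=f"synthetic_{seed}")
    records: list[PlantRecord] = []
    for i in range(n_instances):
        brick = o.bricks[rng.choice(pool)]
        reps = sorted(
            g.id for g in brick.glyphs.values() if g.modifier is Modifier.REPETITION
        )
        counts = {r: rng.randint(0, 2) for r in reps}
        keep = rng.random() < 0.5
        names = sorted(required_variables(brick, keep, counts))
        bindings = {n: labels.fresh() for n in names}
        sub = instantiate(brick, bindings, counts, keep)
        idmap = _merge(out, sub, f"i{i}_")
        records.append(
            PlantRecord(
                brick=brick.id,
                bindings=bindings,
                elements=frozenset(idmap.values()),
            )
        )
    for j in range(n_decoys):
        brick = o.bricks[rng.choice(pool)] if pool else None
        if brick is None:
            break
        decoy = _make_decoy(brick, labels, rng)
        _merge(out, decoy, f"d{j}_")
    out.validate()
    return out, records
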