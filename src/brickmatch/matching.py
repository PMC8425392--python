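"""Finding, completing and generating instance bricks.

The matcher answers one question: where does a template brick occur in a PD
map? A match assigns every plain template glyph to a *distinct* instance
glyph of a compatible class, such that

* every label (and state-variable value/variable) pattern matches under one
  global, consistent set of variable bindings;
* every template arc maps to a distinct instance arc of a compatible class
  between the images of its endpoints;
* containment agrees: template parent links and compartment references map
  onto the instance ones (a template glyph with no compartment reference may
  sit in any or no compartment);
* repetition glyphs (``{...}`` labels) greedily absorb *all* remaining
  compatible glyphs in their role, and no unmatched glyph with that role may
  remain (exclusivity);
* absence glyphs (``!...!`` labels) forbid any compatible glyph in their role.

A *role* is one of reactant-of(P), product-of(P), modulator-of(P, arc class),
subunit-of(C) or decoration-of(G), anchored at the image of the template
glyph the construct is attached to.

Successful matches are *completed*: decorating auxiliary units, containing
compartments and all consumption/production participants of matched
processes are pulled in recursively. Two matches that complete to the same
element set are the same instance brick (this is what makes instance counts
well defined when a process has interchangeable participants).

Glyphs nested inside a submap are invisible to the matcher: a submap is a
single opaque node.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Mapping

from .errors import BrickmatchError, UsageError
from .ontology import TemplateBrick, TemplateGlyph, _template_roles
from .patterns import (
    Bindings,
    LabelPattern,
    Modifier,
    match_label,
    render_label,
)
from .sbgn import (
    Arc,
    ArcClass,
    AUXILIARY_CLASSES,
    EPN_CLASSES,
    Glyph,
    GlyphClass,
    Language,
    MODULATION_ARC_CLASSES,
    PROCESS_CLASSES,
    SbgnMap,
    StateValue,
)

# ---------------------------------------------------------------------------
# Glyph and arc compatibility
# ---------------------------------------------------------------------------

#: Template glyph classes with generalisation semantics: the template class
#: matches its own SBGN counterpart plus every descendant class.
_GLYPH_GENERALISATIONS: dict[GlyphClass, frozenset[GlyphClass]] = {
    GlyphClass.PROCESS: PROCESS_CLASSES,  # every stoichiometric process, never phenotype
    GlyphClass.UNSPECIFIED_ENTITY: EPN_CLASSES,  # every entity pool
}

#: Modulation-arc generalisation hierarchy: modulation is the root; a
#: stimulation template arc also accepts catalysis and necessary stimulation.
_ARC_GENERALISATIONS: dict[ArcClass, frozenset[ArcClass]] = {
    ArcClass.MODULATION: MODULATION_ARC_CLASSES,
    ArcClass.STIMULATION: frozenset(
        {ArcClass.STIMULATION, ArcClass.CATALYSIS, ArcClass.NECESSARY_STIMULATION}
    ),
}


def glyph_compatible(template_cls: GlyphClass, instance: Glyph, smap: SbgnMap) -> bool:
    """Can a template glyph of ``template_cls`` match ``instance``?

    Class-level test only (labels and states are matched separately). The
    macromolecule template additionally rejects instances decorated with a
    material-type unit of information other than ``mt:prot`` — the bare
    macromolecule glyph conventionally stands for a pool of proteins.
    """
    accepted = _GLYPH_GENERALISATIONS.get(template_cls, frozenset({template_cls}))
    if instance.cls not in accepted:
        return False
    if template_cls in (GlyphClass.MACROMOLECULE, GlyphClass.MACROMOLECULE_MULTIMER):
        for unit in smap.auxiliary_units(instance.id):
            if unit.cls is GlyphClass.UNIT_OF_INFORMATION:
                label = unit.label
                if label.startswith("mt:") and label != "mt:prot":
                    return False
    return True


def arc_compatible(template_cls: ArcClass, instance_cls: ArcClass) -> bool:
    """Reflexive, directed arc-class compatibility along the modulation hierarchy."""
    return instance_cls in _ARC_GENERALISATIONS.get(
        template_cls, frozenset({template_cls})
    )


# ---------------------------------------------------------------------------
# Match data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Match:
    """One raw (pre-completion) solution of the constraint problem."""

    brick: str
    assignment: Mapping[str, str]  # plain template glyph id -> instance glyph id
    repetition: Mapping[str, frozenset[str]]  # repetition glyph id -> bound set
    bindings: Mapping[str, str]
    core: frozenset[str]  # matched glyph + arc ids


@dataclass(frozen=True)
class InstanceBrick:
    """A completed match; ``identity`` makes distinctness well defined."""

    match: Match
    elements: frozenset[str]

    @property
    def brick(self) -> str:
        return self.match.brick

    @property
    def identity(self) -> tuple[str, frozenset[str]]:
        return (self.match.brick, self.elements)


# ---------------------------------------------------------------------------
# Completion
# ---------------------------------------------------------------------------


def complete_match(match: Match, smap: SbgnMap) -> InstanceBrick:
    """Close the matched core under the three completion rules.

    Recursively add, for every included glyph: the auxiliary units decorating
    it (units of information and state variables — never subunits), the
    compartment containing it, and, for process-kind glyphs, every glyph
    linked by a consumption or production arc together with that arc. The
    result is the least fixpoint, so completing twice changes nothing.
    """
    elems: set[str] = set(match.core)
    frontier: list[str] = [e for e in elems if e in smap.glyphs]
    while frontier:
        gid = frontier.pop()
        g = smap.glyphs[gid]
        additions: list[str] = []
        for unit in smap.auxiliary_units(gid):
            additions.append(unit.id)
        if g.compartment_ref is not None:
            additions.append(g.compartment_ref)
        if g.cls in PROCESS_CLASSES:
            for a in smap.arcs.values():
                if a.cls is ArcClass.CONSUMPTION and a.target == gid:
                    other = a.source
                elif a.cls is ArcClass.PRODUCTION and a.source == gid:
                    other = a.target
                else:
                    continue
                if a.id not in elems:
                    elems.add(a.id)
                if other not in elems:
                    additions.append(other)
        for new in additions:
            if new not in elems:
                elems.add(new)
                if new in smap.glyphs:
                    frontier.append(new)
    return InstanceBrick(match=match, elements=frozenset(elems))


# ---------------------------------------------------------------------------
# Role machinery (shared by repetition, absence and exclusivity)
# ---------------------------------------------------------------------------


def _glyphs_in_role(
    smap: SbgnMap,
    role: tuple,
    anchor_instance: str,
    visible: frozenset[str],
) -> list[tuple[str, tuple[str, ...]]]:
    """Instance glyphs filling ``role`` at ``anchor_instance``.

    Returns ``(glyph id, connecting arc ids)`` pairs; the arcs are the ones a
    repetition binding would pull into the matched core.
    """
    kind, _anchor_tid, detail = role
    out: dict[str, list[str]] = {}
    if kind == "reactant":
        for a in smap.arcs.values():
            if a.cls is ArcClass.CONSUMPTION and a.target == anchor_instance:
                if a.source in visible:
                    out.setdefault(a.source, []).append(a.id)
    elif kind == "product":
        for a in smap.arcs.values():
            if a.cls is ArcClass.PRODUCTION and a.source == anchor_instance:
                if a.target in visible:
                    out.setdefault(a.target, []).append(a.id)
    elif kind == "modulator":
        for a in smap.arcs.values():
            if (
                a.cls in MODULATION_ARC_CLASSES
                and a.target == anchor_instance
                and arc_compatible(detail, a.cls)
                and a.source in visible
            ):
                out.setdefault(a.source, []).append(a.id)
    elif kind == "subunit":
        for g in smap.subunits(anchor_instance):
            if g.id in visible:
                out.setdefault(g.id, [])
    elif kind == "decoration":
        for g in smap.auxiliary_units(anchor_instance):
            if g.id in visible:
                out.setdefault(g.id, [])
    return [(gid, tuple(arcs)) for gid, arcs in sorted(out.items())]


def _label_matches_locally(
    tglyph: TemplateGlyph, instance: Glyph, env: Bindings
) -> bool:
    """Label/state test for repetition and absence glyphs.

    Variables already bound globally must agree; variables local to the
    construct may bind per candidate glyph (their bindings do not propagate,
    matching one repetition label against differently labelled glyphs).
    """
    stripped = LabelPattern(tokens=tglyph.label.tokens, modifier=Modifier.NONE)
    if not match_label(stripped, instance.label, env):
        return False
    if tglyph.state is not None:
        state = instance.state or StateValue()
        value_pat, variable_pat = tglyph.state
        for env2 in match_label(value_pat, state.value, env):
            if match_label(variable_pat, state.variable, env2):
                return True
        return False
    return True


# ---------------------------------------------------------------------------
# The search
# ---------------------------------------------------------------------------


class _Search:
    def __init__(self, brick: TemplateBrick, smap: SbgnMap):
        self.brick = brick
        self.smap = smap
        hidden = smap.hidden_glyphs()
        self.visible = frozenset(set(smap.glyphs) - hidden)
        self.visible_arcs = [
            a
            for a in smap.arcs.values()
            if a.source in self.visible and a.target in self.visible
        ]
        self.plain = [
            g for g in brick.glyphs.values() if g.modifier is Modifier.NONE
        ]
        self.repetition = sorted(
            (g for g in brick.glyphs.values() if g.modifier is Modifier.REPETITION),
            key=lambda g: g.id,
        )
        self.absence = sorted(
            (g for g in brick.glyphs.values() if g.modifier is Modifier.ABSENCE),
            key=lambda g: g.id,
        )
        plain_ids = {g.id for g in self.plain}
        self.template_arcs = [
            a
            for a in brick.arcs.values()
            if a.source in plain_ids and a.target in plain_ids
        ]
        # static candidate lists (class-level + relaxed label test)
        self.candidates: dict[str, list[Glyph]] = {}
        for t in self.plain:
            cands = []
            for gid in sorted(self.visible):
                g = smap.glyphs[gid]
                if not glyph_compatible(t.cls, g, smap):
                    continue
                if not match_label(t.label, g.label, {}):
                    continue
                if t.state is not None:
                    state = g.state or StateValue()
                    value_pat, variable_pat = t.state
                    ok = any(
                        match_label(variable_pat, state.variable, env)
                        for env in match_label(value_pat, state.value, {})
                    )
                    if not ok:
                        continue
                cands.append(g)
            self.candidates[t.id] = cands
        # search order: scarcest candidates first keeps backtracking shallow
        self.order = sorted(self.plain, key=lambda t: (len(self.candidates[t.id]), t.id))

    # -- constraint propagation -------------------------------------------

    def _structure_ok(self, t: TemplateGlyph, g: Glyph, asg: dict[str, str]) -> bool:
        glyphs = self.smap.glyphs
        # parent links, both directions
        if t.parent is not None and t.parent in asg and g.parent != asg[t.parent]:
            return False
        for u in self.plain:
            if u.id in asg and u.parent == t.id and glyphs[asg[u.id]].parent != g.id:
                return False
        # compartment references, both directions
        if (
            t.compartment_ref is not None
            and t.compartment_ref in asg
            and g.compartment_ref != asg[t.compartment_ref]
        ):
            return False
        for u in self.plain:
            if (
                u.id in asg
                and u.compartment_ref == t.id
                and glyphs[asg[u.id]].compartment_ref != g.id
            ):
                return False
        # every template arc with both endpoints placed needs a compatible arc
        for ta in self.template_arcs:
            ends = {ta.source, ta.target}
            if t.id not in ends:
                continue
            other = ta.target if ta.source == t.id else ta.source
            if other not in asg and other != t.id:
                continue
            src = g.id if ta.source == t.id else asg[ta.source]
            dst = g.id if ta.target == t.id else asg[ta.target]
            if not any(
                a.source == src and a.target == dst and arc_compatible(ta.cls, a.cls)
                for a in self.visible_arcs
            ):
                return False
        return True

    # -- plain-glyph assignment -------------------------------------------

    def _assign(self, i: int, asg: dict[str, str], env: Bindings) -> Iterator[tuple[dict, Bindings]]:
        if i == len(self.order):
            yield dict(asg), dict(env)
            return
        t = self.order[i]
        used = set(asg.values())
        for g in self.candidates[t.id]:
            if g.id in used:
                continue
            if not self._structure_ok(t, g, asg):
                continue
            for env2 in match_label(t.label, g.label, env):
                if t.state is None:
                    asg[t.id] = g.id
                    yield from self._assign(i + 1, asg, env2)
                    del asg[t.id]
                else:
                    state = g.state or StateValue()
                    value_pat, variable_pat = t.state
                    for env3 in match_label(value_pat, state.value, env2):
                        for env4 in match_label(variable_pat, state.variable, env3):
                            asg[t.id] = g.id
                            yield from self._assign(i + 1, asg, env4)
                            del asg[t.id]

    # -- arc assignment ----------------------------------------------------

    def _arc_assignments(self, asg: dict[str, str]) -> Iterator[dict[str, str]]:
        """Injective template-arc -> instance-arc assignments."""
        options: list[list[str]] = []
        for ta in self.template_arcs:
            src, dst = asg[ta.source], asg[ta.target]
            opts = [
                a.id
                for a in self.visible_arcs
                if a.source == src and a.target == dst and arc_compatible(ta.cls, a.cls)
            ]
            if not opts:
                return
            options.append(opts)
        for combo in itertools.product(*options):
            if len(set(combo)) == len(combo):
                yield dict(zip((ta.id for ta in self.template_arcs), combo))

    # -- negative constraints and repetition ------------------------------

    def _negatives(
        self, asg: dict[str, str], env: Bindings
    ) -> Iterator[tuple[dict[str, frozenset[str]], frozenset[str]]]:
        """Check absence, bind repetitions greedily; yield at most one outcome."""
        assigned = set(asg.values())
        for t in self.absence:
            role = _template_roles(self.brick, t)[0]
            anchor = asg[role[1]]
            for gid, _arcs in _glyphs_in_role(self.smap, role, anchor, self.visible):
                if gid in assigned:
                    continue  # accounted for by another template glyph
                g = self.smap.glyphs[gid]
                if glyph_compatible(t.cls, g, self.smap) and _label_matches_locally(
                    t, g, env
                ):
                    return  # forbidden glyph present
        rep_sets: dict[str, frozenset[str]] = {}
        rep_arcs: set[str] = set()
        taken: set[str] = set(assigned)
        for t in self.repetition:
            role = _template_roles(self.brick, t)[0]
            anchor = asg[role[1]]
            bound: set[str] = set()
            for gid, arcs in _glyphs_in_role(self.smap, role, anchor, self.visible):
                if gid in taken:
                    continue
                g = self.smap.glyphs[gid]
                if glyph_compatible(t.cls, g, self.smap) and _label_matches_locally(
                    t, g, env
                ):
                    bound.add(gid)
                    rep_arcs.update(arcs)
                else:
                    return  # exclusivity: unmatched glyph in the same role
            taken.update(bound)
            rep_sets[t.id] = frozenset(bound)
        yield rep_sets, frozenset(rep_arcs)

    # -- driver ------------------------------------------------------------

    def run(self) -> list[InstanceBrick]:
        results: dict[tuple, InstanceBrick] = {}
        for asg, env in self._assign(0, {}, {}):
            for arc_asg in self._arc_assignments(asg):
                for rep_sets, rep_arcs in self._negatives(asg, env):
                    core = (
                        frozenset(asg.values())
                        | frozenset(arc_asg.values())
                        | frozenset(itertools.chain.from_iterable(rep_sets.values()))
                        | rep_arcs
                    )
                    match = Match(
                        brick=self.brick.id,
                        assignment=dict(asg),
                        repetition=dict(rep_sets),
                        bindings=dict(env),
                        core=core,
                    )
                    inst = complete_match(match, self.smap)
                    results.setdefault(inst.identity, inst)
        return sorted(
            results.values(), key=lambda i: (i.brick, tuple(sorted(i.elements)))
        )


def find_matches(brick: TemplateBrick, smap: SbgnMap) -> list[InstanceBrick]:
    """All distinct instance bricks of ``brick`` in ``smap`` (PD only)."""
    if brick.language is not Language.PD:
        raise UsageError(f"brick {brick.id} is a {brick.language.value} brick; only PD is matched")
    if smap.language is not Language.PD:
        raise UsageError(f"map {smap.id!r} is a {smap.language.value} map; only PD is matched")
    return _Search(brick, smap).run()


# ---------------------------------------------------------------------------
# Template-based construction
# ---------------------------------------------------------------------------


def instantiate(
    brick: TemplateBrick,
    bindings: Mapping[str, str],
    repetition_counts: Mapping[str, int] | None = None,
    keep_optionals: bool = True,
) -> SbgnMap:
    """Generate a concrete PD map from a template brick.

    Every plain template glyph becomes one glyph; a repetition glyph with
    count k expands to k copies whose variables are looked up with suffixes
    ``_1`` .. ``_k``; absence glyphs generate nothing (a positive count for
    one is a usage error). The result always matches its source brick.
    """
    counts = dict(repetition_counts or {})
    smap = SbgnMap(language=brick.language, id=f"{brick.id.replace(':', '_')}_instance")

    copies: dict[str, list[str]] = {}  # template glyph id -> generated glyph ids

    def strip(pattern: LabelPattern) -> LabelPattern:
        return LabelPattern(tokens=pattern.tokens, modifier=Modifier.NONE)

    def suffixed(pattern_vars: frozenset[str], i: int) -> dict[str, str]:
        local: dict[str, str] = {}
        for name in pattern_vars:
            key = f"{name}_{i}"
            if key in bindings:
                local[name] = bindings[key]
        return local

    for t in sorted(brick.glyphs.values(), key=lambda g: g.id):
        if t.modifier is Modifier.ABSENCE:
            if counts.get(t.id, 0) > 0:
                raise UsageError(
                    f"absence glyph {t.id!r} cannot be instantiated with a positive count"
                )
            copies[t.id] = []
            continue
        if t.modifier is Modifier.REPETITION:
            k = counts.get(t.id, 0)
            if k < 0:
                raise UsageError(f"negative repetition count for glyph {t.id!r}")
            ids = []
            all_vars = t.label.variables(True) | (
                (t.state[0].variables(True) | t.state[1].variables(True))
                if t.state
                else frozenset()
            )
            for i in range(1, k + 1):
                local = suffixed(all_vars, i)
                gid = f"{t.id}_{i}"
                smap.add_glyph(
                    Glyph(
                        id=gid,
                        cls=t.cls,
                        label=render_label(strip(t.label), local, keep_optionals),
                        state=(
                            StateValue(
                                value=render_label(t.state[0], local, keep_optionals),
                                variable=render_label(t.state[1], local, keep_optionals),
                            )
                            if t.state is not None
                            else None
                        ),
                        compartment_ref=t.compartment_ref,
                        parent=t.parent,
                    )
                )
                ids.append(gid)
            copies[t.id] = ids
            continue
        smap.add_glyph(
            Glyph(
                id=t.id,
                cls=t.cls,
                label=render_label(t.label, bindings, keep_optionals),
                state=(
                    StateValue(
                        value=render_label(t.state[0], bindings, keep_optionals),
                        variable=render_label(t.state[1], bindings, keep_optionals),
                    )
                    if t.state is not None
                    else None
                ),
                compartment_ref=t.compartment_ref,
                parent=t.parent,
            )
        )
        copies[t.id] = [t.id]

    for a in sorted(brick.arcs.values(), key=lambda a: a.id):
        for i, (src, dst) in enumerate(
            itertools.product(copies.get(a.source, []), copies.get(a.target, []))
        ):
            aid = a.id if i == 0 and len(copies[a.source]) * len(copies[a.target]) == 1 else f"{a.id}_{i + 1}"
            smap.add_arc(Arc(id=aid, cls=a.cls, source=src, target=dst))

    smap.validate()
    return smap


# ---------------------------------------------------------------------------
# Subsumption
# ---------------------------------------------------------------------------


class Subsumption(str, Enum):
    SUBSUMES = "subsumes"
    NOT_SUBSUMES = "not-subsumes"
    UNKNOWN = "unknown"


def required_variables(
    brick: TemplateBrick, keep_optionals: bool, counts: Mapping[str, int]
) -> set[str]:
    """Variable names (suffixed for repetition copies) an instantiation needs."""
    out: set[str] = set()
    for t in brick.glyphs.values():
        if t.modifier is Modifier.ABSENCE:
            continue
        names: set[str] = set(t.label.variables(keep_optionals))
        if t.state is not None:
            names |= t.state[0].variables(keep_optionals)
            names |= t.state[1].variables(keep_optionals)
        if t.modifier is Modifier.REPETITION:
            for i in range(1, counts.get(t.id, 0) + 1):
                out.update(f"{n}_{i}" for n in names)
        else:
            out.update(names)
    return out


def canonical_instantiations(brick: TemplateBrick) -> list[SbgnMap]:
    """The variant instantiations used for the subsumption test.

    Optionals all kept and all dropped, repetition counts all 0 and all 2,
    with fresh pairwise-distinct literals for every variable.
    """
    reps = [g.id for g in brick.glyphs.values() if g.modifier is Modifier.REPETITION]
    variants: list[SbgnMap] = []
    for keep in (True, False):
        for count in (0, 2):
            counts = {r: count for r in reps}
            names = sorted(required_variables(brick, keep, counts))
            bindings = {name: f"v{i}v" for i, name in enumerate(names)}
            try:
                variants.append(instantiate(brick, bindings, counts, keep))
            except BrickmatchError:
                continue
    return variants


def infer_subsumption(a: TemplateBrick, b: TemplateBrick) -> Subsumption:
    """Is every instance matched by ``a`` also matched by ``b``?

    Sound but incomplete: ``b`` is tested against the canonical
    instantiations of ``a``. If ``b`` matches them all the answer is
    ``subsumes``; if some variant is matched by ``a`` but not by ``b`` it is
    a concrete counterexample (``not-subsumes``); otherwise ``unknown``.
    """
    if a.language is not Language.PD or b.language is not Language.PD:
        raise UsageError("subsumption inference is defined for PD bricks only")
    variants = canonical_instantiations(a)
    if not variants:
        return Subsumption.UNKNOWN
    all_b = True
    all_a = True
    for m in variants:
        a_ok = bool(find_matches(a, m))
        b_ok = bool(find_matches(b, m))
        if a_ok and not b_ok:
            return Subsumption.NOT_SUBSUMES
        all_b &= b_ok
        all_a &= a_ok
    if all_a and all_b:
        return Subsumption.SUBSUMES
    return Subsumption.UNKNOWN
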