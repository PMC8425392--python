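"""Independent brute-force oracles used to validate the real implementations.

These deliberately use a different algorithmic shape than the production
code: the label oracle enumerates every segmentation of the text instead of
recursive prefix matching, and the graph oracle enumerates every injective
glyph assignment over class-compatible candidates instead of backtracking
with forward checking.
"""

from __future__ import annotations

import itertools

from brickmatch.matching import (
    InstanceBrick,
    Match,
    _glyphs_in_role,
    _label_matches_locally,
    arc_compatible,
    complete_match,
    glyph_compatible,
)
from brickmatch.ontology import TemplateBrick, _template_roles
from brickmatch.patterns import (
    Disjunction,
    LabelPattern,
    Literal,
    Modifier,
    OptionalGroup,
    Variable,
    match_label,
)
from brickmatch.sbgn import SbgnMap, StateValue


# ---------------------------------------------------------------------------
# Label oracle: enumerate all segmentations
# ---------------------------------------------------------------------------


def _expansions(tokens):
    """All flattenings of the token sequence into ('lit', s) / ('var', n) units."""
    if not tokens:
        yield []
        return
    head, rest = tokens[0], tokens[1:]
    tails = list(_expansions(rest))
    if isinstance(head, Literal):
        heads = [[("lit", head.text)]]
    elif isinstance(head, Variable):
        heads = [[("var", head.name)]]
    elif isinstance(head, OptionalGroup):
        heads = [[]] + [h for h in _expansions(list(head.body))]
    elif isinstance(head, Disjunction):
        heads = [[("lit", head.left)], [("lit", head.right)]]
    else:  # pragma: no cover
        raise TypeError(head)
    for h in heads:
        for t in tails:
            yield h + t


def oracle_match_label(pattern: LabelPattern, text: str, given=None) -> set:
    """All binding extensions, as a set of frozensets of (name, value) pairs."""
    given = dict(given or {})
    solutions = set()
    for units in _expansions(list(pattern.tokens)):
        k = len(units)
        if k == 0:
            if text == "":
                solutions.add(frozenset(given.items()))
            continue
        # all ways to cut text into k ordered (possibly empty) parts
        for cuts in itertools.combinations_with_replacement(range(len(text) + 1), k - 1):
            bounds = (0,) + cuts + (len(text),)
            parts = [text[bounds[i] : bounds[i + 1]] for i in range(k)]
            env = dict(given)
            ok = True
            for (kind, payload), part in zip(units, parts):
                if kind == "lit":
                    if part != payload:
                        ok = False
                        break
                else:
                    if not part:
                        ok = False
                        break
                    if payload in env and env[payload] != part:
                        ok = False
                        break
                    env[payload] = part
            if ok:
                solutions.add(frozenset(env.items()))
    return solutions


# ---------------------------------------------------------------------------
# Graph oracle: exhaustive injective assignment enumeration
# ---------------------------------------------------------------------------


def _binding_product(pairs, env):
    """All consistent environments extending env across (pattern, text) pairs."""
    envs = [dict(env)]
    for pattern, text in pairs:
        nxt = []
        for e in envs:
            nxt.extend(match_label(pattern, text, e))
        if not nxt:
            return []
        # dedup
        seen, out = set(), []
        for e in nxt:
            key = tuple(sorted(e.items()))
            if key not in seen:
                seen.add(key)
                out.append(e)
        envs = out
    return envs


def oracle_find_matches(brick: TemplateBrick, smap: SbgnMap) -> list[InstanceBrick]:
    """Exhaustive reference matcher: try every injective assignment."""
    hidden = smap.hidden_glyphs()
    visible = frozenset(set(smap.glyphs) - hidden)
    visible_arcs = [
        a for a in smap.arcs.values() if a.source in visible and a.target in visible
    ]
    plain = sorted(
        (g for g in brick.glyphs.values() if g.modifier is Modifier.NONE),
        key=lambda g: g.id,
    )
    reps = sorted(
        (g for g in brick.glyphs.values() if g.modifier is Modifier.REPETITION),
        key=lambda g: g.id,
    )
    absents = [g for g in brick.glyphs.values() if g.modifier is Modifier.ABSENCE]
    plain_ids = {g.id for g in plain}
    template_arcs = [
        a for a in brick.arcs.values() if a.source in plain_ids and a.target in plain_ids
    ]

    candidates = [
        [g for g in sorted(visible) if glyph_compatible(t.cls, smap.glyphs[g], smap)]
        for t in plain
    ]
    results: dict[tuple, InstanceBrick] = {}
    for combo in itertools.product(*candidates):
        if len(set(combo)) != len(combo):
            continue
        asg = {t.id: gid for t, gid in zip(plain, combo)}
        # structural constraints
        ok = True
        for t in plain:
            g = smap.glyphs[asg[t.id]]
            if t.parent is not None and g.parent != asg.get(t.parent):
                ok = False
                break
            if (
                t.compartment_ref is not None
                and g.compartment_ref != asg.get(t.compartment_ref)
            ):
                ok = False
                break
        if not ok:
            continue
        # labels and states, all binding solutions
        pairs = []
        for t in plain:
            g = smap.glyphs[asg[t.id]]
            pairs.append((t.label, g.label))
            if t.state is not None:
                state = g.state or StateValue()
                pairs.append((t.state[0], state.value))
                pairs.append((t.state[1], state.variable))
        for env in _binding_product(pairs, {}):
            # injective arc assignment, brute force
            arc_opts = []
            for ta in template_arcs:
                opts = [
                    a.id
                    for a in visible_arcs
                    if a.source == asg[ta.source]
                    and a.target == asg[ta.target]
                    and arc_compatible(ta.cls, a.cls)
                ]
                arc_opts.append(opts)
            for arc_combo in itertools.product(*arc_opts):
                if len(set(arc_combo)) != len(arc_combo):
                    continue
                # absence
                assigned = set(asg.values())
                violated = False
                for t in absents:
                    role = _template_roles(brick, t)[0]
                    for gid, _arcs in _glyphs_in_role(
                        smap, role, asg[role[1]], visible
                    ):
                        if gid in assigned:
                            continue
                        if glyph_compatible(
                            t.cls, smap.glyphs[gid], smap
                        ) and _label_matches_locally(t, smap.glyphs[gid], env):
                            violated = True
                            break
                    if violated:
                        break
                if violated:
                    continue
                # greedy repetition + exclusivity
                rep_sets = {}
                rep_arcs: set[str] = set()
                taken = set(assigned)
                failed = False
                for t in reps:
                    role = _template_roles(brick, t)[0]
                    bound = set()
                    for gid, arcs in _glyphs_in_role(
                        smap, role, asg[role[1]], visible
                    ):
                        if gid in taken:
                            continue
                        if glyph_compatible(
                            t.cls, smap.glyphs[gid], smap
                        ) and _label_matches_locally(t, smap.glyphs[gid], env):
                            bound.add(gid)
                            rep_arcs.update(arcs)
                        else:
                            failed = True
                            break
                    if failed:
                        break
                    taken.update(bound)
                    rep_sets[t.id] = frozenset(bound)
                if failed:
                    continue
                core = (
                    frozenset(asg.values())
                    | frozenset(arc_combo)
                    | frozenset(itertools.chain.from_iterable(rep_sets.values()))
                    | frozenset(rep_arcs)
                )
                match = Match(
                    brick=brick.id,
                    assignment=dict(asg),
                    repetition=rep_sets,
                    bindings=dict(env),
                    core=core,
                )
                inst = complete_match(match, smap)
                results.setdefault(inst.identity, inst)
    return sorted(results.values(), key=lambda i: (i.brick, tuple(sorted(i.elements))))
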