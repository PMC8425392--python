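"""Whole-map annotation against a brick library.

``annotate_map`` runs every PD template brick of a library over one map and
turns each instance brick into term annotations via the brick's
associations. Per-term counts tally *distinct instance identities*, so two
routes to the same completed element set count once.

The completeness-evaluation step flags *generic-only* instances: instances
of a generic brick (irreversible process, modulatory activity, ...) whose
focal element is not shared with any instance of a more specific brick
recorded as a subclass of that generic brick. The focal element of a
process-kind instance is its process glyph; for activity-kind instances it
is the matched modulation-kind arc. Comparing focal elements rather than
whole element sets is deliberate: a specific instance legitimately spans
more elements (the enzyme, the catalysis arc) than the generic instance of
the same event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .matching import InstanceBrick, find_matches
from .ontology import BrickOntology
from .sbgn import (
    MODULATION_ARC_CLASSES,
    PROCESS_CLASSES,
    SbgnMap,
    write_sbgnml,
)


@dataclass(frozen=True)
class Annotation:
    instance: InstanceBrick
    term: str
    relation: str
    brick: str


@dataclass
class AnnotationReport:
    map_id: str
    annotations: list[Annotation]
    counts: dict[str, int]
    instances: list[InstanceBrick]
    focals: dict[tuple, str | None]  # instance identity -> focal element id
    generic_only: list[InstanceBrick] = field(default_factory=list)


def focal_element(instance: InstanceBrick, smap: SbgnMap) -> str | None:
    """The element identifying *which event* an instance is about.

    Activity-kind instances (a modulation-kind arc in the matched core) focus
    on that arc; process-kind instances focus on their process glyph.
    """
    core_arcs = sorted(
        aid
        for aid in instance.match.core
        if aid in smap.arcs and smap.arcs[aid].cls in MODULATION_ARC_CLASSES
    )
    if core_arcs:
        return core_arcs[0]
    core_processes = sorted(
        gid
        for gid in instance.match.core
        if gid in smap.glyphs and smap.glyphs[gid].cls in PROCESS_CLASSES
    )
    if core_processes:
        return core_processes[0]
    return None


def annotate_map(smap: SbgnMap, o: BrickOntology) -> AnnotationReport:
    """Match every PD brick of the library and collect annotations.

    Output ordering is deterministic (brick id, then sorted element ids).
    """
    instances: list[InstanceBrick] = []
    for brick in sorted(o.pd_bricks(), key=lambda b: b.id):
        instances.extend(find_matches(brick, smap))

    annotations: list[Annotation] = []
    for inst in instances:
        brick = o.bricks[inst.brick]
        for term, relation in sorted(brick.associations):
            annotations.append(
                Annotation(instance=inst, term=term, relation=relation, brick=brick.id)
            )

    counts: dict[str, int] = {}
    for term in sorted({a.term for a in annotations}):
        identities = {a.instance.identity for a in annotations if a.term == term}
        counts[term] = len(identities)

    focals = {inst.identity: focal_element(inst, smap) for inst in instances}
    report = AnnotationReport(
        map_id=smap.id,
        annotations=annotations,
        counts=counts,
        instances=instances,
        focals=focals,
    )
    report.generic_only = generic_only_instances(report, o, set(o.generic_bricks))
    return report


def generic_only_instances(
    report: AnnotationReport, o: BrickOntology, generic: set[str]
) -> list[InstanceBrick]:
    """Instances matched by a generic brick but by no more specific one.

    An instance I of a generic brick g is generic-only when no instance of a
    non-generic brick s recorded as a subclass of g (``(s, g)`` in the
    library's subsumptions) shares I's focal element. These are the
    instances worth manual triage: they may reveal a missing term or brick,
    a misrepresentation, or a concept deliberately left out of the ontology
    (e.g. the stimulation of a dissociation).
    """
    for g in generic:
        if g not in o.bricks:
            raise KeyError(g)
    specifics_of: dict[str, set[str]] = {g: set() for g in generic}
    for sub, sup in o.subsumptions:
        if sup in generic and sub != sup and sub not in generic:
            specifics_of[sup].add(sub)
    specific_focals: dict[str, set[str | None]] = {}
    for inst in report.instances:
        specific_focals.setdefault(inst.brick, set()).add(report.focals[inst.identity])

    out: list[InstanceBrick] = []
    for inst in report.instances:
        if inst.brick not in generic:
            continue
        focal = report.focals[inst.identity]
        covered = any(
            focal in specific_focals.get(s, ())
            for s in specifics_of[inst.brick]
        )
        if not covered:
            out.append(inst)
    return out


def export_instances(
    report: AnnotationReport, smap: SbgnMap
) -> list[tuple[str, bytes]]:
    """One SBGN-ML document per distinct instance, named brick id + ordinal.

    Each document contains exactly the instance's completed elements;
    completion guarantees that parents of auxiliary units and referenced
    compartments are present, so the excerpt is a valid map on its own.
    """
    seen: set[tuple] = set()
    out: list[tuple[str, bytes]] = []
    ordinals: dict[str, int] = {}
    for inst in report.instances:
        if inst.identity in seen:
            continue
        seen.add(inst.identity)
        ordinals[inst.brick] = ordinals.get(inst.brick, 0) + 1
        n = ordinals[inst.brick]
        sub = SbgnMap(
            language=smap.language,
            id=f"{smap.id}_{inst.brick.replace(':', '_')}_{n:03d}",
        )
        for gid in sorted(inst.elements):
            if gid not in smap.glyphs:
                continue
            g = smap.glyphs[gid]
            sub.add_glyph(
                type(g)(
                    id=g.id,
                    cls=g.cls,
                    label=g.label,
                    state=g.state,
                    compartment_ref=(
                        g.compartment_ref if g.compartment_ref in inst.elements else None
                    ),
                    parent=g.parent if g.parent in inst.elements else None,
                    clone=g.clone,
                )
            )
        for aid in sorted(inst.elements):
            if aid in smap.arcs:
                sub.add_arc(smap.arcs[aid])
        name = f"{inst.brick.replace(':', '_')}_{n:03d}.sbgn"
        out.append((name, write_sbgnml(sub)))
    return out


def report_to_json(report: AnnotationReport) -> bytes:
    """Serialize a report for the CLI (schema in ``data/report.schema.json``)."""
    doc = {
        "map": report.map_id,
        "counts": dict(sorted(report.counts.items())),
        "instances": [
            {
                "brick": inst.brick,
                "elements": sorted(inst.elements),
                "bindings": dict(sorted(inst.match.bindings.items())),
                "focal": report.focals[inst.identity],
                "generic_only": inst in report.generic_only,
            }
            for inst in report.instances
        ],
        "annotations": [
            {
                "brick": a.brick,
                "term": a.term,
                "relation": a.relation,
                "elements": sorted(a.instance.elements),
            }
            for a in report.annotations
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=False).encode("utf-8")
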