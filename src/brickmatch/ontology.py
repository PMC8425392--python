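"""The Bricks Ontology: terms, template bricks, categories and their relations.

A *term* names a biological concept (a CURIE from GO, SBO or the brick
namespace BKO); terms form an acyclic parent hierarchy. A *template brick* is
a small SBGN pattern — glyphs whose labels are :mod:`patterns` label patterns
— associated with one or more terms through one of five relations:

``main``       the brick fully represents the term;
``narrow``     the brick represents only a sub-concept of the term;
``alternate``  the brick fully represents the term but another (main) brick
               is preferred;
``synonym``    (AF bricks only) the brick represents a synonym of the term;
``broad``      (AF/ER bricks only) the brick represents a broader concept.

*Categories* are flat browsing metadata; *subsumptions* record brick
subclass relationships (A subclass-of B: every instance matched by A is also
matched by B), which the matcher can verify empirically.

The on-disk form is a JSON dialect (see ``data/library.schema.json``); the
bundled default library ships in ``data/library.json``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import networkx as nx

from .errors import LibraryLoadError
from .patterns import LabelPattern, Modifier, parse_pattern
from .sbgn import Arc, ArcClass, GlyphClass, Language

RELATIONS = ("main", "narrow", "alternate", "synonym", "broad")
_AF_ER_ONLY_RELATIONS = {"synonym": (Language.AF,), "broad": (Language.AF, Language.ER)}
_CURIE_RE = re.compile(r"^(GO|SBO|BKO):\d{7}$")


@dataclass(frozen=True)
class Term:
    id: str
    name: str
    source: str  # GO | SBO | BKO
    parents: frozenset[str] = frozenset()
    alternate_ids: frozenset[str] = frozenset()
    #: True for leaf terms that cannot be drawn as a generic SBGN pattern but
    #: stay in the ontology because a descendant (in the source ontology)
    #: covers them.
    unrepresentable: bool = False


@dataclass(frozen=True)
class TemplateGlyph:
    """One glyph of a template brick; its label (and state) are patterns."""

    id: str
    cls: GlyphClass
    label: LabelPattern
    state: tuple[LabelPattern, LabelPattern] | None = None  # (value, variable)
    compartment_ref: str | None = None
    parent: str | None = None

    @property
    def modifier(self) -> Modifier:
        return self.label.modifier


@dataclass(frozen=True)
class TemplateBrick:
    id: str
    language: Language
    name: str
    glyphs: dict[str, TemplateGlyph]
    arcs: dict[str, Arc]
    associations: frozenset[tuple[str, str]]  # (term id, relation)
    categories: frozenset[str] = frozenset()

    def __hash__(self):
        return hash(self.id)

    def __eq__(self, other):
        if not isinstance(other, TemplateBrick):
            return NotImplemented
        return (
            self.id == other.id
            and self.language == other.language
            and self.name == other.name
            and self.glyphs == other.glyphs
            and self.arcs == other.arcs
            and self.associations == other.associations
            and self.categories == other.categories
        )


@dataclass(frozen=True)
class Category:
    id: str
    name: str
    supercategory: str | None = None


@dataclass(frozen=True)
class Diagnostic:
    rule: str
    subject: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.subject}: {self.message}"


class BrickOntology:
    """Terms, bricks and categories plus the recorded subsumption edges."""

    def __init__(
        self,
        terms: dict[str, Term],
        bricks: dict[str, TemplateBrick],
        categories: dict[str, Category],
        subsumptions: set[tuple[str, str]],
        generic_bricks: frozenset[str] = frozenset(),
        name: str = "library",
    ):
        self.terms = terms
        self.bricks = bricks
        self.categories = categories
        self.subsumptions = set(subsumptions)
        self.generic_bricks = frozenset(generic_bricks)
        self.name = name

    def pd_bricks(self) -> list[TemplateBrick]:
        return [b for b in self.bricks.values() if b.language is Language.PD]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BrickOntology):
            return NotImplemented
        return (
            self.terms == other.terms
            and self.bricks == other.bricks
            and self.categories == other.categories
            and self.subsumptions == other.subsumptions
            and self.generic_bricks == other.generic_bricks
            and self.name == other.name
        )


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------


def bricks_for_term(
    o: BrickOntology, term: str, relations: set[str] | frozenset[str]
) -> set[TemplateBrick]:
    """Bricks associated with ``term`` through one of ``relations``.

    No transitivity over the term hierarchy: only direct associations count.
    """
    if term not in o.terms:
        raise KeyError(term)
    return {
        b
        for b in o.bricks.values()
        if any(t == term and r in relations for (t, r) in b.associations)
    }


def term_descendants(o: BrickOntology, term: str) -> set[str]:
    """Transitive closure over child links, excluding ``term`` itself."""
    if term not in o.terms:
        raise KeyError(term)
    children: dict[str, set[str]] = {t: set() for t in o.terms}
    for t in o.terms.values():
        for p in t.parents:
            if p in children:
                children[p].add(t.id)
    out: set[str] = set()
    frontier = [term]
    while frontier:
        cur = frontier.pop()
        for child in children.get(cur, ()):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


# ---------------------------------------------------------------------------
# Consistency checking
# ---------------------------------------------------------------------------


def check_consistency(o: BrickOntology) -> list[Diagnostic]:
    """All invariant violations, as a (possibly empty) list of diagnostics."""
    diags: list[Diagnostic] = []

    # term hierarchy resolves and is acyclic
    term_graph = nx.DiGraph()
    term_graph.add_nodes_from(o.terms)
    for t in o.terms.values():
        for p in t.parents:
            if p not in o.terms:
                diags.append(
                    Diagnostic("term-parent-unresolved", t.id, f"unknown parent {p!r}")
                )
            else:
                term_graph.add_edge(p, t.id)
    try:
        cycle = nx.find_cycle(term_graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        names = " -> ".join(edge[0] for edge in cycle)
        diags.append(Diagnostic("term-cycle", cycle[0][0], f"parent cycle {names}"))

    # leaf terms carry at least one brick (unless marked unrepresentable)
    has_child = {p for t in o.terms.values() for p in t.parents}
    terms_with_bricks = {t for b in o.bricks.values() for (t, _r) in b.associations}
    for t in o.terms.values():
        if t.id in has_child or t.unrepresentable:
            continue
        if t.id not in terms_with_bricks:
            diags.append(
                Diagnostic(
                    "leaf-term-no-brick",
                    t.id,
                    "term without descendants must have at least one associated brick",
                )
            )

    # brick-level rules
    for b in o.bricks.values():
        if not _CURIE_RE.match(b.id):
            diags.append(Diagnostic("brick-id-curie", b.id, "brick id is not a BKO CURIE"))
        if not b.associations:
            diags.append(
                Diagnostic("brick-no-association", b.id, "brick has no term association")
            )
        for term, relation in sorted(b.associations):
            if term not in o.terms:
                diags.append(
                    Diagnostic("association-term-unknown", b.id, f"unknown term {term!r}")
                )
            if relation not in RELATIONS:
                diags.append(
                    Diagnostic("association-relation", b.id, f"unknown relation {relation!r}")
                )
            elif relation in _AF_ER_ONLY_RELATIONS:
                allowed = _AF_ER_ONLY_RELATIONS[relation]
                if b.language not in allowed:
                    langs = "/".join(l.name for l in allowed)
                    diags.append(
                        Diagnostic(
                            "relation-language",
                            b.id,
                            f"relation {relation!r} is specific to {langs} bricks",
                        )
                    )
        for c in sorted(b.categories):
            if c not in o.categories:
                diags.append(
                    Diagnostic("brick-category-unknown", b.id, f"unknown category {c!r}")
                )
        if b.language is Language.PD and not b.glyphs:
            diags.append(Diagnostic("pd-brick-empty", b.id, "PD brick has no glyphs"))
        diags.extend(_check_brick_structure(b))

    # categories resolve and are acyclic
    cat_graph = nx.DiGraph()
    cat_graph.add_nodes_from(o.categories)
    for c in o.categories.values():
        if c.supercategory is not None:
            if c.supercategory not in o.categories:
                diags.append(
                    Diagnostic(
                        "category-unresolved", c.id, f"unknown supercategory {c.supercategory!r}"
                    )
                )
            else:
                cat_graph.add_edge(c.supercategory, c.id)
    try:
        cycle = nx.find_cycle(cat_graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        diags.append(Diagnostic("category-cycle", cycle[0][0], "supercategory cycle"))

    # subsumption edges resolve and are acyclic (identity pairs aside)
    sub_graph = nx.DiGraph()
    for a, b in sorted(o.subsumptions):
        for end in (a, b):
            if end not in o.bricks:
                diags.append(
                    Diagnostic("subsumption-unknown-brick", end, "unknown brick in subsumption")
                )
        if a != b:
            sub_graph.add_edge(a, b)
    try:
        cycle = nx.find_cycle(sub_graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        diags.append(Diagnostic("subsumption-cycle", cycle[0][0], "subsumption cycle"))

    for g in o.generic_bricks:
        if g not in o.bricks:
            diags.append(Diagnostic("generic-unknown-brick", g, "unknown generic brick"))

    return diags


def _check_brick_structure(b: TemplateBrick) -> list[Diagnostic]:
    """Per-brick structural rules: references, modifiers, role anchoring."""
    diags: list[Diagnostic] = []
    for g in b.glyphs.values():
        if g.parent is not None and g.parent not in b.glyphs:
            diags.append(
                Diagnostic("template-parent-unresolved", b.id, f"glyph {g.id!r} parent")
            )
        if g.compartment_ref is not None and g.compartment_ref not in b.glyphs:
            diags.append(
                Diagnostic(
                    "template-compartment-unresolved", b.id, f"glyph {g.id!r} compartmentRef"
                )
            )
        if (g.state is not None) != (g.cls is GlyphClass.STATE_VARIABLE):
            diags.append(
                Diagnostic(
                    "template-state", b.id, f"glyph {g.id!r}: state iff class state variable"
                )
            )
    for a in b.arcs.values():
        for end in (a.source, a.target):
            if end not in b.glyphs:
                diags.append(
                    Diagnostic("arc-endpoint-unknown", b.id, f"arc {a.id!r} endpoint {end!r}")
                )

    # repetition/absence glyphs must be anchored to exactly one role, and at
    # most one repetition glyph may occupy a given role anchor
    anchors: dict[tuple, list[str]] = {}
    for g in b.glyphs.values():
        if g.modifier is Modifier.NONE:
            continue
        roles = _template_roles(b, g)
        if len(roles) != 1:
            diags.append(
                Diagnostic(
                    "modifier-anchor",
                    b.id,
                    f"glyph {g.id!r} with {g.modifier.value} modifier must have exactly "
                    f"one role anchor (found {len(roles)})",
                )
            )
            continue
        role = roles[0]
        anchor_glyph = b.glyphs.get(role[1])
        if anchor_glyph is None or anchor_glyph.modifier is not Modifier.NONE:
            diags.append(
                Diagnostic(
                    "modifier-anchor",
                    b.id,
                    f"glyph {g.id!r} must anchor to a plain template glyph",
                )
            )
        if g.modifier is Modifier.REPETITION:
            anchors.setdefault(role, []).append(g.id)
    for role, gids in anchors.items():
        if len(gids) > 1:
            diags.append(
                Diagnostic(
                    "repetition-role-clash",
                    b.id,
                    f"glyphs {sorted(gids)} share the repetition role {role[0]} of {role[1]!r}",
                )
            )
    return diags


def _template_roles(b: TemplateBrick, g: TemplateGlyph) -> list[tuple]:
    """Roles a template glyph plays: (kind, anchor glyph id, detail)."""
    roles: list[tuple] = []
    for a in b.arcs.values():
        if a.cls is ArcClass.CONSUMPTION and a.source == g.id:
            roles.append(("reactant", a.target, None))
        elif a.cls is ArcClass.PRODUCTION and a.target == g.id:
            roles.append(("product", a.source, None))
        elif a.cls in {
            ArcClass.MODULATION,
            ArcClass.STIMULATION,
            ArcClass.INHIBITION,
            ArcClass.CATALYSIS,
            ArcClass.NECESSARY_STIMULATION,
        } and a.source == g.id:
            roles.append(("modulator", a.target, a.cls))
    if g.parent is not None:
        parent = b.glyphs.get(g.parent)
        if parent is not None:
            if g.cls in {GlyphClass.UNIT_OF_INFORMATION, GlyphClass.STATE_VARIABLE}:
                roles.append(("decoration", g.parent, None))
            else:
                roles.append(("subunit", g.parent, None))
    return roles


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def load_library(source) -> BrickOntology:
    """Load and fully validate a brick-library JSON document.

    ``source`` may be bytes, a str of JSON, a file-like object, or a path.
    Label patterns are parsed eagerly; any structural problem, unresolved
    reference or consistency violation raises LibraryLoadError with a
    JSON-pointer-style location.
    """
    if isinstance(source, bytes):
        text = source.decode("utf-8")
    elif isinstance(source, str):
        text = open(source, encoding="utf-8").read() if source.lstrip()[:1] != "{" else source
    elif hasattr(source, "read"):
        data = source.read()
        text = data.decode("utf-8") if isinstance(data, bytes) else data
    else:
        raise LibraryLoadError(f"unsupported source type {type(source).__name__}")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise LibraryLoadError(f"invalid JSON: {exc}") from None
    if not isinstance(doc, dict):
        raise LibraryLoadError("top level must be a JSON object")
    for key in ("terms", "bricks"):
        if key not in doc:
            raise LibraryLoadError(f"missing required key {key!r}", pointer=f"/{key}")

    terms: dict[str, Term] = {}
    for i, raw in enumerate(_expect_list(doc, "terms")):
        ptr = f"/terms/{i}"
        tid = _expect_str(raw, "id", ptr)
        if tid in terms:
            raise LibraryLoadError(f"duplicate term id {tid!r}", pointer=ptr)
        terms[tid] = Term(
            id=tid,
            name=_expect_str(raw, "name", ptr),
            source=raw.get("source", tid.split(":")[0]),
            parents=frozenset(raw.get("parents", [])),
            alternate_ids=frozenset(raw.get("alternate_ids", [])),
            unrepresentable=bool(raw.get("unrepresentable", False)),
        )

    categories: dict[str, Category] = {}
    for i, raw in enumerate(_expect_list(doc, "categories", required=False)):
        ptr = f"/categories/{i}"
        cid = _expect_str(raw, "id", ptr)
        if cid in categories:
            raise LibraryLoadError(f"duplicate category id {cid!r}", pointer=ptr)
        categories[cid] = Category(
            id=cid,
            name=_expect_str(raw, "name", ptr),
            supercategory=raw.get("supercategory"),
        )

    bricks: dict[str, TemplateBrick] = {}
    for i, raw in enumerate(_expect_list(doc, "bricks")):
        ptr = f"/bricks/{i}"
        bricks_entry = _load_brick(raw, ptr)
        if bricks_entry.id in bricks:
            raise LibraryLoadError(f"duplicate brick id {bricks_entry.id!r}", pointer=ptr)
        bricks[bricks_entry.id] = bricks_entry

    subsumptions: set[tuple[str, str]] = set()
    for i, raw in enumerate(_expect_list(doc, "subsumptions", required=False)):
        ptr = f"/subsumptions/{i}"
        if not (isinstance(raw, list) and len(raw) == 2):
            raise LibraryLoadError("subsumption must be a [sub, super] pair", pointer=ptr)
        subsumptions.add((raw[0], raw[1]))

    ontology = BrickOntology(
        terms=terms,
        bricks=bricks,
        categories=categories,
        subsumptions=subsumptions,
        generic_bricks=frozenset(doc.get("generic_bricks", [])),
        name=doc.get("name", "library"),
    )
    diags = check_consistency(ontology)
    if diags:
        listing = "; ".join(str(d) for d in diags[:8])
        more = f" (+{len(diags) - 8} more)" if len(diags) > 8 else ""
        raise LibraryLoadError(f"inconsistent library: {listing}{more}")
    return ontology


def _load_brick(raw: dict, ptr: str) -> TemplateBrick:
    bid = _expect_str(raw, "id", ptr)
    try:
        language = Language(raw.get("language", Language.PD.value))
    except ValueError:
        raise LibraryLoadError(
            f"unknown language {raw.get('language')!r}", pointer=f"{ptr}/language"
        ) from None
    glyphs: dict[str, TemplateGlyph] = {}
    for j, g in enumerate(_expect_list(raw, "glyphs", required=False)):
        gptr = f"{ptr}/glyphs/{j}"
        gid = _expect_str(g, "id", gptr)
        try:
            cls = GlyphClass(_expect_str(g, "class", gptr))
        except ValueError:
            raise LibraryLoadError(
                f"unknown glyph class {g.get('class')!r}", pointer=f"{gptr}/class"
            ) from None
        glyphs[gid] = TemplateGlyph(
            id=gid,
            cls=cls,
            label=_load_pattern(g.get("label", ""), f"{gptr}/label"),
            state=_load_state(g.get("state"), gptr),
            compartment_ref=g.get("compartment"),
            parent=g.get("parent"),
        )
    arcs: dict[str, Arc] = {}
    for j, a in enumerate(_expect_list(raw, "arcs", required=False)):
        aptr = f"{ptr}/arcs/{j}"
        aid = _expect_str(a, "id", aptr)
        try:
            cls = ArcClass(_expect_str(a, "class", aptr))
        except ValueError:
            raise LibraryLoadError(
                f"unknown arc class {a.get('class')!r}", pointer=f"{aptr}/class"
            ) from None
        arcs[aid] = Arc(
            id=aid,
            cls=cls,
            source=_expect_str(a, "source", aptr),
            target=_expect_str(a, "target", aptr),
        )
    associations = frozenset(
        (
            _expect_str(assoc, "term", f"{ptr}/associations/{j}"),
            _expect_str(assoc, "relation", f"{ptr}/associations/{j}"),
        )
        for j, assoc in enumerate(_expect_list(raw, "associations", required=False))
    )
    return TemplateBrick(
        id=bid,
        language=language,
        name=raw.get("name", ""),
        glyphs=glyphs,
        arcs=arcs,
        associations=associations,
        categories=frozenset(raw.get("categories", [])),
    )


def _load_pattern(text, ptr: str) -> LabelPattern:
    if not isinstance(text, str):
        raise LibraryLoadError("label pattern must be a string", pointer=ptr)
    try:
        return parse_pattern(text)
    except Exception as exc:
        raise LibraryLoadError(f"bad label pattern {text!r}: {exc}", pointer=ptr) from None


def _load_state(raw, ptr: str) -> tuple[LabelPattern, LabelPattern] | None:
    if raw is None:
        return None
    if not isinstance(raw, dict):
        raise LibraryLoadError("state must be an object", pointer=f"{ptr}/state")
    return (
        _load_pattern(raw.get("value", ""), f"{ptr}/state/value"),
        _load_pattern(raw.get("variable", ""), f"{ptr}/state/variable"),
    )


def _expect_list(doc: dict, key: str, required: bool = True) -> list:
    if key not in doc:
        if required:
            raise LibraryLoadError(f"missing required key {key!r}", pointer=f"/{key}")
        return []
    value = doc[key]
    if not isinstance(value, list):
        raise LibraryLoadError(f"{key!r} must be an array", pointer=f"/{key}")
    return value


def _expect_str(raw, key: str, ptr: str) -> str:
    if not isinstance(raw, dict) or not isinstance(raw.get(key), str) or not raw.get(key):
        raise LibraryLoadError(f"missing or empty string field {key!r}", pointer=ptr)
    return raw[key]


def save_library(o: BrickOntology) -> bytes:
    """Serialize an ontology back to the library JSON dialect (sorted, stable)."""
    doc = {
        "name": o.name,
        "terms": [
            {
                "id": t.id,
                "name": t.name,
                "source": t.source,
                "parents": sorted(t.parents),
                "alternate_ids": sorted(t.alternate_ids),
                "unrepresentable": t.unrepresentable,
            }
            for t in sorted(o.terms.values(), key=lambda t: t.id)
        ],
        "categories": [
            {"id": c.id, "name": c.name, "supercategory": c.supercategory}
            for c in sorted(o.categories.values(), key=lambda c: c.id)
        ],
        "bricks": [
            {
                "id": b.id,
                "language": b.language.value,
                "name": b.name,
                "glyphs": [
                    {
                        "id": g.id,
                        "class": g.cls.value,
                        "label": g.label.source(),
                        "state": (
                            None
                            if g.state is None
                            else {
                                "value": g.state[0].source(),
                                "variable": g.state[1].source(),
                            }
                        ),
                        "compartment": g.compartment_ref,
                        "parent": g.parent,
                    }
                    for g in sorted(b.glyphs.values(), key=lambda g: g.id)
                ],
                "arcs": [
                    {"id": a.id, "class": a.cls.value, "source": a.source, "target": a.target}
                    for a in sorted(b.arcs.values(), key=lambda a: a.id)
                ],
                "associations": [
                    {"term": t, "relation": r} for (t, r) in sorted(b.associations)
                ],
                "categories": sorted(b.categories),
            }
            for b in sorted(o.bricks.values(), key=lambda b: b.id)
        ],
        "subsumptions": sorted([list(p) for p in o.subsumptions]),
        "generic_bricks": sorted(o.generic_bricks),
    }
    return json.dumps(doc, indent=2, ensure_ascii=False).encode("utf-8")


def default_library() -> BrickOntology:
    """The library bundled with the package."""
    from importlib.resources import files

    data = files("brickmatch.data").joinpath("library.json").read_bytes()
    return load_library(data)
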