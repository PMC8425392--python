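"""In-memory model of SBGN Process Description maps and SBGN-ML I/O.

The model keeps only the semantic content of a map: glyph classes, labels,
state variables, containment (compartments, complexes, decorations) and arcs.
Geometry is deliberately absent — matching must never depend on layout — and
is synthesized on write so that emitted documents stay schema-valid.

Reading accepts the SBGN-ML milestone 0.2 and 0.3 namespaces; writing always
emits 0.2 (the dialect with the widest tool support). XML nesting of glyph
elements becomes ``parent`` links; ``compartmentRef`` attributes become
``compartment_ref`` links; ports are resolved to their owning glyph.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum

from lxml import etree

from .errors import (
    IntegrityError,
    LanguageMismatchError,
    RoleError,
    SbgnParseError,
    UnsupportedClassError,
)

NS_02 = "http://sbgn.org/libsbgn/0.2"
NS_03 = "http://sbgn.org/libsbgn/0.3"
_READ_NAMESPACES = (NS_02, NS_03)


class Language(str, Enum):
    PD = "process description"
    AF = "activity flow"
    ER = "entity relationship"


class GlyphClass(str, Enum):
    """The PD glyph classes this model supports."""

    MACROMOLECULE = "macromolecule"
    SIMPLE_CHEMICAL = "simple chemical"
    NUCLEIC_ACID_FEATURE = "nucleic acid feature"
    COMPLEX = "complex"
    UNSPECIFIED_ENTITY = "unspecified entity"
    PERTURBING_AGENT = "perturbing agent"
    SOURCE_AND_SINK = "source and sink"
    MACROMOLECULE_MULTIMER = "macromolecule multimer"
    SIMPLE_CHEMICAL_MULTIMER = "simple chemical multimer"
    NUCLEIC_ACID_FEATURE_MULTIMER = "nucleic acid feature multimer"
    COMPLEX_MULTIMER = "complex multimer"
    PROCESS = "process"
    OMITTED_PROCESS = "omitted process"
    UNCERTAIN_PROCESS = "uncertain process"
    ASSOCIATION = "association"
    DISSOCIATION = "dissociation"
    PHENOTYPE = "phenotype"
    COMPARTMENT = "compartment"
    SUBMAP = "submap"
    TAG = "tag"
    UNIT_OF_INFORMATION = "unit of information"
    STATE_VARIABLE = "state variable"


class ArcClass(str, Enum):
    CONSUMPTION = "consumption"
    PRODUCTION = "production"
    MODULATION = "modulation"
    STIMULATION = "stimulation"
    INHIBITION = "inhibition"
    CATALYSIS = "catalysis"
    NECESSARY_STIMULATION = "necessary stimulation"
    LOGIC_ARC = "logic arc"
    EQUIVALENCE_ARC = "equivalence arc"


#: Entity pool node classes (what the generic "unspecified entity" template accepts).
EPN_CLASSES = frozenset(
    {
        GlyphClass.MACROMOLECULE,
        GlyphClass.SIMPLE_CHEMICAL,
        GlyphClass.NUCLEIC_ACID_FEATURE,
        GlyphClass.COMPLEX,
        GlyphClass.UNSPECIFIED_ENTITY,
        GlyphClass.PERTURBING_AGENT,
        GlyphClass.SOURCE_AND_SINK,
        GlyphClass.MACROMOLECULE_MULTIMER,
        GlyphClass.SIMPLE_CHEMICAL_MULTIMER,
        GlyphClass.NUCLEIC_ACID_FEATURE_MULTIMER,
        GlyphClass.COMPLEX_MULTIMER,
    }
)

#: Stoichiometric process classes (what the generic "process" template accepts;
#: the phenotype glyph is explicitly excluded).
PROCESS_CLASSES = frozenset(
    {
        GlyphClass.PROCESS,
        GlyphClass.OMITTED_PROCESS,
        GlyphClass.UNCERTAIN_PROCESS,
        GlyphClass.ASSOCIATION,
        GlyphClass.DISSOCIATION,
    }
)

#: Auxiliary unit classes (decorations that completion pulls in).
AUXILIARY_CLASSES = frozenset({GlyphClass.UNIT_OF_INFORMATION, GlyphClass.STATE_VARIABLE})

MODULATION_ARC_CLASSES = frozenset(
    {
        ArcClass.MODULATION,
        ArcClass.STIMULATION,
        ArcClass.INHIBITION,
        ArcClass.CATALYSIS,
        ArcClass.NECESSARY_STIMULATION,
    }
)

# Milestone-3 spelling of the empty-set glyph.
_GLYPH_CLASS_ALIASES = {"empty set": GlyphClass.SOURCE_AND_SINK}

# Classes that belong to the other two SBGN languages; seeing one of these in a
# PD document is a language mismatch, not merely an unknown class.
_AF_ER_GLYPH_CLASSES = frozenset(
    {
        "biological activity",
        "delay",
        "existence",
        "location",
        "outcome",
        "entity",
        "interaction",
        "variable value",
        "implicit xor",
        "annotation",
    }
)
_AF_ER_ARC_CLASSES = frozenset(
    {
        "positive influence",
        "negative influence",
        "unknown influence",
        "interaction",
        "assignment",
        "absolute inhibition",
        "absolute stimulation",
        "modulation absolute",
    }
)

_PATTERN_DELIMITERS = set("$[]{}!")


@dataclass(frozen=True)
class StateValue:
    """Value/variable pair of a state variable glyph, e.g. P @ S221.

    Both fields may be empty; neither may contain pattern delimiter characters.
    """

    value: str = ""
    variable: str = ""

    def __post_init__(self):
        for text in (self.value, self.variable):
            bad = _PATTERN_DELIMITERS.intersection(text)
            if bad:
                raise IntegrityError(
                    f"state value/variable may not contain delimiter characters: {sorted(bad)}"
                )

    def display(self) -> str:
        return f"{self.value}@{self.variable}" if self.variable else self.value


@dataclass
class Glyph:
    id: str
    cls: GlyphClass
    label: str = ""
    state: StateValue | None = None
    compartment_ref: str | None = None
    parent: str | None = None
    clone: bool = False

    def __post_init__(self):
        if (self.state is not None) != (self.cls is GlyphClass.STATE_VARIABLE):
            raise IntegrityError(
                f"glyph {self.id!r}: state is present iff class is state variable"
            )


@dataclass
class Arc:
    id: str
    cls: ArcClass
    source: str
    target: str


class SbgnMap:
    """A single SBGN map: glyphs and arcs keyed by id.

    ``glyphs`` and ``arcs`` are insertion-ordered dicts; two maps compare equal
    when they have the same language and element-wise equal glyphs and arcs
    (order-insensitive).
    """

    def __init__(self, language: Language = Language.PD, id: str = "map"):
        self.language = language
        self.id = id
        self.glyphs: dict[str, Glyph] = {}
        self.arcs: dict[str, Arc] = {}

    # -- construction -----------------------------------------------------

    def add_glyph(self, glyph: Glyph) -> Glyph:
        if glyph.id in self.glyphs or glyph.id in self.arcs:
            raise IntegrityError(f"duplicate element id {glyph.id!r}")
        self.glyphs[glyph.id] = glyph
        return glyph

    def add_arc(self, arc: Arc) -> Arc:
        if arc.id in self.arcs or arc.id in self.glyphs:
            raise IntegrityError(f"duplicate element id {arc.id!r}")
        self.arcs[arc.id] = arc
        return arc

    # -- queries ----------------------------------------------------------

    def glyph(self, gid: str) -> Glyph:
        try:
            return self.glyphs[gid]
        except KeyError:
            raise IntegrityError(f"no glyph with id {gid!r}") from None

    def children(self, gid: str) -> list[Glyph]:
        return [g for g in self.glyphs.values() if g.parent == gid]

    def auxiliary_units(self, gid: str) -> list[Glyph]:
        """Units of information and state variables decorating ``gid``."""
        return [g for g in self.children(gid) if g.cls in AUXILIARY_CLASSES]

    def subunits(self, gid: str) -> list[Glyph]:
        return [g for g in self.children(gid) if g.cls in EPN_CLASSES]

    def hidden_glyphs(self) -> frozenset[str]:
        """Ids of glyphs nested (directly or transitively) inside a submap.

        Submaps are opaque: their content is retained in the model but
        excluded from matching.
        """
        hidden: set[str] = set()

        def is_hidden(g: Glyph) -> bool:
            seen = set()
            cur = g
            while cur.parent is not None and cur.parent not in seen:
                seen.add(cur.parent)
                parent = self.glyphs.get(cur.parent)
                if parent is None:
                    return False
                if parent.cls is GlyphClass.SUBMAP:
                    return True
                cur = parent
            return False

        for g in self.glyphs.values():
            if is_hidden(g):
                hidden.add(g.id)
        return frozenset(hidden)

    # -- integrity --------------------------------------------------------

    def validate(self) -> None:
        """Check all reference and containment invariants; raise IntegrityError."""
        for g in self.glyphs.values():
            if g.parent is not None and g.parent not in self.glyphs:
                raise IntegrityError(f"glyph {g.id!r}: dangling parent {g.parent!r}")
            if g.compartment_ref is not None:
                comp = self.glyphs.get(g.compartment_ref)
                if comp is None:
                    raise IntegrityError(
                        f"glyph {g.id!r}: dangling compartmentRef {g.compartment_ref!r}"
                    )
                if comp.cls is not GlyphClass.COMPARTMENT:
                    raise IntegrityError(
                        f"glyph {g.id!r}: compartmentRef {g.compartment_ref!r} "
                        "is not a compartment"
                    )
        # no containment cycles via parent
        for g in self.glyphs.values():
            seen: set[str] = set()
            cur: str | None = g.id
            while cur is not None:
                if cur in seen:
                    raise IntegrityError(f"containment cycle through glyph {cur!r}")
                seen.add(cur)
                cur = self.glyphs[cur].parent if cur in self.glyphs else None
        for a in self.arcs.values():
            for end, gid in (("source", a.source), ("target", a.target)):
                if gid not in self.glyphs:
                    raise IntegrityError(f"arc {a.id!r}: dangling {end} {gid!r}")
        # orientation invariants hold after read-time normalisation
        for a in self.arcs.values():
            if a.cls is ArcClass.CONSUMPTION:
                if self.glyphs[a.target].cls not in PROCESS_CLASSES:
                    raise IntegrityError(
                        f"consumption arc {a.id!r} must target a process-kind glyph"
                    )
            elif a.cls is ArcClass.PRODUCTION:
                if self.glyphs[a.source].cls not in PROCESS_CLASSES:
                    raise IntegrityError(
                        f"production arc {a.id!r} must source a process-kind glyph"
                    )

    # -- equality ---------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SbgnMap):
            return NotImplemented
        return (
            self.language == other.language
            and self.id == other.id
            and self.glyphs == other.glyphs
            and self.arcs == other.arcs
        )

    def __repr__(self) -> str:
        return (
            f"<SbgnMap {self.id!r} language={self.language.value!r} "
            f"glyphs={len(self.glyphs)} arcs={len(self.arcs)}>"
        )


def participants_of(
    smap: SbgnMap, process: str
) -> tuple[set[str], set[str], set[tuple[str, ArcClass]]]:
    """Classify the arcs incident to a process-kind glyph.

    Returns ``(reactants, products, modulators)`` where reactants are sources
    of consumption arcs into the process, products are targets of production
    arcs out of it, and modulators are ``(glyph id, arc class)`` pairs for
    modulation-kind arcs pointing at it. Every incident arc is classified
    exactly once.
    """
    g = smap.glyph(process)
    if g.cls not in PROCESS_CLASSES:
        raise RoleError(f"glyph {process!r} ({g.cls.value}) is not a process-kind glyph")
    reactants: set[str] = set()
    products: set[str] = set()
    modulators: set[tuple[str, ArcClass]] = set()
    for a in smap.arcs.values():
        if a.cls is ArcClass.CONSUMPTION and a.target == process:
            reactants.add(a.source)
        elif a.cls is ArcClass.PRODUCTION and a.source == process:
            products.add(a.target)
        elif a.cls in MODULATION_ARC_CLASSES and a.target == process:
            modulators.add((a.source, a.cls))
    return reactants, products, modulators


# ---------------------------------------------------------------------------
# SBGN-ML reading
# ---------------------------------------------------------------------------


def _localname(el) -> str:
    return etree.QName(el).localname


def _parse_glyph_class(raw: str, language: Language) -> GlyphClass:
    if raw in _GLYPH_CLASS_ALIASES:
        return _GLYPH_CLASS_ALIASES[raw]
    try:
        return GlyphClass(raw)
    except ValueError:
        if language is Language.PD and raw in _AF_ER_GLYPH_CLASSES:
            raise LanguageMismatchError(
                f"glyph class {raw!r} belongs to AF/ER, not to a PD map"
            ) from None
        raise UnsupportedClassError(raw, "glyph") from None


def _parse_arc_class(raw: str, language: Language) -> ArcClass:
    try:
        return ArcClass(raw)
    except ValueError:
        if language is Language.PD and raw in _AF_ER_ARC_CLASSES:
            raise LanguageMismatchError(
                f"arc class {raw!r} belongs to AF/ER, not to a PD map"
            ) from None
        raise UnsupportedClassError(raw, "arc") from None


def read_sbgnml(source) -> SbgnMap:
    """Read an SBGN-ML document (bytes, file-like object, or path).

    Milestone 0.2 and 0.3 namespaces are accepted. Nested glyph elements
    become ``parent`` links, ``compartmentRef`` attributes become
    ``compartment_ref``, ports are resolved to their owning glyph, and
    consumption/production arcs are re-oriented so that consumption always
    targets — and production always sources — the process.
    """
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    elif isinstance(source, str):
        source = open(source, "rb")
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise SbgnParseError(f"malformed XML: {exc.msg}", line=exc.lineno) from None
    root = tree.getroot()
    qname = etree.QName(root)
    if qname.namespace not in _READ_NAMESPACES:
        raise SbgnParseError(
            f"not an SBGN-ML 0.2/0.3 document (root namespace {qname.namespace!r})"
        )
    map_el = next((el for el in root if _localname(el) == "map"), None)
    if map_el is None:
        raise SbgnParseError("document has no <map> element")
    lang_raw = map_el.get("language", Language.PD.value)
    try:
        language = Language(lang_raw)
    except ValueError:
        raise SbgnParseError(f"unknown map language {lang_raw!r}") from None

    smap = SbgnMap(language=language, id=map_el.get("id", "map"))
    port_owner: dict[str, str] = {}

    def walk_glyph(el, parent_id: str | None) -> None:
        raw_cls = el.get("class", "")
        cls = _parse_glyph_class(raw_cls, language)
        gid = el.get("id")
        if gid is None:
            raise SbgnParseError("glyph without id", line=el.sourceline)
        label = ""
        state: StateValue | None = None
        clone = False
        for child in el:
            name = _localname(child)
            if name == "label":
                label = child.get("text", "") or ""
            elif name == "state":
                state = StateValue(
                    value=child.get("value", "") or "",
                    variable=child.get("variable", "") or "",
                )
            elif name == "clone":
                clone = True
            elif name == "port":
                pid = child.get("id")
                if pid:
                    port_owner[pid] = gid
        if cls is GlyphClass.STATE_VARIABLE and state is None:
            state = StateValue()
        glyph = Glyph(
            id=gid,
            cls=cls,
            label=label,
            state=state,
            compartment_ref=el.get("compartmentRef"),
            parent=parent_id,
            clone=clone,
        )
        smap.add_glyph(glyph)
        for child in el:
            if _localname(child) == "glyph":
                walk_glyph(child, gid)

    for el in map_el:
        if _localname(el) == "glyph":
            walk_glyph(el, None)

    def resolve(ref: str, arc_id: str) -> str:
        if ref in smap.glyphs:
            return ref
        if ref in port_owner:
            return port_owner[ref]
        raise IntegrityError(f"arc {arc_id!r}: dangling reference {ref!r}")

    for el in map_el:
        if _localname(el) != "arc":
            continue
        aid = el.get("id")
        if aid is None:
            raise SbgnParseError("arc without id", line=el.sourceline)
        cls = _parse_arc_class(el.get("class", ""), language)
        source_id = resolve(el.get("source", ""), aid)
        target_id = resolve(el.get("target", ""), aid)
        # Normalise orientation: the matcher assumes consumption arcs point at
        # the process and production arcs leave it.
        if language is Language.PD:
            if (
                cls is ArcClass.CONSUMPTION
                and smap.glyphs[target_id].cls not in PROCESS_CLASSES
                and smap.glyphs[source_id].cls in PROCESS_CLASSES
            ):
                source_id, target_id = target_id, source_id
            elif (
                cls is ArcClass.PRODUCTION
                and smap.glyphs[source_id].cls not in PROCESS_CLASSES
                and smap.glyphs[target_id].cls in PROCESS_CLASSES
            ):
                source_id, target_id = target_id, source_id
        smap.add_arc(Arc(id=aid, cls=cls, source=source_id, target=target_id))

    smap.validate()
    return smap


# ---------------------------------------------------------------------------
# SBGN-ML writing
# ---------------------------------------------------------------------------

_GRID = 140.0  # synthetic layout pitch; semantics never depend on it


def write_sbgnml(smap: SbgnMap) -> bytes:
    """Serialize a map as schema-valid SBGN-ML 0.2 bytes.

    Output is deterministic: glyphs and arcs are emitted sorted by id, and
    synthetic bounding boxes are laid out on a grid in that same order, so a
    given map always produces identical bytes.
    """
    smap.validate()
    nsmap = {None: NS_02}
    root = etree.Element(f"{{{NS_02}}}sbgn", nsmap=nsmap)
    map_el = etree.SubElement(root, f"{{{NS_02}}}map")
    map_el.set("language", smap.language.value)
    map_el.set("id", smap.id)

    order = {gid: i for i, gid in enumerate(sorted(smap.glyphs))}
    elements: dict[str, etree._Element] = {}

    def emit_glyph(glyph: Glyph, container) -> None:
        el = etree.SubElement(container, f"{{{NS_02}}}glyph")
        el.set("id", glyph.id)
        el.set("class", glyph.cls.value)
        if glyph.compartment_ref is not None:
            el.set("compartmentRef", glyph.compartment_ref)
        if glyph.label:
            label = etree.SubElement(el, f"{{{NS_02}}}label")
            label.set("text", glyph.label)
        if glyph.state is not None:
            state = etree.SubElement(el, f"{{{NS_02}}}state")
            if glyph.state.value:
                state.set("value", glyph.state.value)
            if glyph.state.variable:
                state.set("variable", glyph.state.variable)
        if glyph.clone:
            etree.SubElement(el, f"{{{NS_02}}}clone")
        i = order[glyph.id]
        bbox = etree.SubElement(el, f"{{{NS_02}}}bbox")
        bbox.set("x", str((i % 8) * _GRID))
        bbox.set("y", str((i // 8) * _GRID))
        bbox.set("w", "80")
        bbox.set("h", "40")
        elements[glyph.id] = el

    def emit_tree(parent_id: str | None, container) -> None:
        for gid in sorted(smap.glyphs):
            glyph = smap.glyphs[gid]
            if glyph.parent == parent_id:
                emit_glyph(glyph, container)
                emit_tree(gid, elements[gid])

    emit_tree(None, map_el)

    for aid in sorted(smap.arcs):
        arc = smap.arcs[aid]
        el = etree.SubElement(map_el, f"{{{NS_02}}}arc")
        el.set("id", arc.id)
        el.set("class", arc.cls.value)
        el.set("source", arc.source)
        el.set("target", arc.target)
        start = etree.SubElement(el, f"{{{NS_02}}}start")
        start.set("x", "0")
        start.set("y", "0")
        end = etree.SubElement(el, f"{{{NS_02}}}end")
        end.set("x", "0")
        end.set("y", "0")

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
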