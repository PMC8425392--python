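"""SBGN-ML reading/writing and the map model."""

import pytest

from brickmatch.errors import (
    IntegrityError,
    LanguageMismatchError,
    RoleError,
    SbgnParseError,
    UnsupportedClassError,
)
from brickmatch.fixtures import random_pd_map
from brickmatch.sbgn import (
    Arc,
    ArcClass,
    Glyph,
    GlyphClass,
    Language,
    SbgnMap,
    StateValue,
    participants_of,
    read_sbgnml,
    write_sbgnml,
)

NS2 = "http://sbgn.org/libsbgn/0.2"
NS3 = "http://sbgn.org/libsbgn/0.3"


def doc(body, ns=NS2, language="process description"):
    return (
        f'<sbgn xmlns="{ns}"><map language="{language}" id="m">{body}</map></sbgn>'
    ).encode()


MINIMAL = """
<glyph id="nucleus" class="compartment"><label text="nucleus"/><bbox x="0" y="0" w="100" h="100"/></glyph>
<glyph id="erk" class="macromolecule" compartmentRef="nucleus"><label text="ERK"/><bbox x="10" y="10" w="40" h="20"/></glyph>
"""


class TestRead:
    def test_minimal_document(self):
        m = read_sbgnml(doc(MINIMAL))
        assert len(m.glyphs) == 2
        assert m.glyphs["erk"].compartment_ref == "nucleus"
        assert m.glyphs["erk"].label == "ERK"
        assert m.language is Language.PD

    def test_milestone_03_namespace_and_empty_set_alias(self):
        body = '<glyph id="src" class="empty set"><bbox x="0" y="0" w="10" h="10"/></glyph>'
        m = read_sbgnml(doc(body, ns=NS3))
        assert m.glyphs["src"].cls is GlyphClass.SOURCE_AND_SINK

    def test_nested_glyphs_become_parent_links(self):
        body = """
        <glyph id="mm" class="macromolecule"><label text="RSK"/>
          <glyph id="sv" class="state variable"><state value="P" variable="S221"/></glyph>
        </glyph>
        """
        m = read_sbgnml(doc(body))
        assert m.glyphs["sv"].parent == "mm"
        assert m.glyphs["sv"].state == StateValue("P", "S221")

    def test_ports_resolve_to_owning_glyph(self):
        body = """
        <glyph id="x" class="macromolecule"><label text="X"/></glyph>
        <glyph id="p" class="process"><port id="p.1"/><port id="p.2"/></glyph>
        <arc id="a1" class="consumption" source="x" target="p.1"/>
        """
        m = read_sbgnml(doc(body))
        assert m.arcs["a1"].target == "p"

    def test_consumption_orientation_normalised(self):
        # drawn process -> entity in the wild; flipped so consumption targets the process
        body = """
        <glyph id="x" class="macromolecule"><label text="X"/></glyph>
        <glyph id="p" class="process"/>
        <arc id="a1" class="consumption" source="p" target="x"/>
        """
        m = read_sbgnml(doc(body))
        assert (m.arcs["a1"].source, m.arcs["a1"].target) == ("x", "p")

    def test_malformed_xml_reports_line(self):
        with pytest.raises(SbgnParseError) as err:
            read_sbgnml(b"<sbgn xmlns='http://sbgn.org/libsbgn/0.2'>\n<map>\n</sbgn>")
        assert err.value.line is not None

    def test_unknown_class_named_in_error(self):
        with pytest.raises(UnsupportedClassError) as err:
            read_sbgnml(doc('<glyph id="g" class="flux capacitor"/>'))
        assert "flux capacitor" in str(err.value)

    def test_af_class_in_pd_document_is_language_mismatch(self):
        with pytest.raises(LanguageMismatchError):
            read_sbgnml(doc('<glyph id="g" class="biological activity"/>'))
        with pytest.raises(LanguageMismatchError):
            read_sbgnml(
                doc(
                    '<glyph id="a" class="macromolecule"/>'
                    '<glyph id="b" class="macromolecule"/>'
                    '<arc id="x" class="positive influence" source="a" target="b"/>'
                )
            )

    def test_dangling_reference_named_in_error(self):
        with pytest.raises(IntegrityError) as err:
            read_sbgnml(
                doc(
                    '<glyph id="a" class="macromolecule"/>'
                    '<arc id="x" class="consumption" source="a" target="ghost"/>'
                )
            )
        assert "ghost" in str(err.value)


class TestWrite:
    def test_empty_map_is_valid(self):
        data = write_sbgnml(SbgnMap())
        m = read_sbgnml(data)
        assert not m.glyphs and not m.arcs

    def test_output_is_deterministic(self, figures):
        for m in figures.values():
            assert write_sbgnml(m) == write_sbgnml(m)

    def test_state_variable_gets_synthesized_geometry(self):
        m = SbgnMap()
        m.add_glyph(Glyph("mm", GlyphClass.MACROMOLECULE, "X"))
        m.add_glyph(
            Glyph("sv", GlyphClass.STATE_VARIABLE, state=StateValue("P"), parent="mm")
        )
        data = write_sbgnml(m)
        assert b"bbox" in data
        assert read_sbgnml(data) == m

    def test_invariant_violation_rejected_before_output(self):
        m = SbgnMap()
        m.add_glyph(Glyph("a", GlyphClass.MACROMOLECULE, "A"))
        m.add_arc(Arc("x", ArcClass.CONSUMPTION, "a", "missing"))
        with pytest.raises(IntegrityError):
            write_sbgnml(m)


class TestRoundTrip:
    def test_figures_round_trip(self, figures):
        for name, m in figures.items():
            assert read_sbgnml(write_sbgnml(m)) == m, name

    def test_random_maps_round_trip(self, library):
        """Write/read is the identity on the typed model for 200 random maps."""
        pool = sorted(b.id for b in library.pd_bricks())
        for seed in range(200):
            brick = pool[seed % len(pool)]
            m, _records = random_pd_map(seed, 2, 1, {brick}, library=library)
            assert read_sbgnml(write_sbgnml(m)) == m, (seed, brick)


class TestModel:
    def test_state_iff_state_variable_class(self):
        with pytest.raises(IntegrityError):
            Glyph("g", GlyphClass.MACROMOLECULE, state=StateValue("P"))
        with pytest.raises(IntegrityError):
            Glyph("g", GlyphClass.STATE_VARIABLE)

    def test_state_value_rejects_delimiters(self):
        with pytest.raises(IntegrityError):
            StateValue(value="P$")

    def test_containment_cycle_detected(self):
        m = SbgnMap()
        m.add_glyph(Glyph("a", GlyphClass.COMPLEX, parent="b"))
        m.add_glyph(Glyph("b", GlyphClass.COMPLEX, parent="a"))
        with pytest.raises(IntegrityError):
            m.validate()

    def test_hidden_glyphs_are_submap_contents(self, figures):
        hidden = figures["fig1"].hidden_glyphs()
        assert "sm_mek" in hidden and "sm_p" in hidden
        assert "erk" not in hidden and "mapk_sm" not in hidden


class TestParticipants:
    def test_fig10a_counts(self, figures):
        reactants, products, modulators = participants_of(figures["fig10a"], "p")
        assert len(reactants) == 3 and len(products) == 3
        assert modulators == {("enzyme", ArcClass.CATALYSIS)}

    def test_fig10b_reactants_include_atp(self, figures):
        reactants, _products, _mod = participants_of(figures["fig10b"], "p")
        assert "atp" in reactants

    def test_process_with_no_arcs(self):
        m = SbgnMap()
        m.add_glyph(Glyph("p", GlyphClass.PROCESS))
        assert participants_of(m, "p") == (set(), set(), set())

    def test_non_process_raises_role_error(self, figures):
        with pytest.raises(RoleError):
            participants_of(figures["fig10a"], "enzyme")

    def test_incident_arcs_partitioned_exactly_once(self, figures):
        """Every arc touching a process is classified in exactly one bucket."""
        for m in figures.values():
            for g in m.glyphs.values():
                if g.cls.value not in (
                    "process", "omitted process", "uncertain process",
                    "association", "dissociation",
                ):
                    continue
                reactants, products, modulators = participants_of(m, g.id)
                incident = [
                    a for a in m.arcs.values() if g.id in (a.source, a.target)
                ]
                assert len(incident) >= len(reactants) + len(products) + len(modulators)
                classified = 0
                for a in incident:
                    buckets = 0
                    if a.cls is ArcClass.CONSUMPTION and a.target == g.id:
                        assert a.source in reactants
                        buckets += 1
                    if a.cls is ArcClass.PRODUCTION and a.source == g.id:
                        assert a.target in products
                        buckets += 1
                    if (
                        a.cls.value in (
                            "modulation", "stimulation", "inhibition",
                            "catalysis", "necessary stimulation",
                        )
                        and a.target == g.id
                    ):
                        assert (a.source, a.cls) in modulators
                        buckets += 1
                    assert buckets <= 1
                    classified += buckets
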