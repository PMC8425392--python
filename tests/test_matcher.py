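"""Matching semantics: compatibility, instances, completion, construction."""

import random

import pytest

from brickmatch.errors import MissingBindingError, UsageError
from brickmatch.fixtures import random_pd_map
from brickmatch.matching import (
    Subsumption,
    arc_compatible,
    complete_match,
    find_matches,
    glyph_compatible,
    infer_subsumption,
    instantiate,
    required_variables,
)
from brickmatch.patterns import Modifier
from brickmatch.sbgn import (
    Arc,
    ArcClass,
    Glyph,
    GlyphClass,
    Language,
    SbgnMap,
    StateValue,
)

from _oracles import oracle_find_matches


def _mm(mid, label, uoi=None):
    m = SbgnMap()
    m.add_glyph(Glyph(mid, GlyphClass.MACROMOLECULE, label))
    if uoi:
        m.add_glyph(
            Glyph(f"{mid}_u", GlyphClass.UNIT_OF_INFORMATION, uoi, parent=mid)
        )
    return m


class TestGlyphCompatibility:
    def test_unspecified_entity_matches_any_entity_pool(self):
        m = SbgnMap()
        m.add_glyph(Glyph("atp", GlyphClass.SIMPLE_CHEMICAL, "ATP"))
        assert glyph_compatible(GlyphClass.UNSPECIFIED_ENTITY, m.glyphs["atp"], m)

    def test_material_type_rule(self):
        m = _mm("g", "glycogen", uoi="mt:psac")
        assert not glyph_compatible(GlyphClass.MACROMOLECULE, m.glyphs["g"], m)
        m2 = _mm("p", "ERK", uoi="mt:prot")
        assert glyph_compatible(GlyphClass.MACROMOLECULE, m2.glyphs["p"], m2)
        m3 = _mm("q", "ERK")
        assert glyph_compatible(GlyphClass.MACROMOLECULE, m3.glyphs["q"], m3)

    def test_process_never_matches_phenotype(self):
        m = SbgnMap()
        m.add_glyph(Glyph("ph", GlyphClass.PHENOTYPE, "growth"))
        assert not glyph_compatible(GlyphClass.PROCESS, m.glyphs["ph"], m)

    def test_process_matches_all_stoichiometric_processes(self):
        m = SbgnMap()
        for gid, cls in (
            ("a", GlyphClass.ASSOCIATION),
            ("d", GlyphClass.DISSOCIATION),
            ("o", GlyphClass.OMITTED_PROCESS),
        ):
            m.add_glyph(Glyph(gid, cls))
            assert glyph_compatible(GlyphClass.PROCESS, m.glyphs[gid], m)

    def test_multimer_needs_same_multimer_class(self):
        m = SbgnMap()
        m.add_glyph(Glyph("mm", GlyphClass.MACROMOLECULE_MULTIMER, "dimer"))
        assert not glyph_compatible(GlyphClass.MACROMOLECULE, m.glyphs["mm"], m)
        assert glyph_compatible(GlyphClass.MACROMOLECULE_MULTIMER, m.glyphs["mm"], m)
        assert glyph_compatible(GlyphClass.UNSPECIFIED_ENTITY, m.glyphs["mm"], m)


class TestArcCompatibility:
    @pytest.mark.parametrize(
        "template,instance,expected",
        [
            (ArcClass.STIMULATION, ArcClass.CATALYSIS, True),
            (ArcClass.STIMULATION, ArcClass.NECESSARY_STIMULATION, True),
            (ArcClass.CATALYSIS, ArcClass.STIMULATION, False),
            (ArcClass.MODULATION, ArcClass.INHIBITION, True),
            (ArcClass.MODULATION, ArcClass.CATALYSIS, True),
            (ArcClass.INHIBITION, ArcClass.MODULATION, False),
            (ArcClass.CONSUMPTION, ArcClass.CONSUMPTION, True),
            (ArcClass.CONSUMPTION, ArcClass.PRODUCTION, False),
        ],
    )
    def test_examples(self, template, instance, expected):
        assert arc_compatible(template, instance) is expected

    def test_hierarchy_is_reflexive_transitive_closure(self):
        """Over the five modulation classes, compatibility equals the
        reflexive-transitive closure of the generalisation edges."""
        edges = {
            (ArcClass.MODULATION, ArcClass.STIMULATION),
            (ArcClass.MODULATION, ArcClass.INHIBITION),
            (ArcClass.STIMULATION, ArcClass.CATALYSIS),
            (ArcClass.STIMULATION, ArcClass.NECESSARY_STIMULATION),
        }
        classes = [
            ArcClass.MODULATION, ArcClass.STIMULATION, ArcClass.INHIBITION,
            ArcClass.CATALYSIS, ArcClass.NECESSARY_STIMULATION,
        ]
        closure = {(c, c) for c in classes} | set(edges)
        changed = True
        while changed:
            changed = False
            for (a, b) in list(closure):
                for (c, d) in edges:
                    if b == c and (a, d) not in closure:
                        closure.add((a, d))
                        changed = True
        for a in classes:
            for b in classes:
                assert arc_compatible(a, b) == ((a, b) in closure)


class TestFindMatches:
    def test_three_phosphorylations_in_fig1(self, library, figures):
        inst = find_matches(library.bricks["BKO:0000440"], figures["fig1"])
        assert len(inst) == 3

    def test_passive_transport_rejects_atp_consumption(self, library, figures):
        assert find_matches(library.bricks["BKO:0000492"], figures["fig10b"]) == []

    def test_repetition_binds_remaining_substrates(self, library, figures):
        inst = find_matches(library.bricks["BKO:0000197"], figures["fig10a"])
        assert len(inst) == 1
        assert len(inst[0].match.repetition["substrate_n"]) == 2
        assert len(inst[0].match.repetition["product_m"]) == 2

    def test_empty_map_matches_nothing(self, library):
        empty = SbgnMap()
        for brick in library.pd_bricks():
            assert find_matches(brick, empty) == []

    def test_variable_consistency_across_glyphs(self, library, figures):
        """The translocation brick matches ERK/ERK but never ERK-cyt/ERK-nuc."""
        inst = find_matches(library.bricks["BKO:0000484"], figures["fig9b"])
        assert len(inst) == 1
        assert inst[0].match.bindings == {
            "UNSPEC": "ERK", "COMP_1": "cytosol", "COMP": "nucleus",
        }
        assert "erkcyt" not in inst[0].elements

    def test_language_mismatch_is_usage_error(self, library):
        af_map = SbgnMap(language=Language.AF)
        with pytest.raises(UsageError):
            find_matches(library.bricks["BKO:0000440"], af_map)
        pd_map = SbgnMap()
        with pytest.raises(UsageError):
            find_matches(library.bricks["BKO:0000231"], pd_map)

    def test_submap_content_is_opaque(self, library, figures):
        """The phosphorylation hidden in the MAPK-cascade submap is not counted."""
        fig1 = figures["fig1"]
        inst = find_matches(library.bricks["BKO:0000440"], fig1)
        for i in inst:
            assert "sm_p" not in i.elements

    def test_isolated_glyph_leaves_matches_unchanged(self, library, figures):
        for name in ("fig1", "fig10a", "fig10b"):
            base = figures[name]
            grown = SbgnMap(id=base.id)
            for g in base.glyphs.values():
                grown.add_glyph(g)
            for a in base.arcs.values():
                grown.add_arc(a)
            grown.add_glyph(Glyph("loner", GlyphClass.MACROMOLECULE, "zz"))
            for brick in library.pd_bricks():
                before = {i.elements for i in find_matches(brick, base)}
                after = {i.elements for i in find_matches(brick, grown)}
                assert before == after, (name, brick.id)

    def test_no_two_results_share_identity(self, library, figures):
        for smap in figures.values():
            for brick in library.pd_bricks():
                inst = find_matches(brick, smap)
                assert len({i.identity for i in inst}) == len(inst)

    def test_agrees_with_exhaustive_oracle_on_small_maps(self, library):
        """Spot check against the exhaustive enumeration oracle (the full
        500-case sweep runs in the acceptance suite)."""
        pool = sorted(b.id for b in library.pd_bricks())
        for seed in range(40):
            brick = library.bricks[pool[seed % len(pool)]]
            smap, _records = random_pd_map(seed, 1, 1, {brick.id}, library=library)
            got = [(i.brick, i.elements) for i in find_matches(brick, smap)]
            want = [(i.brick, i.elements) for i in oracle_find_matches(brick, smap)]
            assert got == want, (seed, brick.id)


class TestCompletion:
    def test_atp_adp_pulled_into_phosphorylation_instance(self, library, figures):
        inst = find_matches(library.bricks["BKO:0000440"], figures["fig1"])
        p2 = next(i for i in inst if "p2" in i.elements)
        assert {"atp", "adp", "a_p2_atp", "a_p2_adp"} <= p2.elements

    def test_compartment_of_matched_glyph_included(self, library, figures):
        inst = find_matches(library.bricks["BKO:0000440"], figures["fig1"])
        p3 = next(i for i in inst if "p3" in i.elements)
        assert "nucleus" in p3.elements

    def test_completion_is_idempotent(self, library, figures):
        for smap in figures.values():
            for brick in library.pd_bricks():
                for inst in find_matches(brick, smap):
                    again = complete_match(inst.match, smap)
                    twice = complete_match(
                        type(inst.match)(
                            brick=inst.match.brick,
                            assignment=inst.match.assignment,
                            repetition=inst.match.repetition,
                            bindings=inst.match.bindings,
                            core=inst.elements,
                        ),
                        smap,
                    )
                    assert again.elements == inst.elements
                    assert twice.elements == inst.elements


class TestInstantiate:
    def test_phosphorylation_of_rsk_at_s221(self, library):
        m = instantiate(
            library.bricks["BKO:0000440"],
            {"LABEL": "RSK", "RES": "S221"},
            {},
            keep_optionals=True,
        )
        macromolecules = [
            g for g in m.glyphs.values() if g.cls is GlyphClass.MACROMOLECULE
        ]
        assert sorted(g.label for g in macromolecules) == ["RSK", "RSK"]
        assert m.glyphs["product_sv"].state == StateValue("P", "S221")
        assert m.glyphs["substrate_sv"].state == StateValue("", "S221")
        assert any(g.cls is GlyphClass.PROCESS for g in m.glyphs.values())

    def test_zero_repetitions_give_minimal_reaction(self, library):
        m = instantiate(
            library.bricks["BKO:0000197"],
            {"ENZYME": "E", "SUBSTRATE_1": "s", "PRODUCT_1": "p"},
            {"substrate_n": 0, "product_m": 0},
            keep_optionals=False,
        )
        chemicals = [
            g for g in m.glyphs.values() if g.cls is GlyphClass.SIMPLE_CHEMICAL
        ]
        assert len(chemicals) == 2

    def test_repetition_copies_use_suffixed_variables(self, library):
        m = instantiate(
            library.bricks["BKO:0000197"],
            {
                "ENZYME": "E", "SUBSTRATE_1": "s", "PRODUCT_1": "p",
                "SUBSTRATE_N_1": "s2", "SUBSTRATE_N_2": "s3",
            },
            {"substrate_n": 2, "product_m": 0},
            keep_optionals=False,
        )
        assert m.glyphs["substrate_n_1"].label == "s2"
        assert m.glyphs["substrate_n_2"].label == "s3"

    def test_missing_binding_raises(self, library):
        with pytest.raises(MissingBindingError):
            instantiate(library.bricks["BKO:0000440"], {"LABEL": "RSK"}, {}, True)

    def test_positive_count_for_absence_glyph_rejected(self, library):
        with pytest.raises(UsageError):
            instantiate(
                library.bricks["BKO:0000492"],
                {"SOLUTE": "glc", "COMP": "cell"},
                {"no_atp": 1},
                False,
            )

    def test_round_trip_every_bundled_brick(self, library):
        """Instantiations are always matched back by their source brick."""
        rng = random.Random(11)
        for brick in library.pd_bricks():
            reps = sorted(
                g.id for g in brick.glyphs.values()
                if g.modifier is Modifier.REPETITION
            )
            for trial in range(5):
                counts = {r: rng.randint(0, 2) for r in reps}
                keep = trial % 2 == 0
                names = sorted(required_variables(brick, keep, counts))
                bindings = {
                    n: "".join(rng.choice("nopq") for _ in range(rng.randint(2, 6)))
                    for n in names
                }
                m = instantiate(brick, bindings, counts, keep)
                inst = find_matches(brick, m)
                assert inst, (brick.id, counts, keep)
                covered = set().union(*(i.elements for i in inst))
                assert set(m.glyphs) <= covered, brick.id


class TestSubsumption:
    def test_phosphorylation_under_generic_process(self, library):
        a = library.bricks["BKO:0000440"]
        b = library.bricks["BKO:0000901"]
        assert infer_subsumption(a, b) is Subsumption.SUBSUMES
        assert infer_subsumption(b, a) is Subsumption.NOT_SUBSUMES

    def test_reflexive_on_every_bundled_brick(self, library):
        for brick in library.pd_bricks():
            assert infer_subsumption(brick, brick) is Subsumption.SUBSUMES

    def test_sibling_bricks_do_not_subsume(self, library):
        a = library.bricks["BKO:0000484"]  # translocation
        b = library.bricks["BKO:0000440"]  # phosphorylation
        assert infer_subsumption(a, b) is Subsumption.NOT_SUBSUMES

    def test_recorded_pairs_confirmed(self, library):
        for sub, sup in sorted(library.subsumptions):
            assert (
                infer_subsumption(library.bricks[sub], library.bricks[sup])
                is Subsumption.SUBSUMES
            ), (sub, sup)
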