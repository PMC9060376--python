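"""Species identity, propensity evaluation, reactions and CRN assembly."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from crnforge.core import (
    CRN,
    ComplexSpecies,
    CRNForgeError,
    Propensity,
    PropensityError,
    Reaction,
    Species,
    SpeciesError,
    assemble_crn,
    canonical_name,
    evaluate_propensity,
    make_complex,
    reversible_pair,
)

from conftest import simple_species, species_trees


class TestSpecies:
    def test_canonical_name_material_prefix(self):
        assert canonical_name(Species("X", "dna")) == "dna_X"
        assert canonical_name(Species("X", "rna")) == "rna_X"
        assert canonical_name(Species("P")) == "P"  # untyped: bare name

    def test_attributes_sorted_and_deduplicated(self):
        sp = Species("X", "rna", ["b", "a", "b"])
        assert sp.attributes == ("b", "a")
        assert sp.canonical_name == "rna_X_a_b"

    @pytest.mark.parametrize("bad", ["", "a b", "a_b", "x:y", "dna", "complex",
                                     "complex2", "none", "(a)"])
    def test_invalid_names_rejected(self, bad):
        with pytest.raises(SpeciesError):
            Species(bad, "protein")

    def test_equality_is_structural(self):
        assert Species("X", "dna") == Species("X", "dna")
        assert Species("X", "dna") != Species("X", "rna")
        assert Species("X", "dna") != Species("X", "dna", ["tag1"])
        assert len({Species("X", "dna"), Species("X", "dna")}) == 1

    def test_complex_display_and_canonical(self):
        cx = make_complex([Species("X", "dna"), Species("P", "protein")])
        assert cx.display == "dna_X:protein_P"
        assert cx.canonical_name == "complex_dna_X_protein_P"
        assert cx.material_type == "complex"

    def test_complex_requires_two_members(self):
        with pytest.raises(SpeciesError):
            make_complex([Species("G", "dna")])

    def test_nested_complex_not_flattened(self):
        a, b, c = (Species(n) for n in "abc")
        nested = make_complex([make_complex([a, b]), c])
        flat = make_complex([a, b, c])
        assert nested.display == flat.display == "a:b:c"
        assert nested != flat
        assert nested.canonical_name != flat.canonical_name

    def test_member_order_matters(self):
        a, b = Species("a"), Species("b")
        assert make_complex([a, b]) != make_complex([b, a])

    @given(st.lists(species_trees, min_size=2, max_size=12))
    def test_canonical_name_injective(self, species):
        """Distinct species never share a canonical name (random trees)."""
        for x, y in itertools.combinations(species, 2):
            if x.canonical_name == y.canonical_name:
                assert x == y


class TestPropensity:
    def test_massaction_concentration_convention(self):
        a, b = Species("a"), Species("b")
        p = Propensity.massaction(2.0)
        assert evaluate_propensity(p, {a: 1, b: 1}, {a: 3, b: 4}) == 24
        # repeated input uses s^2, not s*(s-1)
        assert evaluate_propensity(Propensity.massaction(1.0), {a: 2}, {a: 3}) == 9

    def test_hill_negative_half_saturation(self):
        r, d = Species("r"), Species("d")
        p = Propensity.hill_negative(k=1, K=2, n=2, regulator=r, scaler=d)
        assert evaluate_propensity(p, {d: 1}, {r: 2, d: 1}) == pytest.approx(0.5)

    def test_hill_scaler_defaults_to_one(self):
        r = Species("r")
        p = Propensity.hill_positive(k=3, K=1, n=1, regulator=r)
        assert evaluate_propensity(p, {}, {r: 1}) == pytest.approx(1.5)

    @given(
        st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.2, 4),
        st.floats(0, 100), st.floats(0, 50),
    )
    def test_hill_pair_partition_of_unity(self, k, K, n, r_val, d_val):
        """hill_negative + hill_positive with shared parameters sum to k*d."""
        r, d = Species("r"), Species("d")
        state = {r: r_val, d: d_val}
        total = sum(
            evaluate_propensity(ctor(k=k, K=K, n=n, regulator=r, scaler=d), {}, state)
            for ctor in (Propensity.hill_negative, Propensity.hill_positive)
        )
        assert total == pytest.approx(k * d_val, rel=1e-9)

    @given(st.floats(0.1, 5), st.integers(1, 3), st.integers(1, 3))
    def test_massaction_homogeneity(self, c, na, nb):
        """Scaling the state by c scales the rate by c^(total multiplicity)."""
        a, b = Species("a"), Species("b")
        p = Propensity.massaction(1.7)
        inputs = {a: na, b: nb}
        base = evaluate_propensity(p, inputs, {a: 2.0, b: 3.0})
        scaled = evaluate_propensity(p, inputs, {a: 2.0 * c, b: 3.0 * c})
        assert scaled == pytest.approx(base * c ** (na + nb), rel=1e-9)

    def test_invalid_hill_parameters_rejected(self):
        r = Species("r")
        with pytest.raises(PropensityError):
            Propensity.hill_negative(k=1, K=0, n=2, regulator=r)
        with pytest.raises(PropensityError):
            Propensity.hill_negative(k=1, K=1, n=-1, regulator=r)
        with pytest.raises(PropensityError):
            Propensity("hill_negative", {"k": 1, "K": 1, "n": 1})  # no regulator

    def test_missing_and_negative_state_rejected(self):
        a = Species("a")
        p = Propensity.massaction(1.0)
        with pytest.raises(PropensityError):
            evaluate_propensity(p, {a: 1}, {})
        with pytest.raises(PropensityError):
            evaluate_propensity(p, {a: 1}, {a: -1.0})

    def test_general_expression(self):
        a = Species("a", "protein")
        p = Propensity.general("v * protein_a / (km + protein_a)", v=2.0, km=1.0)
        assert evaluate_propensity(p, {a: 1}, {a: 1.0}) == pytest.approx(1.0)

    def test_general_expression_rejects_unsafe_syntax(self):
        with pytest.raises(PropensityError):
            Propensity.general("__import__('os')")


class TestReaction:
    def test_both_sides_empty_rejected(self):
        with pytest.raises(CRNForgeError):
            Reaction({}, {}, Propensity.massaction(1.0))

    def test_one_empty_side_allowed(self):
        a = Species("a")
        degradation = Reaction.massaction({a: 1}, {}, 0.1)
        assert str(degradation) == "a --0.1--> ∅"

    def test_reversible_pair_mirrors(self):
        g = Species("G", "dna")
        p = Species("P", "protein")
        gp = make_complex([g, p])
        fwd, rev = reversible_pair({g: 1, p: 1}, {gp: 1}, 100, 10)
        assert fwd.inputs == rev.outputs and fwd.outputs == rev.inputs
        assert fwd.propensity.parameters["k"] == 100
        assert rev.propensity.parameters["k"] == 10

    def test_zero_rate_reaction_retained(self):
        a, b = Species("a"), Species("b")
        fwd, _ = reversible_pair({a: 1}, {b: 1}, 0.0, 1.0)
        assert fwd.propensity.parameters["k"] == 0.0

    def test_symmetric_pair(self):
        a, b = Species("a"), Species("b")
        fwd, rev = reversible_pair({a: 1}, {b: 1}, 2.0, 2.0)
        assert fwd == Reaction.massaction({a: 1}, {b: 1}, 2.0)
        assert rev == Reaction.massaction({b: 1}, {a: 1}, 2.0)

    def test_equality_ignores_input_listing_order(self):
        a, b, c = Species("a"), Species("b"), Species("c")
        r1 = Reaction.massaction([a, b], [c], 1.0)
        r2 = Reaction.massaction([b, a], [c], 1.0)
        assert r1 == r2 and hash(r1) == hash(r2)


class TestCRNAssembly:
    def test_species_deduplicated_with_warning(self, caplog):
        x = Species("X", "dna")
        with caplog.at_level("WARNING"):
            crn = assemble_crn([x, Species("X", "dna")], [])
        assert len(crn.species) == 1
        assert "duplicate species" in caplog.text

    def test_reaction_participants_auto_added(self):
        x, y = Species("X", "dna"), Species("Y", "rna")
        crn = assemble_crn([], [Reaction.massaction({x: 1}, {x: 1, y: 1}, 0.1)])
        assert crn.species == [x, y]

    def test_duplicate_reactions_deduplicated_with_warning(self, caplog):
        x = Species("X")
        rx = Reaction.massaction({x: 1}, {}, 1.0)
        with caplog.at_level("WARNING"):
            crn = assemble_crn([], [rx, Reaction.massaction({x: 1}, {}, 1.0)])
        assert len(crn.reactions) == 1
        assert "duplicate reaction" in caplog.text

    def test_assembly_idempotent(self):
        x, y = Species("X", "dna"), Species("Y", "rna")
        reactions = [
            Reaction.massaction({x: 1}, {x: 1, y: 1}, 0.1),
            Reaction.massaction({y: 1}, {}, 0.2),
        ]
        once = assemble_crn([x], reactions)
        twice = assemble_crn(once.species, once.reactions)
        assert once == twice
        assert once.pretty_print() == twice.pretty_print()

    def test_hill_regulator_included_in_species_closure(self):
        d, t, r = Species("d", "dna"), Species("t", "rna"), Species("r", "protein")
        rx = Reaction({d: 1}, {d: 1, t: 1},
                      Propensity.hill_negative(1, 1, 1, regulator=r, scaler=d))
        crn = assemble_crn([], [rx])
        assert r in crn.species

    def test_graph_export_bipartite_edges(self):
        x, y = Species("X", "dna"), Species("Y", "rna")
        crn = assemble_crn([], [Reaction.massaction({x: 1}, {x: 1, y: 1}, 0.1)])
        assert crn.graph_edges() == ["dna_X\tr0", "r0\tdna_X", "r0\trna_Y"]
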