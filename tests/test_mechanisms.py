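"""Reaction schemas: structure, rates, machinery conservation, purity."""

from collections import Counter

import pytest

from crnforge.core import Propensity, Reaction, Species, make_complex
from crnforge.mechanisms import (
    ConfigurationError,
    MachinerySpecies,
    hill_transcription_update,
    mm_catalysis_update,
    mm_degradation_update,
    mm_transcription_update,
    mm_translation_update,
    multi_occupancy_transcription_update,
    one_step_binding_update,
    simple_transcription_update,
    simple_translation_update,
)

DNA = Species("X", "dna")
RNA = Species("X", "rna")
PROT = Species("X", "protein")
P = Species("P")
R = Species("R")
RNASE = Species("RNase")


def content(species, target):
    """Copies of *target* inside *species*, counting complex members."""
    if species == target:
        return 1
    if isinstance(species, type(make_complex([P, R]))):
        return sum(content(m, target) for m in species.members)
    return 0


def machinery_conserved(reactions, machinery):
    """True iff every reaction conserves total *machinery* content
    (free plus bound inside complexes)."""
    for rx in reactions:
        produced = sum(n * content(sp, machinery) for sp, n in rx.outputs)
        consumed = sum(n * content(sp, machinery) for sp, n in rx.inputs)
        if produced != consumed:
            return False
    return True


class TestSimpleSchemas:
    def test_simple_transcription_single_catalytic_reaction(self):
        species, reactions = simple_transcription_update(DNA, RNA, 0.1)
        assert reactions == [Reaction.massaction({DNA: 1}, {DNA: 1, RNA: 1}, 0.1)]
        assert set(species) == {DNA, RNA}

    def test_simple_translation_mirrors_transcription(self):
        _, reactions = simple_translation_update(RNA, PROT, 0.5)
        assert reactions == [Reaction.massaction({RNA: 1}, {RNA: 1, PROT: 1}, 0.5)]

    def test_zero_rate_structure_retained(self):
        _, reactions = simple_transcription_update(DNA, RNA, 0.0)
        assert reactions[0].propensity.parameters["k"] == 0.0

    def test_identical_template_and_product_rejected(self):
        with pytest.raises(ConfigurationError):
            simple_transcription_update(DNA, DNA, 0.1)
        with pytest.raises(ConfigurationError):
            simple_translation_update(RNA, RNA, 0.5)


class TestMichaelisMentenSchemas:
    def test_mm_transcription_reactions_and_species(self):
        species, reactions = mm_transcription_update(DNA, RNA, P, 100, 10, 0.1)
        bound = make_complex([DNA, P])
        assert set(species) == {DNA, P, bound, RNA}
        assert reactions == [
            Reaction.massaction({DNA: 1, P: 1}, {bound: 1}, 100),
            Reaction.massaction({bound: 1}, {DNA: 1, P: 1}, 10),
            Reaction.massaction({bound: 1}, {DNA: 1, P: 1, RNA: 1}, 0.1),
        ]

    def test_mm_translation_reactions_and_species(self):
        species, reactions = mm_translation_update(RNA, PROT, R, 100, 10, 0.5)
        bound = make_complex([RNA, R])
        assert set(species) == {RNA, R, bound, PROT}
        assert reactions == [
            Reaction.massaction({RNA: 1, R: 1}, {bound: 1}, 100),
            Reaction.massaction({bound: 1}, {RNA: 1, R: 1}, 10),
            Reaction.massaction({bound: 1}, {RNA: 1, R: 1, PROT: 1}, 0.5),
        ]

    @pytest.mark.parametrize("machinery,update,args", [
        (P, mm_transcription_update, (DNA, RNA)),
        (R, mm_translation_update, (RNA, PROT)),
    ])
    def test_machinery_conserved_over_catalytic_cycle(self, machinery, update, args):
        _, reactions = update(*args, machinery, 100, 10, 1.0)
        assert machinery_conserved(reactions, machinery)

    def test_zero_unbinding_rate_still_emitted(self):
        _, reactions = mm_transcription_update(DNA, RNA, P, 100, 0, 0.1)
        assert reactions[1].propensity.parameters["k"] == 0.0

    def test_purity_identical_calls_identical_output(self):
        assert mm_transcription_update(DNA, RNA, P, 100, 10, 0.1) == \
            mm_transcription_update(DNA, RNA, P, 100, 10, 0.1)


class TestHillTranscription:
    def test_repression_limits(self):
        reg = Species("rep", "protein")
        _, reactions = hill_transcription_update(DNA, RNA, reg, "negative",
                                                 ktx=0.1, K=2, n=2)
        prop = reactions[0].propensity
        from crnforge.core import evaluate_propensity
        # absent repressor: full rate ktx * [dna]
        assert evaluate_propensity(prop, {DNA: 1}, {reg: 0, DNA: 3.0}) == \
            pytest.approx(0.3)
        # saturating repressor: rate -> 0
        assert evaluate_propensity(prop, {DNA: 1}, {reg: 1e9, DNA: 3.0}) == \
            pytest.approx(0.0, abs=1e-12)

    def test_leak_adds_massaction_reaction(self):
        reg = Species("rep", "protein")
        _, reactions = hill_transcription_update(DNA, RNA, reg, "negative",
                                                 ktx=0.1, K=2, n=2, leak=0.01)
        assert len(reactions) == 2
        assert reactions[1].propensity == Propensity.massaction(0.01)

    def test_invalid_hill_parameters(self):
        reg = Species("rep", "protein")
        with pytest.raises(Exception):
            hill_transcription_update(DNA, RNA, reg, "negative", 0.1, K=0, n=2)
        with pytest.raises(Exception):
            hill_transcription_update(DNA, RNA, reg, "negative", 0.1, K=2, n=0)


def brute_force_occupancy_model(m, kb, ku, ktx):
    """Independent enumeration of the occupancy ladder's states/transitions."""
    states = {0: DNA}
    for i in range(1, m + 1):
        states[i] = make_complex([DNA] + [P] * i)
    reactions = set()
    for i in range(1, m + 1):
        reactions.add(Reaction.massaction({states[i - 1]: 1, P: 1}, {states[i]: 1}, kb))
        reactions.add(Reaction.massaction({states[i]: 1}, {states[i - 1]: 1, P: 1},
                                          i * ku))
        reactions.add(Reaction.massaction(
            {states[i]: 1}, {states[i - 1]: 1, P: 1, RNA: 1}, i * ktx))
    return set(states.values()) | {P, RNA}, reactions


class TestMultiOccupancy:
    def test_m1_identical_to_mm_transcription(self):
        mm_species, mm_reactions = mm_transcription_update(DNA, RNA, P, 100, 10, 0.1)
        mo_species, mo_reactions = multi_occupancy_transcription_update(
            DNA, RNA, P, 1, 100, 10, 0.1)
        assert set(mo_species) == set(mm_species)
        assert mo_reactions == mm_reactions

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_matches_brute_force_state_enumeration(self, m):
        species, reactions = multi_occupancy_transcription_update(
            DNA, RNA, P, m, 100, 10, 0.1)
        oracle_species, oracle_reactions = brute_force_occupancy_model(m, 100, 10, 0.1)
        assert set(species) == oracle_species
        assert set(reactions) == oracle_reactions
        assert len(reactions) == 3 * m

    def test_m3_touches_six_species(self):
        species, _ = multi_occupancy_transcription_update(DNA, RNA, P, 3, 1, 1, 1)
        assert len(set(species)) == 6  # dna + 3 occupancy states + P + transcript

    def test_invalid_occupancy(self):
        with pytest.raises(ConfigurationError):
            multi_occupancy_transcription_update(DNA, RNA, P, 0, 1, 1, 1)


class TestCatalysisBindingDegradation:
    def test_catalysis_template(self):
        E, S, Pr = Species("E", "protein"), Species("S"), Species("Pr")
        species, reactions = mm_catalysis_update(E, S, Pr, 100, 10, 1)
        bound = make_complex([E, S])
        assert bound in species
        assert len(reactions) == 3
        assert reactions[2] == Reaction.massaction({bound: 1}, {E: 1, Pr: 1}, 1)

    def test_enzyme_equal_substrate_permitted(self):
        E, Pr = Species("E", "protein"), Species("Pr")
        species, _ = mm_catalysis_update(E, E, Pr, 1, 1, 1)
        assert make_complex([E, E]) in species

    def test_substrate_equal_product_rejected(self):
        E, S = Species("E", "protein"), Species("S")
        with pytest.raises(ConfigurationError):
            mm_catalysis_update(E, S, S, 1, 1, 1)

    def test_binding_homodimer_and_ternary(self):
        A, B, C = Species("A"), Species("B"), Species("C")
        _, reactions = one_step_binding_update([A, A], 100, 10)
        assert reactions[0] == Reaction.massaction(
            Counter([A, A]), {make_complex([A, A]): 1}, 100)
        species, reactions = one_step_binding_update([A, B, C], 100, 10)
        assert make_complex([A, B, C]) in species
        assert len(reactions) == 2  # single-step ternary association

    def test_binding_requires_two_members(self):
        with pytest.raises(ConfigurationError):
            one_step_binding_update([Species("A")], 1, 1)

    def test_degradation_consumes_target_only(self):
        M = Species("M", "rna")
        species, reactions = mm_degradation_update(M, RNASE, 100, 10, 1)
        deg = reactions[2]
        assert deg.outputs == ((RNASE, 1),)
        assert machinery_conserved(reactions, RNASE)
        assert not machinery_conserved(reactions, M)  # the target is consumed
        assert make_complex([M, RNASE]) in species


def test_machinery_species_must_be_distinct():
    with pytest.raises(ConfigurationError):
        MachinerySpecies(P, P, RNASE)
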