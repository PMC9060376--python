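"""Component enumeration: fixed points, depth caps, transcript scanning.

The transcript scanner is checked against an independent oracle that works
by candidate-terminator distances rather than a positional scan: for every
promoter it ranks all in-orientation terminators by scan distance (modular
on circular DNA), picks the nearest, and collects the in-orientation
RBS/CDS parts strictly closer than it, ordered by distance.
"""

import itertools

import pytest

from crnforge.components import Component
from crnforge.enumeration import (
    ComponentEnumerator,
    DNAConstruct,
    Part,
    RNAConstruct,
    TranscriptEnumerator,
    enumerate_fixed_point,
    parse_parts,
    transcript_enumeration,
)
from crnforge.fixtures import FixtureSeed, random_construct


# ---------------------------------------------------------------------------
# fixed-point iteration with a toy global dimerizer
# ---------------------------------------------------------------------------

class Dimerizer(ComponentEnumerator):
    """Adds a component named 'a.b' for every unordered pair {a, b}."""

    scope = "global"

    @staticmethod
    def pair_name(a: str, b: str) -> str:
        return ".".join(sorted((a, b)))

    def enumerate(self, components):
        names = [c.name for c in components]
        out = []
        for a, b in itertools.combinations(names, 2):
            name = self.pair_name(a, b)
            if name not in names:
                out.append(Component(name))
        return out


def brute_force_dimer_closure(names, rounds):
    """Independent bounded closure over pair names."""
    current = set(names)
    for _ in range(rounds):
        new = {
            Dimerizer.pair_name(a, b)
            for a, b in itertools.combinations(sorted(current), 2)
        }
        nxt = current | new
        if nxt == current:
            break
        current = nxt
    return current


class TestFixedPoint:
    def test_no_enumerators_is_immediate_fixed_point(self):
        comps = [Component("a"), Component("b")]
        assert enumerate_fixed_point(comps, (), max_depth=5) == comps

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_dimerizer_matches_bounded_closure(self, depth, caplog):
        initial = [Component("a"), Component("b")]
        with caplog.at_level("WARNING"):
            result = enumerate_fixed_point(initial, [Dimerizer()], max_depth=depth)
        expected = brute_force_dimer_closure(["a", "b"], depth)
        assert {c.name for c in result} == expected
        # the cap binds iff one more round would still add components
        unbounded = brute_force_dimer_closure(["a", "b"], depth + 1)
        cap_binds = unbounded != expected
        assert ("depth cap" in caplog.text) == cap_binds

    def test_depth_one_dimerizer_small_example(self):
        result = enumerate_fixed_point(
            [Component("a"), Component("b")], [Dimerizer()], max_depth=1)
        assert {c.name for c in result} == {"a", "b", "a.b"}

    def test_output_contains_input(self):
        initial = [Component("a"), Component("b"), Component("c")]
        result = enumerate_fixed_point(initial, [Dimerizer()], max_depth=2)
        assert set(initial) <= set(result)

    def test_terminating_enumerator_reaches_fixed_point_silently(self, caplog):
        class OneShot(ComponentEnumerator):
            def enumerate(self, components):
                if not any(c.name == "extra" for c in components):
                    return [Component("extra")]
                return []

        with caplog.at_level("WARNING"):
            result = enumerate_fixed_point(
                [Component("a")], [OneShot()], max_depth=10)
        assert {c.name for c in result} == {"a", "extra"}
        assert "depth cap" not in caplog.text


# ---------------------------------------------------------------------------
# transcript enumeration vs brute-force oriented-pair oracle
# ---------------------------------------------------------------------------

def oracle_transcripts(parts, topology):
    """Distance-ranked candidate-terminator oracle (see module docstring)."""
    n = len(parts)
    circular = topology == "circular"
    result = set()
    for i, promoter in enumerate(parts):
        if promoter.part_type != "promoter":
            continue
        step = 1 if promoter.orientation == "forward" else -1

        def distance(j):
            # number of scan steps from the promoter to part j
            if circular:
                return ((j - i) * step) % n
            d = (j - i) * step
            return d if d > 0 else None

        candidates = [
            (distance(j), j) for j, p in enumerate(parts)
            if p.part_type == "terminator" and p.orientation == promoter.orientation
            and distance(j) is not None and distance(j) > 0
        ]
        stop_distance, terminator = min(candidates) if candidates else (n, None)
        contained = sorted(
            (distance(j), p.name) for j, p in enumerate(parts)
            if p.part_type in ("rbs", "cds")
            and p.orientation == promoter.orientation
            and distance(j) is not None and 0 < distance(j) < stop_distance
        )
        result.add((i, terminator, tuple(name for _, name in contained)))
    return result


def as_triples(transcripts):
    return {
        (t.promoter_index, t.terminator_index, tuple(p.name for p in t.parts))
        for t in transcripts
    }


class TestTranscriptEnumeration:
    def test_linear_terminated_transcript(self):
        c = DNAConstruct("d", "p1:promoter:forward,u1:rbs:forward,"
                              "c1:cds:forward,t1:terminator:forward")
        (t,) = transcript_enumeration(c)
        assert t.terminator_index == 3
        assert [p.name for p in t.parts] == ["u1", "c1"]

    def test_linear_runoff_without_terminator(self):
        c = DNAConstruct("d", "p1:promoter:forward,u1:rbs:forward,c1:cds:forward")
        (t,) = transcript_enumeration(c)
        assert t.runoff
        assert [p.name for p in t.parts] == ["u1", "c1"]

    def test_two_strand_construct(self):
        c = DNAConstruct("d", (
            "p1:promoter:forward,u1:rbs:forward,c1:cds:forward,"
            "t1:terminator:forward,c2:cds:reverse,u2:rbs:reverse,"
            "p2:promoter:reverse"
        ))
        assert as_triples(transcript_enumeration(c)) == oracle_transcripts(
            c.parts, c.topology)
        triples = as_triples(transcript_enumeration(c))
        # reverse promoter reads leftward: promoter-proximal part first
        assert (6, None, ("u2", "c2")) in triples

    def test_circular_wraps_once(self):
        c = DNAConstruct(
            "d", "c1:cds:forward,t1:terminator:forward,p1:promoter:forward",
            topology="circular")
        (t,) = transcript_enumeration(c)
        assert t.terminator_index == 1
        assert [p.name for p in t.parts] == ["c1"]

    def test_circular_promoter_only_full_circle(self):
        c = DNAConstruct("d", "p1:promoter:forward,c1:cds:forward",
                         topology="circular")
        (t,) = transcript_enumeration(c)
        assert t.runoff and [p.name for p in t.parts] == ["c1"]

    def test_opposite_strand_terminator_read_through(self):
        c = DNAConstruct("d", "p1:promoter:forward,t1:terminator:reverse,"
                              "c1:cds:forward")
        (t,) = transcript_enumeration(c)
        assert t.terminator_index is None
        assert [p.name for p in t.parts] == ["c1"]

    @pytest.mark.parametrize("batch", range(5))
    def test_matches_oracle_on_seeded_random_constructs(self, batch):
        """Scanner agrees with the oriented-pair oracle on 500 random
        constructs of length <= 12, both topologies."""
        for i in range(100):
            seed = FixtureSeed(seed=batch * 1000 + i,
                               length=1 + (batch * 100 + i) % 12)
            construct = random_construct(seed)
            assert as_triples(transcript_enumeration(construct)) == \
                oracle_transcripts(construct.parts, construct.topology), (
                    f"seed {seed.seed}: {[str(p) for p in construct.parts]} "
                    f"({construct.topology})"
                )

    @pytest.mark.parametrize("seed", [11, 42, 99])
    def test_reversing_construct_mirrors_transcripts(self, seed):
        construct = random_construct(FixtureSeed(seed=seed, length=10))
        mirrored = construct.reversed_construct()
        n = len(construct.parts)
        direct = as_triples(transcript_enumeration(construct))
        flipped = {
            (n - 1 - i, None if t is None else n - 1 - t, names)
            for i, t, names in as_triples(transcript_enumeration(mirrored))
        }
        assert direct == flipped


class TestConstructComponents:
    def test_enumerator_produces_rna_constructs(self):
        c = DNAConstruct("d", "p1:promoter:forward,u1:rbs:forward,"
                              "c1:cds:forward,t1:terminator:forward")
        (rna,) = TranscriptEnumerator().enumerate([c])
        assert isinstance(rna, RNAConstruct)
        assert rna.source_dna == "d"
        assert rna.translation_pairs()[0][1].name == "c1"

    def test_rna_construct_rejects_promoter_parts(self):
        from crnforge.enumeration import Transcript
        from crnforge.mechanisms import ConfigurationError
        bad = Transcript(0, "p1", "forward", None,
                         (Part("p2", "promoter", "forward"),))
        with pytest.raises(ConfigurationError):
            RNAConstruct("r", "d", bad)

    def test_parse_parts_round_trip(self):
        parts = parse_parts("a:promoter:forward, b:rbs, c:cds:reverse")
        assert parts == [Part("a", "promoter", "forward"),
                         Part("b", "rbs", "forward"),
                         Part("c", "cds", "reverse")]

    def test_construct_compiles_to_expression_crn(self):
        from crnforge.mixtures import make_library_mixture
        c = DNAConstruct("d", "p1:promoter:forward,u1:rbs:forward,"
                              "c1:cds:forward,t1:terminator:forward")
        mixture = make_library_mixture(
            "expression_simple",
            parameters={"ktx": 0.1, "ktl": 0.5},
            components=[c],
        )
        crn = mixture.compile_crn()
        from crnforge.core import Species
        assert Species("d", "dna") in crn.species
        assert Species("d-tx0", "rna") in crn.species
        assert Species("c1", "protein") in crn.species
        assert len(crn.reactions) == 2
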