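"""Reference fixtures: the worked expression example, small genetic
circuits, and seeded random DNA constructs.

The worked example is a single expressible DNA part ``X`` (promoter + RBS +
CDS) in a four-parameter context (kb=100, ku=10, ktx=0.1, ktl=0.5).  Under
one-step schemas it compiles to the two-reaction catalytic network

    dna_X -> dna_X + rna_X   @ 0.1
    rna_X -> rna_X + protein_X @ 0.5

and under Michaelis-Menten schemas to the seven-species network with
explicit polymerase/ribosome binding at rates 100/10 and catalytic steps at
0.1/0.5 — the same part, two modeling resolutions.

Circuit fixtures wire Hill-repressed assemblies into the classic repression
cascade, bistable toggle switch, and three-gene repressilator.  The default
parameter set extends the four expression rates with Hill defaults (K=20,
n=2) and a dilution rate (kdil=0.01); these are fixture defaults chosen as
round ball-park values for bacterial gene expression, not measurements.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .core import CRNForgeError
from .components import DNAassembly
from .enumeration import DNAConstruct, Part, PART_TYPES
from .mechanisms import NegativeHillTranscription
from .mixtures import Mixture, make_library_mixture
from .parameters import ParameterDatabase

__all__ = [
    "EXAMPLE_PARAMETERS",
    "DEFAULT_CIRCUIT_PARAMETERS",
    "FixtureSeed",
    "make_example_2_7",
    "make_circuit",
    "random_construct",
    "CIRCUIT_KINDS",
]

#: the worked example's four-parameter context
EXAMPLE_PARAMETERS = {"kb": 100.0, "ku": 10.0, "ktx": 0.1, "ktl": 0.5}

#: expression rates extended with Hill repression and dilution defaults
DEFAULT_CIRCUIT_PARAMETERS = dict(
    EXAMPLE_PARAMETERS, K=20.0, n=2.0, kdil=0.01,
)

CIRCUIT_KINDS = ("repression", "toggle", "repressilator")


def make_example_2_7(schema: str = "simple") -> Mixture:
    """The worked expression example: one assembly ``X`` in a four-parameter
    mixture, under ``"simple"`` or ``"mm"`` transcription/translation."""
    if schema not in ("simple", "mm"):
        raise CRNForgeError(f"schema must be 'simple' or 'mm', got {schema!r}")
    assembly = DNAassembly("X", promoter="prom", rbs="rbs", protein="X")
    kind = "expression_simple" if schema == "simple" else "expression_mm"
    return make_library_mixture(
        kind, parameters=ParameterDatabase(EXAMPLE_PARAMETERS),
        name="mixture", components=[assembly],
    )


def _repressed(name: str, regulator_protein: str) -> DNAassembly:
    return DNAassembly(
        name, promoter="prom", rbs="rbs", protein=name,
        regulator=f"protein:{regulator_protein}",
        mechanisms=[NegativeHillTranscription()],
    )


def make_circuit(kind: str, parameters=None) -> Mixture:
    """Small genetic circuits on the one-step expression mixture.

    * ``repression`` — a constitutive repressor assembly (mixture-supplied
      one-step transcription) driving a reporter whose own local mechanism
      is Hill repression: the same process resolved differently for the two
      parts.
    * ``toggle`` — two assemblies mutually Hill-repressing each other.
    * ``repressilator`` — a three-repressor ring (A ⊣ B ⊣ C ⊣ A).
    """
    params = ParameterDatabase(
        parameters if parameters is not None else DEFAULT_CIRCUIT_PARAMETERS
    )
    if kind == "repression":
        repressor = DNAassembly("repressor", promoter="prom", rbs="rbs",
                                protein="repressor")
        reporter = _repressed("reporter", "repressor")
        components = [repressor, reporter]
    elif kind == "toggle":
        components = [_repressed("A", "B"), _repressed("B", "A")]
    elif kind == "repressilator":
        # C represses A, A represses B, B represses C
        components = [_repressed("A", "C"), _repressed("B", "A"),
                      _repressed("C", "B")]
    else:
        raise CRNForgeError(
            f"unknown circuit kind {kind!r}; expected one of {CIRCUIT_KINDS}"
        )
    return make_library_mixture(
        "expression_simple", parameters=params, name=kind, components=components,
    )


@dataclass(frozen=True)
class FixtureSeed:
    """Reproducible knobs for random fixture generation."""

    seed: int
    length: int = 8
    part_type_weights: dict = field(
        default_factory=lambda: {t: 1.0 for t in PART_TYPES}
    )
    circular_probability: float = 0.5


def random_construct(seed: FixtureSeed | int, length: int | None = None,
                     name: str = "plasmid") -> DNAConstruct:
    """Draw a seeded random DNA construct (part types, orientations,
    topology).  Same seed and knobs -> identical construct."""
    if isinstance(seed, int):
        seed = FixtureSeed(seed=seed, length=length if length is not None else 8)
    elif length is not None:
        seed = FixtureSeed(seed.seed, length, seed.part_type_weights,
                           seed.circular_probability)
    if seed.length < 1:
        raise CRNForgeError(f"construct length must be >= 1, got {seed.length}")
    rng = random.Random(seed.seed)
    types = [t for t in PART_TYPES if seed.part_type_weights.get(t, 0) > 0]
    weights = [seed.part_type_weights[t] for t in types]
    if not types:
        raise CRNForgeError("all part-type weights are zero")
    parts = []
    for i in range(seed.length):
        ptype = rng.choices(types, weights=weights)[0]
        orientation = rng.choice(("forward", "reverse"))
        parts.append(Part(f"{ptype[0]}{i}", ptype, orientation))
    topology = "circular" if rng.random() < seed.circular_probability else "linear"
    return DNAConstruct(name, parts, topology=topology)
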