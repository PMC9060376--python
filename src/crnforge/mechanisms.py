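"""Reaction schemas: functions f(S', θ) -> (S, R).

A mechanism turns a few input species plus rate parameters into the species
and reactions that model one biological process at one level of detail.
The same process — transcription, say — can be modeled as a single
catalytic reaction (simple), with explicit polymerase binding
(Michaelis-Menten), with a quasi-equilibrium Hill rate, or with several
polymerases loaded on one template (multi-occupancy).  Swapping the schema
changes the compiled CRN without touching the component that invoked it.

Two layers live here:

* plain update functions (``simple_transcription_update`` ...) — pure
  functions from species + rates to ``(species, reactions)``;
* thin :class:`Mechanism` classes wrapping them, which carry machinery
  species (polymerase, ribosome, RNase), declare required parameter names,
  and are what components resolve and call during compilation.  A string
  registry maps mechanism names to factories for model-spec files.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

from .core import (
    CRNForgeError,
    Propensity,
    Reaction,
    Species,
    make_complex,
    reversible_pair,
)

__all__ = [
    "ConfigurationError",
    "MachinerySpecies",
    "simple_transcription_update",
    "simple_translation_update",
    "mm_transcription_update",
    "mm_translation_update",
    "hill_transcription_update",
    "multi_occupancy_transcription_update",
    "mm_catalysis_update",
    "one_step_binding_update",
    "mm_degradation_update",
    "Mechanism",
    "SimpleTranscription",
    "SimpleTranslation",
    "MichaelisMentenTranscription",
    "MichaelisMentenTranslation",
    "NegativeHillTranscription",
    "PositiveHillTranscription",
    "MultiOccupancyTranscription",
    "MichaelisMentenCatalysis",
    "OneStepBinding",
    "MichaelisMentenRNADegradation",
    "Dilution",
    "MECHANISM_REGISTRY",
    "register_mechanism",
    "make_mechanism",
]


class ConfigurationError(CRNForgeError, ValueError):
    """A schema or component was invoked with inconsistent arguments."""


class MachinerySpecies:
    """Context-supplied machinery: RNA polymerase, ribosome, and RNase.

    The three species must be distinct; mixtures typically tag them with the
    ``"machinery"`` attribute so dilution-style global mechanisms skip them.
    """

    def __init__(self, rnap: Species, ribosome: Species, rnase: Species):
        trio = (rnap, ribosome, rnase)
        if len({rnap, ribosome, rnase}) != 3:
            raise ConfigurationError(f"machinery species must be distinct, got {trio}")
        self.rnap = rnap
        self.ribosome = ribosome
        self.rnase = rnase


# ---------------------------------------------------------------------------
# Update functions (pure reaction schemas)
# ---------------------------------------------------------------------------

def simple_transcription_update(dna: Species, transcript: Species, ktx: float):
    """dna -> dna + transcript @ ktx (no machinery modeled)."""
    if dna == transcript:
        raise ConfigurationError(
            f"transcript must differ from its template ({dna.display})"
        )
    rxn = Reaction.massaction({dna: 1}, {dna: 1, transcript: 1}, ktx)
    return [dna, transcript], [rxn]


def simple_translation_update(rna: Species, protein: Species, ktl: float):
    """rna -> rna + protein @ ktl (no machinery modeled)."""
    if rna == protein:
        raise ConfigurationError(
            f"protein must differ from its transcript ({rna.display})"
        )
    rxn = Reaction.massaction({rna: 1}, {rna: 1, protein: 1}, ktl)
    return [rna, protein], [rxn]


def mm_transcription_update(dna: Species, transcript: Species, rnap: Species,
                            kb: float, ku: float, ktx: float):
    """Explicit polymerase binding: dna + P <-> dna:P -> dna + P + transcript."""
    if dna == transcript:
        raise ConfigurationError(
            f"transcript must differ from its template ({dna.display})"
        )
    bound = make_complex([dna, rnap])
    fwd, rev = reversible_pair({dna: 1, rnap: 1}, {bound: 1}, kb, ku)
    cat = Reaction.massaction({bound: 1}, {dna: 1, rnap: 1, transcript: 1}, ktx)
    return [dna, rnap, bound, transcript], [fwd, rev, cat]


def mm_translation_update(rna: Species, protein: Species, ribosome: Species,
                          kb: float, ku: float, ktl: float):
    """Explicit ribosome binding: rna + R <-> rna:R -> rna + R + protein."""
    if rna == protein:
        raise ConfigurationError(
            f"protein must differ from its transcript ({rna.display})"
        )
    bound = make_complex([rna, ribosome])
    fwd, rev = reversible_pair({rna: 1, ribosome: 1}, {bound: 1}, kb, ku)
    cat = Reaction.massaction({bound: 1}, {rna: 1, ribosome: 1, protein: 1}, ktl)
    return [rna, ribosome, bound, protein], [fwd, rev, cat]


def hill_transcription_update(dna: Species, transcript: Species,
                              regulator: Species, mode: str,
                              ktx: float, K: float, n: float,
                              leak: float = 0.0):
    """Quasi-equilibrium regulated transcription with a Hill rate law.

    One reaction dna -> dna + transcript whose propensity saturates in the
    regulator (``mode`` selects activation or repression), scaled by the
    template concentration.  A nonzero *leak* adds a regulator-independent
    mass-action production reaction (parameter name ``ktx_leak``).
    """
    if mode not in ("positive", "negative"):
        raise ConfigurationError(f"hill mode must be positive|negative, got {mode!r}")
    if dna == transcript:
        raise ConfigurationError(
            f"transcript must differ from its template ({dna.display})"
        )
    ctor = Propensity.hill_positive if mode == "positive" else Propensity.hill_negative
    prop = ctor(k=ktx, K=K, n=n, regulator=regulator, scaler=dna)
    reactions = [Reaction({dna: 1}, {dna: 1, transcript: 1}, prop)]
    if leak > 0:
        reactions.append(
            Reaction.massaction({dna: 1}, {dna: 1, transcript: 1}, leak)
        )
    return [dna, transcript, regulator], reactions


def multi_occupancy_transcription_update(dna: Species, transcript: Species,
                                         rnap: Species, max_occupancy: int,
                                         kb: float, ku: float, ktx: float):
    """Transcription with up to *max_occupancy* polymerases per template.

    Occupancy state i is the complex of the template with i polymerase
    copies (state 0 is the bare template).  Loading is occupancy-independent
    at *kb*; with i independent polymerases bound, unbinding runs at i*ku
    and production at i*ktx, each production releasing one polymerase.
    Emits 3*max_occupancy irreversible reactions.
    """
    if not isinstance(max_occupancy, int) or max_occupancy < 1:
        raise ConfigurationError(
            f"max_occupancy must be a positive integer, got {max_occupancy!r}"
        )
    if dna == transcript:
        raise ConfigurationError(
            f"transcript must differ from its template ({dna.display})"
        )
    states = [dna] + [
        make_complex([dna] + [rnap] * i) for i in range(1, max_occupancy + 1)
    ]
    reactions = []
    for i in range(1, max_occupancy + 1):
        lower, upper = states[i - 1], states[i]
        fwd, rev = reversible_pair({lower: 1, rnap: 1}, {upper: 1}, kb, i * ku)
        prod = Reaction.massaction(
            {upper: 1}, {lower: 1, rnap: 1, transcript: 1}, i * ktx
        )
        reactions.extend([fwd, rev, prod])
    species = states + [rnap, transcript]
    return species, reactions


def mm_catalysis_update(enzyme: Species, substrate: Species, product: Species,
                        kb: float, ku: float, kcat: float):
    """Michaelis-Menten catalysis: E + S <-> E:S -> E + P."""
    if substrate == product:
        raise ConfigurationError(
            f"substrate and product must differ ({substrate.display})"
        )
    bound = make_complex([enzyme, substrate])
    fwd, rev = reversible_pair(
        Counter([enzyme, substrate]), {bound: 1}, kb, ku
    )
    cat = Reaction.massaction({bound: 1}, {enzyme: 1, product: 1}, kcat)
    return [enzyme, substrate, bound, product], [fwd, rev, cat]


def one_step_binding_update(members: Sequence[Species], kb: float, ku: float):
    """All members bind in a single step: sum(members) <-> member complex."""
    members = list(members)
    if len(members) < 2:
        raise ConfigurationError("binding requires at least 2 member species")
    bound = make_complex(members)
    fwd, rev = reversible_pair(Counter(members), {bound: 1}, kb, ku)
    return list(dict.fromkeys(members)) + [bound], [fwd, rev]


def mm_degradation_update(target: Species, rnase: Species,
                          kb: float, ku: float, kdeg: float):
    """Enzymatic degradation: target + RNase <-> target:RNase -> RNase."""
    bound = make_complex([target, rnase])
    fwd, rev = reversible_pair({target: 1, rnase: 1}, {bound: 1}, kb, ku)
    deg = Reaction.massaction({bound: 1}, {rnase: 1}, kdeg)
    return [target, rnase, bound], [fwd, rev, deg]


# ---------------------------------------------------------------------------
# Mechanism classes
# ---------------------------------------------------------------------------

class Mechanism:
    """Base class for reaction schemas resolvable by components.

    Subclasses set :attr:`mechanism_type` (the slot a component asks for,
    e.g. ``"transcription"``), declare required and optional parameter
    names, and implement :meth:`update`, a pure function from keyword
    species plus a parameter mapping to ``(species, reactions)``.
    """

    mechanism_type: str = ""
    default_name: str = ""
    required_parameters: tuple[str, ...] = ()
    #: name -> default used when the parameter is absent from every database
    optional_parameters: Mapping[str, float] = {}

    def __init__(self, name: str | None = None):
        self.name = name or self.default_name or type(self).__name__.lower()

    def update(self, params: Mapping[str, float], **species):
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}(name={self.name!r})"


class SimpleTranscription(Mechanism):
    mechanism_type = "transcription"
    default_name = "simple_transcription"
    required_parameters = ("ktx",)

    def update(self, params, *, dna, transcript, regulator=None):
        return simple_transcription_update(dna, transcript, params["ktx"])


class SimpleTranslation(Mechanism):
    mechanism_type = "translation"
    default_name = "simple_translation"
    required_parameters = ("ktl",)

    def update(self, params, *, rna, protein):
        return simple_translation_update(rna, protein, params["ktl"])


class MichaelisMentenTranscription(Mechanism):
    mechanism_type = "transcription"
    default_name = "mm_transcription"
    required_parameters = ("kb", "ku", "ktx")

    def __init__(self, rnap: Species | None = None, name: str | None = None):
        super().__init__(name)
        self.rnap = rnap if rnap is not None else Species("P")

    def update(self, params, *, dna, transcript, regulator=None):
        return mm_transcription_update(
            dna, transcript, self.rnap, params["kb"], params["ku"], params["ktx"]
        )


class MichaelisMentenTranslation(Mechanism):
    mechanism_type = "translation"
    default_name = "mm_translation"
    required_parameters = ("kb", "ku", "ktl")

    def __init__(self, ribosome: Species | None = None, name: str | None = None):
        super().__init__(name)
        self.ribosome = ribosome if ribosome is not None else Species("R")

    def update(self, params, *, rna, protein):
        return mm_translation_update(
            rna, protein, self.ribosome, params["kb"], params["ku"], params["ktl"]
        )


class _HillTranscription(Mechanism):
    mechanism_type = "transcription"
    required_parameters = ("ktx", "K", "n")
    optional_parameters = {"ktx_leak": 0.0}
    mode = ""

    def update(self, params, *, dna, transcript, regulator=None):
        if regulator is None:
            raise ConfigurationError(
                f"{self.name} requires a regulator species (none supplied)"
            )
        return hill_transcription_update(
            dna, transcript, regulator, self.mode,
            params["ktx"], params["K"], params["n"],
            leak=params.get("ktx_leak", 0.0),
        )


class NegativeHillTranscription(_HillTranscription):
    default_name = "negative_hill_transcription"
    mode = "negative"


class PositiveHillTranscription(_HillTranscription):
    default_name = "positive_hill_transcription"
    mode = "positive"


class MultiOccupancyTranscription(Mechanism):
    mechanism_type = "transcription"
    default_name = "multi_occupancy_transcription"
    required_parameters = ("kb", "ku", "ktx")

    def __init__(self, rnap: Species | None = None, max_occupancy: int = 2,
                 name: str | None = None):
        super().__init__(name)
        self.rnap = rnap if rnap is not None else Species("P")
        if not isinstance(max_occupancy, int) or max_occupancy < 1:
            raise ConfigurationError(
                f"max_occupancy must be a positive integer, got {max_occupancy!r}"
            )
        self.max_occupancy = max_occupancy

    def update(self, params, *, dna, transcript, regulator=None):
        return multi_occupancy_transcription_update(
            dna, transcript, self.rnap, self.max_occupancy,
            params["kb"], params["ku"], params["ktx"],
        )


class MichaelisMentenCatalysis(Mechanism):
    """E + S1 + ... <-> E:S1:... -> E + P1 + ... (single substrate is the
    classic Michaelis-Menten template; multiple substrates bind in one step)."""

    mechanism_type = "catalysis"
    default_name = "mm_catalysis"
    required_parameters = ("kb", "ku", "kcat")

    def update(self, params, *, enzyme, substrates, products):
        substrates = list(substrates)
        products = list(products)
        if not substrates or not products:
            raise ConfigurationError("catalysis requires substrates and products")
        if Counter(substrates) == Counter(products):
            raise ConfigurationError("substrates and products must differ")
        if len(substrates) == 1 and len(products) == 1:
            return mm_catalysis_update(
                enzyme, substrates[0], products[0],
                params["kb"], params["ku"], params["kcat"],
            )
        bound = make_complex([enzyme] + substrates)
        fwd, rev = reversible_pair(
            Counter([enzyme] + substrates), {bound: 1}, params["kb"], params["ku"]
        )
        cat = Reaction.massaction(
            {bound: 1}, Counter([enzyme] + products), params["kcat"]
        )
        species = list(dict.fromkeys([enzyme] + substrates + [bound] + products))
        return species, [fwd, rev, cat]


class OneStepBinding(Mechanism):
    mechanism_type = "binding"
    default_name = "one_step_binding"
    required_parameters = ("kb", "ku")

    def update(self, params, *, members):
        return one_step_binding_update(members, params["kb"], params["ku"])


class MichaelisMentenRNADegradation(Mechanism):
    mechanism_type = "rna_degradation"
    default_name = "mm_rna_degradation"
    required_parameters = ("kb", "ku", "kdeg")

    def __init__(self, rnase: Species | None = None, name: str | None = None):
        super().__init__(name)
        self.rnase = rnase if rnase is not None else Species("RNase")

    def update(self, params, *, species):
        return mm_degradation_update(
            species, self.rnase, params["kb"], params["ku"], params["kdeg"]
        )


class Dilution(Mechanism):
    """First-order removal species -> 0 @ kdil, used as a global mechanism."""

    mechanism_type = "dilution"
    default_name = "dilution"
    required_parameters = ("kdil",)

    def update(self, params, *, species):
        return [species], [Reaction.massaction({species: 1}, {}, params["kdil"])]


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

MECHANISM_REGISTRY: dict[str, type[Mechanism]] = {}


def register_mechanism(name: str, cls: type[Mechanism] | None = None):
    """Register a mechanism class under *name* (usable as a decorator)."""
    def _register(target):
        MECHANISM_REGISTRY[name] = target
        return target
    return _register(cls) if cls is not None else _register


for _cls in (
    SimpleTranscription, SimpleTranslation,
    MichaelisMentenTranscription, MichaelisMentenTranslation,
    NegativeHillTranscription, PositiveHillTranscription,
    MultiOccupancyTranscription, MichaelisMentenCatalysis,
    OneStepBinding, MichaelisMentenRNADegradation, Dilution,
):
    register_mechanism(_cls.default_name, _cls)


def _species_from_config(value, default: Species) -> Species:
    if value is None:
        return default
    if isinstance(value, Species):
        return value
    if isinstance(value, str):
        if ":" in value:
            material, name = value.split(":", 1)
            return Species(name, material)
        return Species(value)
    raise ConfigurationError(f"cannot interpret species reference {value!r}")


def make_mechanism(name: str, **config) -> Mechanism:
    """Instantiate a registered mechanism by name.

    Machinery overrides accept species references (``"P"`` or
    ``"protein:RNAP"``); ``max_occupancy`` configures the multi-occupancy
    schema.
    """
    if name not in MECHANISM_REGISTRY:
        known = ", ".join(sorted(MECHANISM_REGISTRY))
        raise ConfigurationError(f"unknown mechanism {name!r}; known: {known}")
    cls = MECHANISM_REGISTRY[name]
    kwargs = {}
    if "rnap" in config and issubclass(cls, (MichaelisMentenTranscription,
                                             MultiOccupancyTranscription)):
        kwargs["rnap"] = _species_from_config(config.pop("rnap"), Species("P"))
    if "ribosome" in config and issubclass(cls, MichaelisMentenTranslation):
        kwargs["ribosome"] = _species_from_config(config.pop("ribosome"), Species("R"))
    if "rnase" in config and issubclass(cls, MichaelisMentenRNADegradation):
        kwargs["rnase"] = _species_from_config(config.pop("rnase"), Species("RNase"))
    if "max_occupancy" in config and issubclass(cls, MultiOccupancyTranscription):
        kwargs["max_occupancy"] = int(config.pop("max_occupancy"))
    if config:
        raise ConfigurationError(
            f"mechanism {name!r} does not accept option(s) {sorted(config)}"
        )
    return cls(**kwargs)
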