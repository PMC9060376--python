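"""Mixtures (context) and the compilation algorithm.

A mixture bundles components, default mechanisms, global mechanisms and a
parameter database: it represents both the chemical environment (extract,
cell-like milieu) and the modeling resolution.  Compilation turns a
populated mixture into a CRN in seven ordered steps:

1. global component enumeration, to a fixed point or the depth cap;
2. local component enumeration, likewise;
3. every component (original and enumerated) emits species/reactions;
4. within each update, mechanisms resolve locally first, then from the
   mixture;
5. parameters resolve against the component database first, then the
   mixture's, through the defaulting hierarchy;
6. global mechanisms run exactly once over every species produced so far —
   never recursively, so species they create receive no further global
   processing;
7. everything is assembled into a deduplicated, order-stable CRN.

Compilation is read-only on the mixture, so recompiling reproduces a
byte-identical serialized network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import CRN, Reaction, Species, assemble_crn
from .components import Component, resolve_mechanism, resolve_parameter
from .enumeration import ComponentEnumerator, enumerate_fixed_point
from .mechanisms import (
    ConfigurationError,
    Dilution,
    MachinerySpecies,
    Mechanism,
    MichaelisMentenRNADegradation,
    MichaelisMentenTranscription,
    MichaelisMentenTranslation,
    SimpleTranscription,
    SimpleTranslation,
)
from .parameters import ParameterDatabase, ParameterKey

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesFilter",
    "GlobalMechanism",
    "ParameterRecord",
    "CompilationContext",
    "Mixture",
    "apply_global_mechanisms",
    "MIXTURE_KINDS",
    "make_library_mixture",
]


@dataclass(frozen=True)
class SpeciesFilter:
    """Allow/deny predicate on species material types and attributes.

    Deny rules win; empty allow fields accept everything.  ``attributes``
    matches if the species carries *any* listed tag.
    """

    materials: tuple[str, ...] = ()
    exclude_materials: tuple[str, ...] = ()
    attributes: tuple[str, ...] = ()
    exclude_attributes: tuple[str, ...] = ()

    def __call__(self, species: Species) -> bool:
        if species.material_type in self.exclude_materials:
            return False
        if any(tag in species.attributes for tag in self.exclude_attributes):
            return False
        if self.materials and species.material_type not in self.materials:
            return False
        if self.attributes and not any(
            tag in species.attributes for tag in self.attributes
        ):
            return False
        return True


class GlobalMechanism:
    """A mixture-level schema applied once to every species passing a filter.

    Wraps a single-species mechanism (dilution, RNA degradation, ...).
    Applied non-recursively: species created here are never fed back into
    any global mechanism, including this one.
    """

    def __init__(self, mechanism: Mechanism, filter: SpeciesFilter | None = None):
        self.mechanism = mechanism
        self.filter = filter if filter is not None else SpeciesFilter()

    def applies_to(self, species: Species) -> bool:
        return self.filter(species)

    def __repr__(self):
        return f"GlobalMechanism({self.mechanism.name}, {self.filter})"


@dataclass(frozen=True)
class ParameterRecord:
    """One audited parameter resolution during compilation."""

    component: str
    mechanism: str
    mechanism_type: str
    name: str
    value: float
    matched_key: ParameterKey | None  # None => built-in optional default
    source: str  # "component" | "mixture" | "default"


class CompilationContext:
    """Resolution services handed to components during compilation.

    Centralizes mechanism and parameter resolution (local-before-mixture)
    and records every parameter lookup for auditing.
    """

    def __init__(self, mixture: "Mixture"):
        self.mixture = mixture
        self.parameter_audit: list[ParameterRecord] = []

    def resolve_mechanism(self, component: Component, mechanism_type: str) -> Mechanism:
        return resolve_mechanism(component, self.mixture.mechanisms, mechanism_type)

    def resolve_parameter(self, component: Component, mechanism: Mechanism,
                          name: str, extra_part_ids: Sequence[str] = (),
                          default=None) -> float:
        value, key, source = resolve_parameter(
            component, self.mixture.parameters, mechanism, name,
            extra_part_ids=extra_part_ids, default=default,
        )
        self.parameter_audit.append(ParameterRecord(
            component=component.name, mechanism=mechanism.name,
            mechanism_type=mechanism.mechanism_type, name=name,
            value=value, matched_key=key, source=source,
        ))
        return value

    def resolve_parameters(self, component: Component, mechanism: Mechanism,
                           extra_part_ids: Sequence[str] = ()) -> dict[str, float]:
        """Resolve every required (and present optional) mechanism parameter."""
        params = {}
        for name in mechanism.required_parameters:
            params[name] = self.resolve_parameter(
                component, mechanism, name, extra_part_ids=extra_part_ids
            )
        for name, fallback in mechanism.optional_parameters.items():
            params[name] = self.resolve_parameter(
                component, mechanism, name, extra_part_ids=extra_part_ids,
                default=fallback,
            )
        return params


class Mixture:
    """A named context: components + mechanisms + parameters (+ enumerators).

    ``parameters`` accepts a :class:`ParameterDatabase` or the shorthand
    mapping ``{"kb": 100, ...}`` of global defaults.  ``mechanisms`` accepts
    a list of mechanisms (keyed by their type) or an explicit type->mechanism
    mapping.
    """

    def __init__(self, name: str = "mixture",
                 components: Iterable[Component] = (),
                 mechanisms: Iterable[Mechanism] | Mapping[str, Mechanism] = (),
                 global_mechanisms: Iterable[GlobalMechanism] = (),
                 parameters: ParameterDatabase | Mapping | None = None,
                 global_enumerators: Iterable[ComponentEnumerator] = (),
                 max_enumeration_depth: int = 8):
        self.name = name
        self.components: list[Component] = list(components)
        if isinstance(mechanisms, Mapping):
            self.mechanisms: dict[str, Mechanism] = dict(mechanisms)
        else:
            self.mechanisms = {m.mechanism_type: m for m in mechanisms}
        self.global_mechanisms: list[GlobalMechanism] = list(global_mechanisms)
        if parameters is None:
            self.parameters = ParameterDatabase()
        elif isinstance(parameters, ParameterDatabase):
            self.parameters = parameters
        else:
            self.parameters = ParameterDatabase(parameters)
        self.global_enumerators: list[ComponentEnumerator] = list(global_enumerators)
        if max_enumeration_depth < 1:
            raise ConfigurationError("max_enumeration_depth must be >= 1")
        self.max_enumeration_depth = max_enumeration_depth

    def add_component(self, component: Component) -> None:
        self.components.append(component)

    def add_mechanism(self, mechanism: Mechanism) -> None:
        self.mechanisms[mechanism.mechanism_type] = mechanism

    def __repr__(self):
        return (f"Mixture({self.name!r}: {len(self.components)} components, "
                f"{len(self.mechanisms)} mechanisms)")

    # -- compilation -------------------------------------------------------
    def compile_crn(self, name: str | None = None,
                    context: CompilationContext | None = None) -> CRN:
        """Run the seven-step compilation; returns the assembled CRN.

        The returned CRN's ``metadata`` carries the parameter audit and the
        provenance of global-mechanism products (used by diagnostics).
        """
        ctx = context if context is not None else CompilationContext(self)
        # steps 1-2: global, then local enumeration, each to fixed point
        components = enumerate_fixed_point(
            self.components, self.global_enumerators,
            self.max_enumeration_depth, include_local=False,
        )
        components = enumerate_fixed_point(
            components, (), self.max_enumeration_depth, include_local=True,
        )
        # step 3 (with 4-5 inside each update)
        species: dict[Species, None] = {}
        reactions: list[Reaction] = []
        for comp in components:
            comp_species, comp_reactions = comp.update(ctx)
            for sp in comp_species:
                species.setdefault(sp)
            for rx in comp_reactions:
                for sp in rx.species:
                    species.setdefault(sp)
                reactions.append(rx)
        # step 6
        gm_species, gm_reactions, gm_triggers = apply_global_mechanisms(
            self, list(species), ctx
        )
        gm_created = [sp for sp in gm_species if sp not in species]
        for sp in gm_species:
            species.setdefault(sp)
        reactions.extend(gm_reactions)
        # step 7
        crn = assemble_crn(list(species), reactions,
                           name=name or f"{self.name}")
        crn.metadata["parameter_audit"] = list(ctx.parameter_audit)
        crn.metadata["global_mechanism_triggers"] = gm_triggers
        crn.metadata["global_mechanism_created"] = gm_created
        return crn


def apply_global_mechanisms(mixture: Mixture, species: Sequence[Species],
                            context: CompilationContext | None = None):
    """Step 6: run each global mechanism once per passing species.

    Returns ``(new_species, reactions, triggers)`` where *triggers* maps
    each generated reaction to the species that triggered it.  Species
    created here are not re-fed into any global mechanism.
    """
    ctx = context if context is not None else CompilationContext(mixture)
    new_species: list[Species] = []
    reactions: list[Reaction] = []
    triggers: list[tuple[Species, Reaction]] = []
    carrier = Component("globalmechanisms")
    for gm in mixture.global_mechanisms:
        for sp in species:
            if not gm.applies_to(sp):
                continue
            params = {}
            for pname in gm.mechanism.required_parameters:
                params[pname] = ctx.resolve_parameter(
                    carrier, gm.mechanism, pname,
                    extra_part_ids=[sp.canonical_name]
                    if _is_valid_part_id(sp.canonical_name) else (),
                )
            for pname, fallback in gm.mechanism.optional_parameters.items():
                params[pname] = ctx.resolve_parameter(
                    carrier, gm.mechanism, pname, default=fallback,
                )
            sp_out, rx_out = gm.mechanism.update(params, species=sp)
            new_species.extend(sp_out)
            reactions.extend(rx_out)
            triggers.extend((sp, rx) for rx in rx_out)
    return new_species, reactions, triggers


def _is_valid_part_id(name: str) -> bool:
    return bool(name)


# ---------------------------------------------------------------------------
# Library mixtures
# ---------------------------------------------------------------------------

MIXTURE_KINDS = ("expression_simple", "expression_mm", "txtl_machinery")


def make_library_mixture(kind: str,
                         parameters: ParameterDatabase | Mapping | None = None,
                         name: str | None = None,
                         components: Iterable[Component] = ()) -> Mixture:
    """Construct one of the shipped context bundles.

    * ``expression_simple`` — catalytic one-step transcription/translation,
      no machinery species;
    * ``expression_mm`` — Michaelis-Menten transcription/translation with
      explicit polymerase ``P`` and ribosome ``R``;
    * ``txtl_machinery`` — as ``expression_mm`` but machinery species carry
      the ``"machinery"`` attribute and transcripts are degraded by an
      RNase through a global mechanism (machinery itself is exempt).
    """
    if kind == "expression_simple":
        return Mixture(
            name or kind, components=components,
            mechanisms=[SimpleTranscription(), SimpleTranslation()],
            parameters=parameters,
        )
    if kind == "expression_mm":
        return Mixture(
            name or kind, components=components,
            mechanisms=[
                MichaelisMentenTranscription(rnap=Species("P")),
                MichaelisMentenTranslation(ribosome=Species("R")),
            ],
            parameters=parameters,
        )
    if kind == "txtl_machinery":
        machinery = MachinerySpecies(
            rnap=Species("P", attributes=("machinery",)),
            ribosome=Species("R", attributes=("machinery",)),
            rnase=Species("RNase", attributes=("machinery",)),
        )
        degradation = GlobalMechanism(
            MichaelisMentenRNADegradation(rnase=machinery.rnase),
            SpeciesFilter(materials=("rna",), exclude_attributes=("machinery",)),
        )
        return Mixture(
            name or kind, components=components,
            mechanisms=[
                MichaelisMentenTranscription(rnap=machinery.rnap),
                MichaelisMentenTranslation(ribosome=machinery.ribosome),
            ],
            global_mechanisms=[degradation],
            parameters=parameters,
        )
    raise ConfigurationError(
        f"unknown mixture kind {kind!r}; expected one of {MIXTURE_KINDS}"
    )
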