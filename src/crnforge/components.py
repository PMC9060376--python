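"""Components: biomolecular parts that express functionality via mechanisms.

A component (promoter assembly, enzyme, chemical complex, ...) is not a
species — it is a part that, during compilation, emits zero or more species
and reactions by invoking mechanisms of the types it needs.  Mechanisms and
parameters are resolved locally first (the component's own), then from the
surrounding mixture: a component carrying everything it needs compiles to
the identical sub-CRN in any context, while a bare component inherits the
context's modeling resolution.

Parameter lookup uses the component's name as the ``part_id``; sub-part
names (promoter, RBS) form a secondary part tier tried only when the
primary misses.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .core import CRNForgeError, Species
from .mechanisms import ConfigurationError, Mechanism
from .parameters import (
    MissingParameterError,
    ParameterDatabase,
    ParameterKey,
    search_keys,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Component",
    "DNAassembly",
    "Enzyme",
    "ChemicalComplex",
    "MissingMechanismError",
    "resolve_mechanism",
    "resolve_parameter",
    "as_species",
    "COMPONENT_REGISTRY",
    "register_component",
]


class MissingMechanismError(CRNForgeError, KeyError):
    def __init__(self, component_name: str, mechanism_type: str):
        super().__init__(
            f"component {component_name!r} needs a mechanism of type "
            f"{mechanism_type!r}, found neither locally nor in the mixture"
        )

    def __str__(self):
        return self.args[0]


def as_species(ref, default_material: str = "none") -> Species:
    """Turn a species reference into a Species.

    Accepts a :class:`Species`, a ``"material:name"`` string, or a bare
    name (created with *default_material*).
    """
    if isinstance(ref, Species):
        return ref
    if isinstance(ref, str):
        if ":" in ref:
            material, name = ref.split(":", 1)
            return Species(name, material)
        return Species(ref, default_material)
    raise CRNForgeError(f"cannot interpret species reference {ref!r}")


def resolve_mechanism(component: "Component",
                      mixture_mechanisms: Mapping[str, Mechanism],
                      mechanism_type: str) -> Mechanism:
    """Local mechanism wins; fall back to the mixture's; error if neither."""
    mech = component.local_mechanisms.get(mechanism_type)
    if mech is not None:
        logger.debug(
            "%s: mechanism %r resolved locally -> %s",
            component.name, mechanism_type, mech.name,
        )
        return mech
    mech = mixture_mechanisms.get(mechanism_type)
    if mech is not None:
        logger.debug(
            "%s: mechanism %r resolved from mixture -> %s",
            component.name, mechanism_type, mech.name,
        )
        return mech
    raise MissingMechanismError(component.name, mechanism_type)


def resolve_parameter(component: "Component",
                      mixture_db: ParameterDatabase | None,
                      mechanism: Mechanism,
                      name: str,
                      extra_part_ids: Sequence[str] = (),
                      default=None):
    """Resolve one rate parameter for *component* calling *mechanism*.

    Runs the 6-tier defaulting search against the component's own database
    (if any) first, then the mixture's; within each database the primary
    ``part_id`` (the component name) is tried before any secondary sub-part
    tiers.  Returns ``(value, matched_key, source)`` where source is
    ``"component"`` or ``"mixture"``.  On a complete miss, *default* is
    returned as ``(default, None, "default")`` if given, else a
    :class:`MissingParameterError` lists every attempted key.
    """
    part_ids = list(dict.fromkeys([component.name, *extra_part_ids]))
    # part-specific tiers for the primary part, then each secondary sub-part,
    # then the part-less mechanism/global fallback tiers
    keys: list[ParameterKey] = []
    for part_id in part_ids:
        keys.extend(
            k for k in search_keys(mechanism.name, mechanism.mechanism_type,
                                   part_id, name)
            if k.part_id is not None
        )
    keys.extend(search_keys(mechanism.name, mechanism.mechanism_type, None, name))
    keys = list(dict.fromkeys(keys))
    databases = []
    if component.local_parameters is not None:
        databases.append(("component", component.local_parameters))
    if mixture_db is not None:
        databases.append(("mixture", mixture_db))
    for source, db in databases:
        for key in keys:
            entry = db.get(key)
            if entry is not None:
                if key.part_id is not None and key.part_id != component.name:
                    logger.debug(
                        "%s: parameter %r resolved via sub-part %r",
                        component.name, name, key.part_id,
                    )
                return entry.value, key, source
    if default is not None:
        return default, None, "default"
    raise MissingParameterError(name, keys)


class Component:
    """Base class: a named part with optional local mechanisms, parameters
    and enumerators.  Subclasses implement :meth:`update`."""

    component_type = "component"

    def __init__(self, name: str,
                 mechanisms: Mapping[str, Mechanism] | Iterable[Mechanism] | None = None,
                 parameters: ParameterDatabase | Mapping | None = None,
                 enumerators: Iterable = ()):
        # component names double as species names, so share their grammar
        Species(name)  # raises on an invalid name
        self.name = name
        self.local_mechanisms = self._as_mechanism_map(mechanisms)
        if parameters is None or isinstance(parameters, ParameterDatabase):
            self.local_parameters = parameters
        else:
            self.local_parameters = ParameterDatabase(parameters)
        self.local_enumerators = list(enumerators)

    @staticmethod
    def _as_mechanism_map(mechanisms) -> dict[str, Mechanism]:
        if mechanisms is None:
            return {}
        if isinstance(mechanisms, Mapping):
            return dict(mechanisms)
        return {m.mechanism_type: m for m in mechanisms}

    def update(self, ctx) -> tuple[list[Species], list]:
        """Emit (species, reactions); *ctx* provides mechanism/parameter
        resolution (see :class:`crnforge.mixtures.CompilationContext`)."""
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}({self.name!r})"


class DNAassembly(Component):
    """A DNA part bundling promoter, RBS and coding sequence.

    Emits a dna-material species named after the assembly.  Transcription is
    emitted iff a promoter is set (via the resolved ``"transcription"``
    mechanism); translation iff both RBS and protein are set.  The
    transcript species defaults to the assembly name with rna material, the
    protein product to *protein* with protein material.  Hill-regulated
    assemblies additionally carry a *regulator* species reference.
    """

    component_type = "dna_assembly"

    def __init__(self, name: str, promoter: str | None = None,
                 rbs: str | None = None, protein: str | None = None,
                 transcript: str | None = None, regulator=None,
                 **kwargs):
        super().__init__(name, **kwargs)
        if rbs is not None and protein is None:
            raise ConfigurationError(
                f"assembly {name!r}: an RBS without a protein product is inert; "
                "set protein= or drop rbs="
            )
        self.promoter = promoter
        self.rbs = rbs
        self.protein = protein
        self.transcript = transcript
        self.regulator = as_species(regulator, "protein") if regulator is not None else None

    @property
    def dna_species(self) -> Species:
        return Species(self.name, "dna")

    @property
    def transcript_species(self) -> Species:
        return Species(self.transcript or self.name, "rna")

    @property
    def protein_species(self) -> Species | None:
        return Species(self.protein, "protein") if self.protein else None

    def update(self, ctx):
        species: list[Species] = [self.dna_species]
        reactions: list = []
        if self.promoter:
            mech = ctx.resolve_mechanism(self, "transcription")
            params = ctx.resolve_parameters(
                self, mech, extra_part_ids=[self.promoter]
            )
            sp, rx = mech.update(
                params,
                dna=self.dna_species,
                transcript=self.transcript_species,
                regulator=self.regulator,
            )
            species.extend(sp)
            reactions.extend(rx)
        if self.rbs and self.protein:
            mech = ctx.resolve_mechanism(self, "translation")
            params = ctx.resolve_parameters(self, mech, extra_part_ids=[self.rbs])
            sp, rx = mech.update(
                params,
                rna=self.transcript_species,
                protein=self.protein_species,
            )
            species.extend(sp)
            reactions.extend(rx)
        return species, reactions


class Enzyme(Component):
    """An enzyme converting substrates to products via a catalysis mechanism.

    The enzyme's own species is protein-material by default; substrate and
    product references default to untyped species and are auto-created if
    not defined elsewhere.
    """

    component_type = "enzyme"

    def __init__(self, name: str, substrates: Sequence = (), products: Sequence = (),
                 material: str = "protein", **kwargs):
        super().__init__(name, **kwargs)
        self.enzyme_species = Species(name, material)
        self.substrates = [as_species(s) for s in substrates]
        self.products = [as_species(p) for p in products]
        if not self.substrates or not self.products:
            raise ConfigurationError(
                f"enzyme {name!r} needs at least one substrate and one product"
            )

    def update(self, ctx):
        mech = ctx.resolve_mechanism(self, "catalysis")
        params = ctx.resolve_parameters(self, mech)
        return mech.update(
            params,
            enzyme=self.enzyme_species,
            substrates=self.substrates,
            products=self.products,
        )


class ChemicalComplex(Component):
    """Members bind into a complex via a binding mechanism (single-step by
    default); repeats in *members* encode multiplicity, so a homotetramer is
    ``members=["A"] * 4``."""

    component_type = "chemical_complex"

    def __init__(self, name: str, members: Sequence = (), **kwargs):
        super().__init__(name, **kwargs)
        self.members = [as_species(m) for m in members]
        if len(self.members) < 2:
            raise ConfigurationError(
                f"chemical complex {name!r} needs at least 2 member species"
            )

    def update(self, ctx):
        mech = ctx.resolve_mechanism(self, "binding")
        params = ctx.resolve_parameters(self, mech)
        return mech.update(params, members=self.members)


COMPONENT_REGISTRY: dict[str, type[Component]] = {}


def register_component(name: str, cls: type[Component] | None = None):
    """Register a component class under *name* (usable as a decorator)."""
    def _register(target):
        COMPONENT_REGISTRY[name] = target
        return target
    return _register(cls) if cls is not None else _register


register_component("dna_assembly", DNAassembly)
register_component("enzyme", Enzyme)
register_component("chemical_complex", ChemicalComplex)
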