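"""Declarative model-spec files (YAML) -> Mixture.

A model spec is the declarative twin of the scripting API: it names a
mixture kind, lists components, selects mechanisms by registered name
(globally and per component), pulls in parameter files plus inline
overrides, and states initial concentrations.  Validation is
collect-everything-first: all unresolved names and malformed fields are
reported in a single error.

Example::

    name: expression
    mixture: expression_simple
    components:
      - type: dna_assembly
        name: X
        promoter: prom
        rbs: rbs
        protein: X
    parameters:
      values: {kb: 100, ku: 10, ktx: 0.1, ktl: 0.5}
    initial_concentrations:
      dna_X: 1.0
"""

from __future__ import annotations

from numbers import Real
from pathlib import Path
from typing import Mapping

import yaml

from .core import CRNForgeError, Species
from .components import COMPONENT_REGISTRY, Component
from . import enumeration  # noqa: F401  (registers the dna_construct type)
from .mechanisms import (
    MECHANISM_REGISTRY,
    Mechanism,
    make_mechanism,
)
from .mixtures import MIXTURE_KINDS, Mixture, make_library_mixture
from .parameters import ParameterDatabase, ParameterKey, load_parameter_file

__all__ = ["ModelSpecError", "parse_model_spec", "load_model_spec",
           "initial_concentrations", "INITIAL_CONCENTRATION"]

#: parameter name under which initial concentrations are stored
#: (part_id = species canonical name)
INITIAL_CONCENTRATION = "initial_concentration"

_TOP_LEVEL_KEYS = {
    "name", "mixture", "mechanisms", "components", "parameters",
    "initial_concentrations", "max_depth",
}
_COMPONENT_COMMON_KEYS = {"type", "name", "mechanisms", "parameters"}
_COMPONENT_KEYS = {
    "dna_assembly": _COMPONENT_COMMON_KEYS | {
        "promoter", "rbs", "protein", "transcript", "regulator"},
    "enzyme": _COMPONENT_COMMON_KEYS | {"substrates", "products", "material"},
    "chemical_complex": _COMPONENT_COMMON_KEYS | {"members"},
    "dna_construct": _COMPONENT_COMMON_KEYS | {"parts", "topology"},
}


class ModelSpecError(CRNForgeError):
    """All validation problems of one document, reported together."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid model spec:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


def _build_mechanism(ref, problems, where: str) -> Mechanism | None:
    """A mechanism reference is a registry name or {name: ..., <options>}."""
    if isinstance(ref, str):
        name, config = ref, {}
    elif isinstance(ref, Mapping) and "name" in ref:
        config = dict(ref)
        name = config.pop("name")
    else:
        problems.append(f"{where}: cannot interpret mechanism reference {ref!r}")
        return None
    if name not in MECHANISM_REGISTRY:
        known = ", ".join(sorted(MECHANISM_REGISTRY))
        problems.append(f"{where}: unknown mechanism {name!r} (known: {known})")
        return None
    try:
        return make_mechanism(name, **config)
    except CRNForgeError as exc:
        problems.append(f"{where}: {exc}")
        return None


def _build_mechanism_map(section, problems, where: str) -> dict[str, Mechanism]:
    out: dict[str, Mechanism] = {}
    if section is None:
        return out
    if not isinstance(section, Mapping):
        problems.append(f"{where}: mechanisms must be a mapping of type -> name")
        return out
    for mtype, ref in section.items():
        mech = _build_mechanism(ref, problems, f"{where}.{mtype}")
        if mech is None:
            continue
        if mech.mechanism_type != mtype:
            problems.append(
                f"{where}.{mtype}: mechanism {mech.name!r} has type "
                f"{mech.mechanism_type!r}, not {mtype!r}"
            )
            continue
        out[mtype] = mech
    return out


def _build_parameters(section, base_dir: Path, problems) -> ParameterDatabase:
    db = ParameterDatabase()
    if section is None:
        return db
    if not isinstance(section, Mapping):
        problems.append("parameters: must be a mapping with files/values")
        return db
    unknown = set(section) - {"files", "values", "entries"}
    if unknown:
        problems.append(f"parameters: unknown key(s) {sorted(unknown)}")
    files = section.get("files", [])
    if isinstance(files, (str, Path)):
        files = [files]
    for fname in files:
        path = Path(fname)
        if not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            problems.append(f"parameters: file not found: {path}")
            continue
        try:
            db.update(load_parameter_file(path))
        except CRNForgeError as exc:
            problems.append(f"parameters: {exc}")
    values = section.get("values", {})
    if not isinstance(values, Mapping):
        problems.append("parameters.values: must be a mapping name -> number")
    else:
        for pname, value in values.items():
            if not isinstance(value, Real):
                problems.append(f"parameters.values.{pname}: {value!r} is not a number")
                continue
            db.add(str(pname), float(value), provenance="spec:values")
    entries = section.get("entries", [])
    for i, row in enumerate(entries):
        if not isinstance(row, Mapping) or "name" not in row or "value" not in row:
            problems.append(f"parameters.entries[{i}]: needs name and value")
            continue
        try:
            db.add(
                (row.get("mechanism"), row.get("part_id"), str(row["name"])),
                float(row["value"]), provenance=f"spec:entries[{i}]",
            )
        except (TypeError, ValueError, CRNForgeError) as exc:
            problems.append(f"parameters.entries[{i}]: {exc}")
    return db


def _build_component(entry, problems, index: int) -> Component | None:
    where = f"components[{index}]"
    if not isinstance(entry, Mapping):
        problems.append(f"{where}: must be a mapping")
        return None
    ctype = entry.get("type")
    if ctype not in COMPONENT_REGISTRY:
        known = ", ".join(sorted(COMPONENT_REGISTRY))
        problems.append(f"{where}: unknown component type {ctype!r} (known: {known})")
        return None
    if "name" not in entry:
        problems.append(f"{where}: missing required field 'name'")
        return None
    allowed = _COMPONENT_KEYS.get(ctype, _COMPONENT_COMMON_KEYS)
    unknown = set(entry) - allowed
    if unknown:
        problems.append(f"{where}: unknown field(s) {sorted(unknown)} for {ctype}")
        return None
    kwargs = {k: v for k, v in entry.items()
              if k not in ("type", "mechanisms", "parameters")}
    local_mechanisms = _build_mechanism_map(
        entry.get("mechanisms"), problems, f"{where}.mechanisms"
    )
    local_parameters = None
    if "parameters" in entry:
        if not isinstance(entry["parameters"], Mapping):
            problems.append(f"{where}.parameters: must be a mapping name -> number")
        else:
            local_parameters = ParameterDatabase(entry["parameters"])
    cls = COMPONENT_REGISTRY[ctype]
    try:
        return cls(mechanisms=local_mechanisms, parameters=local_parameters, **kwargs)
    except (TypeError, CRNForgeError) as exc:
        problems.append(f"{where}: {exc}")
        return None


def parse_model_spec(document: Mapping, base_dir=None) -> Mixture:
    """Construct a Mixture from a parsed model-spec mapping.

    The resulting mixture compiles exactly as the equivalent API calls.
    Raises :class:`ModelSpecError` listing every problem found.
    """
    problems: list[str] = []
    if not isinstance(document, Mapping):
        raise ModelSpecError(["document must be a mapping"])
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()
    unknown = set(document) - _TOP_LEVEL_KEYS
    if unknown:
        problems.append(f"unknown top-level key(s): {sorted(unknown)}")

    name = document.get("name", "model")
    kind = document.get("mixture", "custom")
    if kind not in MIXTURE_KINDS and kind != "custom":
        problems.append(
            f"mixture: unknown kind {kind!r}; expected one of "
            f"{MIXTURE_KINDS + ('custom',)}"
        )
        kind = "custom"

    parameters = _build_parameters(document.get("parameters"), base_dir, problems)
    overrides = _build_mechanism_map(document.get("mechanisms"), problems, "mechanisms")

    components = []
    raw_components = document.get("components", [])
    if not isinstance(raw_components, list):
        problems.append("components: must be a list")
        raw_components = []
    for i, entry in enumerate(raw_components):
        comp = _build_component(entry, problems, i)
        if comp is not None:
            components.append(comp)

    max_depth = document.get("max_depth", 8)
    if not isinstance(max_depth, int) or max_depth < 1:
        problems.append(f"max_depth: must be a positive integer, got {max_depth!r}")
        max_depth = 8

    initials = document.get("initial_concentrations", {})
    if not isinstance(initials, Mapping):
        problems.append("initial_concentrations: must be a mapping")
        initials = {}
    for target, value in initials.items():
        if not isinstance(value, Real) or value < 0:
            problems.append(
                f"initial_concentrations.{target}: must be a nonnegative number"
            )

    if problems:
        raise ModelSpecError(problems)

    if kind == "custom":
        mixture = Mixture(name, parameters=parameters)
    else:
        mixture = make_library_mixture(kind, parameters=parameters, name=name)
    mixture.mechanisms.update(overrides)
    for comp in components:
        mixture.add_component(comp)
    mixture.max_enumeration_depth = max_depth
    for target, value in initials.items():
        mixture.parameters.add(
            ParameterKey(None, str(target), INITIAL_CONCENTRATION),
            float(value), provenance="spec:initial_concentrations",
        )
    return mixture


def load_model_spec(path) -> Mixture:
    """Read a YAML model-spec file and construct its Mixture."""
    path = Path(path)
    try:
        document = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ModelSpecError([f"{path}: not valid YAML: {exc}"])
    if document is None:
        raise ModelSpecError([f"{path}: empty document"])
    return parse_model_spec(document, base_dir=path.parent)


def initial_concentrations(mixture: Mixture, crn) -> dict[Species, float]:
    """Read initial concentrations for *crn* species from the parameter
    database (key name ``initial_concentration``, part_id = canonical name;
    default 0)."""
    out: dict[Species, float] = {}
    for sp in crn.species:
        entry = mixture.parameters.get(
            ParameterKey(None, sp.canonical_name, INITIAL_CONCENTRATION)
        )
        if entry is not None:
            out[sp] = entry.value
    return out
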