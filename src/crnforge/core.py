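"""Core chemical reaction network (CRN) representation.

A CRN is a set of species :math:`S = \\{S_i\\}` together with reactions
:math:`I \\to O`, where *I* and *O* are multisets of species and each
reaction carries a propensity (rate law) :math:`\\rho(s; \\theta)`.

Species are typed (dna, rna, protein, complex, small molecule, or untyped)
and may carry attribute tags such as ``"machinery"`` or ``"degradable"``
which downstream filters (e.g. global mechanisms) act on.  Bound species
are represented by :class:`ComplexSpecies`, displayed by joining member
display names with ``":"`` (``dna_X:P`` is a promoter bound to polymerase).

Every species has a *canonical name*: a deterministic, injective string
identity used for deduplication, ordering, and SBML id generation.  The
canonical grammar is::

    simple   := material-prefix "_" name ("_" attribute)*
                (untyped species use the bare name)
    complex  := "complex_" member ("_" member)+          -- flat case
              | "complex" arity "(" member (":" member)* ")" ("_" attribute)*

The flat form is used when all members are simple and attribute-free and
the complex itself has no attributes; the delimited form covers nested or
attributed complexes, where naive concatenation would be ambiguous.
Species names and attribute tags may not contain whitespace, the separator
``"_"``, the delimiters ``":"``, ``"("``, ``")"``, and may not equal a
reserved material token — these constraints make the grammar uniquely
parseable, hence the canonical name injective.

Reversible processes are always stored as two irreversible reactions, and
zero-rate reactions are retained so that the compiled structure never
depends on parameter values.
"""

from __future__ import annotations

import ast
import logging
import math
import re
from collections import Counter
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "MATERIAL_TYPES",
    "Species",
    "ComplexSpecies",
    "Propensity",
    "Reaction",
    "CRN",
    "canonical_name",
    "make_complex",
    "evaluate_propensity",
    "reversible_pair",
    "assemble_crn",
    "CRNForgeError",
    "SpeciesError",
    "PropensityError",
]


class CRNForgeError(Exception):
    """Base class for all errors raised by this package."""


class SpeciesError(CRNForgeError, ValueError):
    """Invalid species construction."""


class PropensityError(CRNForgeError, ValueError):
    """Invalid propensity construction or evaluation."""


MATERIAL_TYPES = ("dna", "rna", "protein", "complex", "small_molecule", "none")

#: canonical-name prefix per material; tokens must not contain the separator
_MATERIAL_PREFIX = {
    "dna": "dna",
    "rna": "rna",
    "protein": "protein",
    "complex": "complex",
    "small_molecule": "smallmolecule",
    "none": "",
}

_RESERVED_TOKENS = frozenset(p for p in _MATERIAL_PREFIX.values() if p) | {"none"}
_NAME_RE = re.compile(r"^[^\s_:()]+$")
_COMPLEX_TOKEN_RE = re.compile(r"^complex\d*$")


def _validate_token(token: str, what: str) -> str:
    if not isinstance(token, str) or not token:
        raise SpeciesError(f"{what} must be a non-empty string, got {token!r}")
    if not _NAME_RE.match(token):
        raise SpeciesError(
            f"{what} {token!r} may not contain whitespace, '_', ':', '(' or ')'"
        )
    if token in _RESERVED_TOKENS or _COMPLEX_TOKEN_RE.match(token):
        raise SpeciesError(f"{what} {token!r} collides with a reserved material token")
    return token


def _normalize_attributes(attributes: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for tag in attributes:
        _validate_token(tag, "attribute tag")
        seen.setdefault(tag)
    return tuple(seen)


class Species:
    """A typed chemical species with optional attribute tags.

    Equality and hashing are structural: two species are equal iff their
    material type, name and attribute set coincide.
    """

    __slots__ = ("name", "material_type", "attributes")

    def __init__(
        self,
        name: str,
        material_type: str = "none",
        attributes: Iterable[str] = (),
    ):
        if material_type not in MATERIAL_TYPES:
            raise SpeciesError(
                f"unknown material type {material_type!r}; expected one of {MATERIAL_TYPES}"
            )
        if material_type == "complex" and type(self) is Species:
            raise SpeciesError("use ComplexSpecies/make_complex for complex material")
        object.__setattr__(self, "name", _validate_token(name, "species name"))
        object.__setattr__(self, "material_type", material_type)
        object.__setattr__(self, "attributes", _normalize_attributes(attributes))

    def __setattr__(self, *_):  # pragma: no cover - defensive
        raise AttributeError("Species objects are immutable")

    # -- identity ---------------------------------------------------------
    def _key(self):
        return (self.material_type, self.name, frozenset(self.attributes))

    def __eq__(self, other):
        return isinstance(other, Species) and self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    def __lt__(self, other: "Species"):
        return self.canonical_name < other.canonical_name

    # -- naming -----------------------------------------------------------
    @property
    def canonical_name(self) -> str:
        prefix = _MATERIAL_PREFIX[self.material_type]
        base = f"{prefix}_{self.name}" if prefix else self.name
        return base + "".join(f"_{a}" for a in sorted(self.attributes))

    @property
    def display(self) -> str:
        return self.canonical_name

    def with_attributes(self, *tags: str) -> "Species":
        return Species(self.name, self.material_type, self.attributes + tags)

    def __str__(self):
        return self.display

    def __repr__(self):
        attrs = f", attributes={list(self.attributes)!r}" if self.attributes else ""
        return f"Species({self.name!r}, {self.material_type!r}{attrs})"


class ComplexSpecies(Species):
    """Two or more species bound together, in a fixed member order.

    Nested complexes are preserved (never flattened): binding order is
    information that component enumeration relies on.  The display form
    joins member displays with ":" (so nesting is invisible in display but
    not in identity or canonical name).
    """

    __slots__ = ("members",)

    def __init__(self, members: Sequence[Species], attributes: Iterable[str] = ()):
        members = tuple(members)
        if len(members) < 2:
            raise SpeciesError("a complex needs at least 2 member species")
        for m in members:
            if not isinstance(m, Species):
                raise SpeciesError(f"complex member {m!r} is not a Species")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "name", ":".join(m.name for m in members))
        object.__setattr__(self, "material_type", "complex")
        object.__setattr__(self, "attributes", _normalize_attributes(attributes))

    def _key(self):
        return ("complex", self.members, frozenset(self.attributes))

    def __eq__(self, other):
        return isinstance(other, ComplexSpecies) and self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    @property
    def canonical_name(self) -> str:
        flat = not self.attributes and all(
            not isinstance(m, ComplexSpecies) and not m.attributes for m in self.members
        )
        if flat:
            return "complex_" + "_".join(m.canonical_name for m in self.members)
        inner = ":".join(m.canonical_name for m in self.members)
        suffix = "".join(f"_{a}" for a in sorted(self.attributes))
        return f"complex{len(self.members)}({inner}){suffix}"

    @property
    def display(self) -> str:
        return ":".join(m.display for m in self.members)

    def __repr__(self):
        attrs = f", attributes={list(self.attributes)!r}" if self.attributes else ""
        return f"ComplexSpecies({list(self.members)!r}{attrs})"


def canonical_name(species: Species) -> str:
    """Deterministic, injective string identity of *species*."""
    return species.canonical_name


def make_complex(members: Sequence[Species], attributes: Iterable[str] = ()) -> ComplexSpecies:
    """Bind *members* (>= 2, order preserved) into a :class:`ComplexSpecies`.

    Nested complexes stay nested: ``make_complex([make_complex([A, B]), C])``
    is a different species from ``make_complex([A, B, C])`` even though both
    display as ``"A:B:C"``.
    """
    return ComplexSpecies(members, attributes)


# ---------------------------------------------------------------------------
# Propensities
# ---------------------------------------------------------------------------

_HILL_KINDS = ("hill_positive", "hill_negative")
_KINDS = ("massaction",) + _HILL_KINDS + ("general",)

_ALLOWED_AST = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.Constant, ast.Name, ast.Load,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.USub, ast.UAdd,
)


def _check_finite(name: str, value) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise PropensityError(f"parameter {name!r} is not a number: {value!r}")
    if not math.isfinite(value):
        raise PropensityError(f"parameter {name!r} must be finite, got {value}")
    return value


class Propensity:
    """Rate law of a reaction: mass-action, Hill, or a general expression.

    Mass-action evaluates as ``k * prod(s_i ** n_i)`` over the reaction's
    input multiplicities (deterministic concentration convention).  The Hill
    forms saturate in a regulator species *r*, optionally scaled by a species
    *d* (e.g. the promoter concentration)::

        hill_negative: k * d * K**n / (K**n + r**n)
        hill_positive: k * d * r**n / (K**n + r**n)

    General propensities hold an arithmetic expression over species
    canonical names and named constants.
    """

    __slots__ = ("kind", "parameters", "regulator", "scaler", "expression")

    def __init__(
        self,
        kind: str,
        parameters: Mapping[str, float],
        regulator: Species | None = None,
        scaler: Species | None = None,
        expression: str | None = None,
    ):
        if kind not in _KINDS:
            raise PropensityError(f"unknown propensity kind {kind!r}")
        params = {k: _check_finite(k, v) for k, v in dict(parameters).items()}
        if kind == "massaction":
            if "k" not in params:
                raise PropensityError("massaction propensity requires parameter 'k'")
            if params["k"] < 0:
                raise PropensityError("massaction rate constant k must be >= 0")
        elif kind in _HILL_KINDS:
            for p in ("k", "K", "n"):
                if p not in params:
                    raise PropensityError(f"hill propensity requires parameter {p!r}")
            if params["K"] <= 0 or params["n"] <= 0:
                raise PropensityError("hill propensity requires K > 0 and n > 0")
            if not isinstance(regulator, Species):
                raise PropensityError("hill propensity requires a regulator species")
        elif kind == "general":
            if not expression or not isinstance(expression, str):
                raise PropensityError("general propensity requires an expression string")
            _compile_expression(expression)  # validate syntax eagerly
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "parameters", dict(params))
        object.__setattr__(self, "regulator", regulator)
        object.__setattr__(self, "scaler", scaler)
        object.__setattr__(self, "expression", expression)

    def __setattr__(self, *_):  # pragma: no cover - defensive
        raise AttributeError("Propensity objects are immutable")

    # constructors --------------------------------------------------------
    @classmethod
    def massaction(cls, k: float) -> "Propensity":
        return cls("massaction", {"k": k})

    @classmethod
    def hill_positive(cls, k, K, n, regulator: Species, scaler: Species | None = None):
        return cls("hill_positive", {"k": k, "K": K, "n": n}, regulator, scaler)

    @classmethod
    def hill_negative(cls, k, K, n, regulator: Species, scaler: Species | None = None):
        return cls("hill_negative", {"k": k, "K": K, "n": n}, regulator, scaler)

    @classmethod
    def general(cls, expression: str, **constants: float) -> "Propensity":
        return cls("general", constants, expression=expression)

    # identity ------------------------------------------------------------
    def _key(self):
        return (
            self.kind,
            frozenset(self.parameters.items()),
            self.regulator,
            self.scaler,
            self.expression,
        )

    def __eq__(self, other):
        return isinstance(other, Propensity) and self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    @property
    def species(self) -> list[Species]:
        """Species referenced by the rate law beyond the reaction inputs."""
        out = []
        if self.regulator is not None:
            out.append(self.regulator)
        if self.scaler is not None and self.scaler not in out:
            out.append(self.scaler)
        return out

    def describe(self) -> str:
        if self.kind == "massaction":
            return f"{self.parameters['k']:g}"
        if self.kind in _HILL_KINDS:
            p = self.parameters
            d = f",d={self.scaler.display}" if self.scaler is not None else ""
            return (
                f"{self.kind}(k={p['k']:g},K={p['K']:g},n={p['n']:g},"
                f"r={self.regulator.display}{d})"
            )
        return f"general({self.expression})"

    def __repr__(self):
        return f"Propensity({self.kind!r}, {self.parameters!r})"


def _compile_expression(expression: str) -> ast.Expression:
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise PropensityError(f"invalid propensity expression {expression!r}: {exc}")
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_AST):
            raise PropensityError(
                f"expression {expression!r} uses unsupported syntax "
                f"({type(node).__name__}); only +,-,*,/,** and names are allowed"
            )
    return tree


def _eval_expression(expression: str, env: Mapping[str, float]) -> float:
    tree = _compile_expression(expression)

    def ev(node):
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise PropensityError(f"non-numeric constant {node.value!r}")
            return float(node.value)
        if isinstance(node, ast.Name):
            if node.id not in env:
                raise PropensityError(
                    f"expression references unknown name {node.id!r}"
                )
            return env[node.id]
        if isinstance(node, ast.UnaryOp):
            v = ev(node.operand)
            return -v if isinstance(node.op, ast.USub) else +v
        if isinstance(node, ast.BinOp):
            a, b = ev(node.left), ev(node.right)
            if isinstance(node.op, ast.Add):
                return a + b
            if isinstance(node.op, ast.Sub):
                return a - b
            if isinstance(node.op, ast.Mult):
                return a * b
            if isinstance(node.op, ast.Div):
                return a / b
            if isinstance(node.op, ast.Pow):
                return a ** b
        raise PropensityError(f"unsupported expression node {node!r}")

    return ev(tree)


def _as_multiset(items) -> Counter:
    if isinstance(items, Counter):
        counts = Counter(items)
    elif isinstance(items, Mapping):
        counts = Counter(dict(items))
    else:
        counts = Counter(items)
    for sp, n in counts.items():
        if not isinstance(sp, Species):
            raise SpeciesError(f"{sp!r} is not a Species")
        if not isinstance(n, int) or n < 1:
            raise SpeciesError(f"stoichiometry of {sp} must be a positive integer")
    return counts


def evaluate_propensity(
    propensity: Propensity,
    inputs,
    state: Mapping[Species, float],
) -> float:
    """Evaluate *propensity* at a concentration *state* (Species -> value).

    The state must cover every species referenced by the rate law and, for
    mass-action, every reaction input.  Negative state values are rejected;
    the result is guaranteed nonnegative and finite.
    """
    inputs = _as_multiset(inputs)

    def lookup(sp: Species) -> float:
        if sp not in state:
            raise PropensityError(f"state is missing species {sp.display}")
        value = float(state[sp])
        if value < 0:
            raise PropensityError(f"negative concentration for {sp.display}: {value}")
        return value

    p = propensity.parameters
    if propensity.kind == "massaction":
        rate = p["k"]
        for sp, n in inputs.items():
            rate *= lookup(sp) ** n
    elif propensity.kind in _HILL_KINDS:
        r = lookup(propensity.regulator)
        d = lookup(propensity.scaler) if propensity.scaler is not None else 1.0
        K, n, k = p["K"], p["n"], p["k"]
        if propensity.kind == "hill_negative":
            rate = k * d * K ** n / (K ** n + r ** n)
        else:
            rate = k * d * r ** n / (K ** n + r ** n)
    else:  # general
        env = {sp.canonical_name: lookup(sp) for sp in state}
        env.update(p)
        rate = _eval_expression(propensity.expression, env)
    if not math.isfinite(rate) or rate < 0:
        raise PropensityError(
            f"propensity evaluated to a non-finite or negative rate: {rate}"
        )
    return rate


# ---------------------------------------------------------------------------
# Reactions
# ---------------------------------------------------------------------------

class Reaction:
    """An irreversible reaction: input multiset -> output multiset @ propensity."""

    __slots__ = ("inputs", "outputs", "propensity")

    def __init__(self, inputs, outputs, propensity: Propensity):
        in_counts = _as_multiset(inputs)
        out_counts = _as_multiset(outputs)
        if not in_counts and not out_counts:
            raise CRNForgeError("a reaction may not have empty inputs AND outputs")
        if not isinstance(propensity, Propensity):
            raise PropensityError(f"{propensity!r} is not a Propensity")
        key = lambda item: item[0].canonical_name
        object.__setattr__(self, "inputs", tuple(sorted(in_counts.items(), key=key)))
        object.__setattr__(self, "outputs", tuple(sorted(out_counts.items(), key=key)))
        object.__setattr__(self, "propensity", propensity)

    def __setattr__(self, *_):  # pragma: no cover - defensive
        raise AttributeError("Reaction objects are immutable")

    @classmethod
    def massaction(cls, inputs, outputs, k: float) -> "Reaction":
        return cls(inputs, outputs, Propensity.massaction(k))

    def _key(self):
        return (self.inputs, self.outputs, self.propensity)

    def __eq__(self, other):
        return isinstance(other, Reaction) and self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    @property
    def species(self) -> list[Species]:
        """All species participating in this reaction, inputs first."""
        seen: dict[Species, None] = {}
        for sp, _ in self.inputs + self.outputs:
            seen.setdefault(sp)
        for sp in self.propensity.species:
            seen.setdefault(sp)
        return list(seen)

    @staticmethod
    def _side(counts) -> str:
        if not counts:
            return "∅"
        return " + ".join(
            (f"{n} {sp.display}" if n > 1 else sp.display) for sp, n in counts
        )

    def __str__(self):
        return (
            f"{self._side(self.inputs)} --{self.propensity.describe()}--> "
            f"{self._side(self.outputs)}"
        )

    def __repr__(self):
        return f"Reaction<{self}>"


def reversible_pair(inputs, outputs, kf: float, kr: float) -> tuple[Reaction, Reaction]:
    """Represent a reversible process as two irreversible mass-action reactions.

    Returns ``(forward, reverse)``: inputs -> outputs @ *kf* and
    outputs -> inputs @ *kr*.  Zero rates are retained.
    """
    return (
        Reaction.massaction(inputs, outputs, kf),
        Reaction.massaction(outputs, inputs, kr),
    )


# ---------------------------------------------------------------------------
# CRN container
# ---------------------------------------------------------------------------

class CRN:
    """Deduplicated, order-stable container of species and reactions.

    Species and reactions keep first-encountered order, which makes
    recompilation of the same input byte-identical when serialized.
    ``metadata`` carries compilation provenance (never part of equality).
    """

    def __init__(self, name: str = "crn", species=(), reactions=()):
        self.name = name
        self._species: dict[Species, None] = {}
        self._reactions: list[Reaction] = []
        self._reaction_set: set[Reaction] = set()
        self.metadata: dict = {}
        for sp in species:
            self.add_species(sp)
        for rx in reactions:
            self.add_reaction(rx)

    # -- construction ------------------------------------------------------
    def add_species(self, species: Species) -> bool:
        if not isinstance(species, Species):
            raise SpeciesError(f"{species!r} is not a Species")
        if species in self._species:
            logger.warning("duplicate species dropped: %s", species.display)
            return False
        self._species[species] = None
        return True

    def add_reaction(self, reaction: Reaction) -> bool:
        if not isinstance(reaction, Reaction):
            raise CRNForgeError(f"{reaction!r} is not a Reaction")
        for sp in reaction.species:
            if sp not in self._species:
                self._species[sp] = None
        if reaction in self._reaction_set:
            logger.warning("duplicate reaction dropped: %s", reaction)
            return False
        self._reactions.append(reaction)
        self._reaction_set.add(reaction)
        return True

    # -- access ------------------------------------------------------------
    @property
    def species(self) -> list[Species]:
        return list(self._species)

    @property
    def reactions(self) -> list[Reaction]:
        return list(self._reactions)

    def __eq__(self, other):
        return (
            isinstance(other, CRN)
            and self.species == other.species
            and self.reactions == other.reactions
        )

    def __hash__(self):  # pragma: no cover - containers rarely hashed
        return hash((tuple(self._species), tuple(self._reactions)))

    def __repr__(self):
        return f"CRN({self.name!r}: {len(self._species)} species, {len(self._reactions)} reactions)"

    # -- serialization ------------------------------------------------------
    def pretty_print(self) -> str:
        """One reaction per line, ``A + B --k--> C`` format, species header."""
        lines = [f"# CRN {self.name}: {len(self._species)} species, "
                 f"{len(self._reactions)} reactions"]
        lines.append("# species: " + ", ".join(sp.display for sp in self._species))
        lines.extend(str(rx) for rx in self._reactions)
        return "\n".join(lines) + "\n"

    def graph_edges(self) -> list[str]:
        """Bipartite species/reaction graph, one tab-separated edge per line.

        Reaction nodes are labeled ``r<i>`` by position; an edge
        ``species -> r<i>`` marks an input, ``r<i> -> species`` an output.
        """
        edges = []
        for i, rx in enumerate(self._reactions):
            rid = f"r{i}"
            for sp, _ in rx.inputs:
                edges.append(f"{sp.canonical_name}\t{rid}")
            for sp, _ in rx.outputs:
                edges.append(f"{rid}\t{sp.canonical_name}")
        return edges

    def write_graph(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.graph_edges()) + "\n")


def assemble_crn(species: Iterable[Species], reactions: Iterable[Reaction],
                 name: str = "crn") -> CRN:
    """Assemble a CRN, deduplicating species and reactions.

    Any reaction participant missing from *species* is auto-added; order is
    first-encountered and stable, so assembly is idempotent and
    deterministic.  A log warning is emitted per duplicate dropped.
    """
    crn = CRN(name=name)
    for sp in species:
        crn.add_species(sp)
    for rx in reactions:
        crn.add_reaction(rx)
    return crn
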