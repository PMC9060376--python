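"""Compilation-time component enumeration.

Enumerators generate new components from existing ones: *local* enumerators
act on the single component that owns them, *global* enumerators on the
whole component set.  Both implement a function g: C -> C' with C ⊆ C' and
are iterated to a fixed point or a recursion-depth cap (new components may
themselves carry enumerators, so closure can grow round by round).
Component identity for fixed-point detection is the component name.

The shipped local enumerator is the transcript scanner: a
:class:`DNAConstruct` lists ordered, oriented parts (promoters, RBSs,
coding sequences, terminators) on a linear or circular DNA; every promoter
is scanned in its own orientation, collecting in-orientation RBS/CDS parts
up to the first in-orientation terminator, and yields an
:class:`RNAConstruct` modeling that transcript's transcription and
translation.  Promoters with no terminator in frame produce a run-off
transcript (to the construct end, or one full revolution on circular DNA);
this permissive choice is flagged in the logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import CRNForgeError, Species
from .components import Component, register_component
from .mechanisms import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentEnumerator",
    "enumerate_fixed_point",
    "Part",
    "parse_part",
    "parse_parts",
    "DNAConstruct",
    "RNAConstruct",
    "Transcript",
    "transcript_enumeration",
    "TranscriptEnumerator",
]

PART_TYPES = ("promoter", "rbs", "cds", "terminator")
ORIENTATIONS = ("forward", "reverse")


class ComponentEnumerator:
    """Base class: a deterministic function from components to new components.

    ``scope`` is ``"local"`` (applied to the owning component only) or
    ``"global"`` (applied to the whole mixture set).  :meth:`enumerate`
    returns the *new* components; the framework forms the union with the
    input set, so enumeration never removes components.
    """

    scope = "global"

    def enumerate(self, components: Sequence[Component]) -> Iterable[Component]:
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}(scope={self.scope})"


def enumerate_fixed_point(initial: Sequence[Component],
                          enumerators: Sequence[ComponentEnumerator] = (),
                          max_depth: int = 8,
                          include_local: bool = True) -> list[Component]:
    """Iterate enumerators to a fixed point or the depth cap.

    Each round applies every global enumerator in *enumerators* to the full
    current set and (when *include_local*) every component's own local
    enumerators to that component, including components created in earlier
    rounds.  Returns a superset of *initial* in stable first-created order;
    warns if the depth cap was hit before the fixed point.
    """
    if max_depth < 1:
        raise CRNForgeError(f"max_depth must be >= 1, got {max_depth}")
    components = list(initial)
    names = {c.name for c in components}

    def one_round(current: list[Component]) -> list[Component]:
        produced: list[Component] = []
        for enum in enumerators:
            produced.extend(enum.enumerate(list(current)))
        if include_local:
            for comp in current:
                for enum in getattr(comp, "local_enumerators", ()):
                    produced.extend(enum.enumerate([comp]))
        fresh = []
        seen = set(names)
        for comp in produced:
            if comp.name not in seen:
                seen.add(comp.name)
                fresh.append(comp)
        return fresh

    for _ in range(max_depth):
        fresh = one_round(components)
        if not fresh:
            return components
        components.extend(fresh)
        names.update(c.name for c in fresh)
    # cap reached: warn only if another round would still create components
    if one_round(components):
        logger.warning(
            "component enumeration stopped at depth cap %d before reaching a "
            "fixed point (%d components so far)", max_depth, len(components),
        )
    return components


# ---------------------------------------------------------------------------
# DNA constructs and transcript enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Part:
    """One oriented part on a DNA construct."""

    name: str
    part_type: str
    orientation: str = "forward"

    def __post_init__(self):
        if self.part_type not in PART_TYPES:
            raise ConfigurationError(
                f"unknown part type {self.part_type!r}; expected one of {PART_TYPES}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(
                f"unknown orientation {self.orientation!r}; expected forward|reverse"
            )
        Species(self.name)  # share the species-name grammar

    def __str__(self):
        return f"{self.name}:{self.part_type}:{self.orientation}"


def parse_part(token: str) -> Part:
    """Parse ``"name:type:orientation"`` (orientation defaults to forward)."""
    fields = [f.strip() for f in token.split(":")]
    if len(fields) == 2:
        fields.append("forward")
    if len(fields) != 3:
        raise ConfigurationError(
            f"cannot parse part token {token!r}; expected name:type[:orientation]"
        )
    return Part(*fields)


def parse_parts(text: str) -> list[Part]:
    """Parse a comma-separated part list."""
    return [parse_part(tok) for tok in text.split(",") if tok.strip()]


@dataclass(frozen=True)
class Transcript:
    """One enumerated transcript: which promoter fired, where it stopped,
    and the in-orientation RBS/CDS parts it covers in 5'->3' read order."""

    promoter_index: int
    promoter_name: str
    orientation: str
    terminator_index: int | None  # None => run-off / full-circle transcript
    parts: tuple[Part, ...]

    @property
    def runoff(self) -> bool:
        return self.terminator_index is None


class DNAConstruct(Component):
    """A DNA component whose part list is scanned for transcripts.

    Carries a :class:`TranscriptEnumerator` as a local enumerator by
    default, so compilation expands it into one :class:`RNAConstruct` per
    enumerated transcript.  Emits its own dna-material species.
    """

    component_type = "dna_construct"

    def __init__(self, name: str, parts: Sequence[Part] | str,
                 topology: str = "linear", enumerators=None, **kwargs):
        if isinstance(parts, str):
            parts = parse_parts(parts)
        parts = [p if isinstance(p, Part) else Part(*p) for p in parts]
        if not parts:
            raise ConfigurationError(f"construct {name!r} needs a non-empty part list")
        if topology not in ("linear", "circular"):
            raise ConfigurationError(
                f"topology must be linear|circular, got {topology!r}"
            )
        if enumerators is None:
            enumerators = [TranscriptEnumerator()]
        super().__init__(name, enumerators=enumerators, **kwargs)
        self.parts = tuple(parts)
        self.topology = topology

    @property
    def dna_species(self) -> Species:
        return Species(self.name, "dna")

    def update(self, ctx):
        return [self.dna_species], []

    def reversed_construct(self) -> "DNAConstruct":
        """Mirror image: reversed part order with every orientation flipped."""
        flip = {"forward": "reverse", "reverse": "forward"}
        parts = [Part(p.name, p.part_type, flip[p.orientation])
                 for p in reversed(self.parts)]
        return DNAConstruct(self.name, parts, topology=self.topology,
                            enumerators=list(self.local_enumerators))


def transcript_enumeration(construct: DNAConstruct) -> list[Transcript]:
    """Scan every promoter for its transcript (see module docstring).

    Forward promoters scan rightward over forward-oriented parts; reverse
    promoters scan leftward over reverse-oriented parts.  Circular
    constructs wrap at most one full revolution.  The first in-orientation
    terminator stops the scan (terminators are absolute); without one the
    transcript runs off and is flagged in the log.
    """
    parts = construct.parts
    n = len(parts)
    circular = construct.topology == "circular"
    transcripts = []
    for i, promoter in enumerate(parts):
        if promoter.part_type != "promoter":
            continue
        step = 1 if promoter.orientation == "forward" else -1
        collected: list[Part] = []
        terminator_index: int | None = None
        for k in range(1, n):
            j = i + step * k
            if not circular and not 0 <= j < n:
                break
            j %= n
            part = parts[j]
            if part.orientation != promoter.orientation:
                continue
            if part.part_type == "terminator":
                terminator_index = j
                break
            if part.part_type in ("rbs", "cds"):
                collected.append(part)
        if terminator_index is None:
            logger.debug(
                "construct %s: promoter %s has no in-frame terminator; "
                "emitting a run-off transcript", construct.name, promoter.name,
            )
        transcripts.append(Transcript(
            promoter_index=i,
            promoter_name=promoter.name,
            orientation=promoter.orientation,
            terminator_index=terminator_index,
            parts=tuple(collected),
        ))
    return transcripts


class RNAConstruct(Component):
    """An RNA component produced by the transcript scan.

    Emits the transcription reaction from its source DNA (via the resolved
    transcription mechanism) and one translation reaction per adjacent
    (RBS, CDS) pair in transcript order, each protein named after its CDS.
    Contains no promoter or terminator parts by construction.
    """

    component_type = "rna_construct"

    def __init__(self, name: str, source_dna: str, transcript: Transcript,
                 **kwargs):
        super().__init__(name, **kwargs)
        for part in transcript.parts:
            if part.part_type not in ("rbs", "cds"):
                raise ConfigurationError(
                    f"RNA construct {name!r} may only carry rbs/cds parts, "
                    f"got {part.part_type}"
                )
        self.source_dna = source_dna
        self.transcript = transcript

    @property
    def rna_species(self) -> Species:
        return Species(self.name, "rna")

    @property
    def dna_species(self) -> Species:
        return Species(self.source_dna, "dna")

    def translation_pairs(self) -> list[tuple[Part, Part]]:
        pairs = []
        parts = self.transcript.parts
        for a, b in zip(parts, parts[1:]):
            if a.part_type == "rbs" and b.part_type == "cds":
                pairs.append((a, b))
        return pairs

    def update(self, ctx):
        species = [self.dna_species, self.rna_species]
        reactions = []
        tx = ctx.resolve_mechanism(self, "transcription")
        params = ctx.resolve_parameters(
            self, tx, extra_part_ids=[self.transcript.promoter_name, self.source_dna]
        )
        sp, rx = tx.update(params, dna=self.dna_species,
                           transcript=self.rna_species, regulator=None)
        species.extend(sp)
        reactions.extend(rx)
        for rbs, cds in self.translation_pairs():
            tl = ctx.resolve_mechanism(self, "translation")
            params = ctx.resolve_parameters(self, tl, extra_part_ids=[rbs.name])
            sp, rx = tl.update(params, rna=self.rna_species,
                               protein=Species(cds.name, "protein"))
            species.extend(sp)
            reactions.extend(rx)
        return species, reactions


class TranscriptEnumerator(ComponentEnumerator):
    """Local enumerator turning a DNAConstruct into RNAConstructs."""

    scope = "local"

    def enumerate(self, components):
        out = []
        for comp in components:
            if not isinstance(comp, DNAConstruct):
                continue
            for t in transcript_enumeration(comp):
                name = f"{comp.name}-tx{t.promoter_index}"
                out.append(RNAConstruct(
                    name, source_dna=comp.name, transcript=t,
                    mechanisms=dict(comp.local_mechanisms),
                    parameters=comp.local_parameters,
                ))
        return out


register_component("dna_construct", DNAConstruct)
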