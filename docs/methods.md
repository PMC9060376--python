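# Methods

This note records the modeling conventions, numerical choices and open
design decisions behind `crnforge`, in the order a model flows through the
compiler.

## The CRN representation

A chemical reaction network is a species set *S* = {Sᵢ} plus reactions
I → O over multisets I, O, each with a propensity ρ(s; θ). Species carry a
material type (`dna`, `rna`, `protein`, `small_molecule`, `complex`, or
untyped) and an ordered set of attribute tags; equality is structural.
Bound species are `ComplexSpecies` with an ordered member list; nesting is
preserved, never flattened, because binding order is information (the
display form `A:B:C` is the same for `(A:B):C` and `A:B:C`, but identity
and canonical name differ).

**Canonical naming.** Every species has a deterministic, injective
canonical name used for ordering, deduplication and SBML ids. Simple
species use `material_name` (`dna_X`), untyped species the bare name, with
attribute tags appended sorted (`rna_X_a_b`). Flat, attribute-free
complexes of simple members concatenate member names
(`complex_dna_X_protein_P`). Naive concatenation is ambiguous for nested
or attributed complexes (e.g. `outer(inner(A,B),C,D)` and
`outer(inner(A,B,C),D)` would collide), so those use a delimited form
`complex<arity>(member:member)` with the attribute suffix outside the
parentheses. Injectivity rests on the name grammar: species names and tags
may not contain whitespace, `_`, `:`, `(`, `)` and may not equal a
reserved material token; it is property-tested over random species trees.
`small_molecule` uses the prefix `smallmolecule` to keep the grammar
separator-free.

**Propensities.** Mass-action evaluates as k·∏sᵢ^nᵢ over input
multiplicities — the deterministic concentration convention (s², not
s(s−1)), matching ODE semantics. Hill forms are
k·d·Kⁿ/(Kⁿ+rⁿ) (repression) and k·d·rⁿ/(Kⁿ+rⁿ) (activation) with
regulator r and an optional scaling species d (the template; d ≡ 1 when
unset); K > 0 and n > 0 are enforced at construction. The two forms with
shared parameters partition k·d at every state, which the tests exploit.
General propensities are arithmetic expressions (`+ - * / **` over species
canonical names and named constants) evaluated by a whitelisted AST walker;
evaluation at any nonnegative state must be nonnegative and finite, and is
checked.

**Structural conventions.** Reversible processes are always stored as two
irreversible mass-action reactions, so propensity handling is uniform and
SBML sets `reversible="false"` throughout. Zero-rate reactions are
retained: pruning would make the compiled *structure* depend on parameter
values. CRN assembly deduplicates species (structural equality) and
reactions (same inputs, outputs and propensity), auto-adds any reaction
participant — including Hill regulators — to the species set, and keeps
first-encountered order, which makes assembly idempotent and recompilation
byte-identical.

## Parameters

Entries are keyed by (mechanism, part_id, name), with either context field
optional. Lookup walks a fixed most-specific-first order: (mechanism
instance, part), (mechanism type, part), (·, part), (mechanism instance, ·),
(mechanism type, ·), (·, ·). When a context field is unspecified the
collapsed key keeps its least-specific position, so genuinely more specific
keys are always tried first and an exact entry can never be shadowed.
Components resolve parameters against their own database first, then the
mixture's; within each database, part-specific tiers for the component name
are tried before sub-part tiers (promoter/RBS names), before the part-less
fallbacks — so a promoter-specific entry beats the global default but not an
assembly-specific one. Every resolution is recorded (requested name,
matched key, source), exposed in the compiled CRN's metadata and via
`crnforge params-audit`; misses raise an error naming the full attempted
key sequence. Parameter files are delimited UTF-8 text (tab or comma,
auto-detected) with columns `mechanism`, `part_id`, `param_name`, `value`;
blank cells mean unspecified, later duplicate rows win with a warning, and
write/load round-trips exactly.

Parameter names follow the field's shorthand: `kb`/`ku` (binding and
unbinding, 1/(conc·time) and 1/time), `ktx`/`ktl` (catalytic transcription
and translation rates, 1/time), `kcat`, `kdeg`, `kdil` (1/time), Hill `K`
(concentration) and `n` (dimensionless), leak `ktx_leak`. Units are the
caller's responsibility; the compiler only checks finiteness and
positivity where the rate law requires it.

## Mechanisms

Mechanisms are pure functions: identical inputs and parameters give
identical output, and every species referenced by an emitted reaction is in
the returned species set. Transcription is available at four resolutions —
one-step catalytic, Michaelis–Menten with explicit polymerase
(template + P ⇌ template:P → template + P + transcript), quasi-equilibrium
Hill (optionally with a mass-action leak, default 0), and multi-occupancy.
Multi-occupancy kinetics are this package's choice of the simplest
exchangeable-polymerase model: loading is occupancy-independent at `kb` up
to the cap m, while state i (the template with i bound polymerases) unbinds
at i·ku and produces at i·ktx; with m = 1 this is reaction-for-reaction the
Michaelis–Menten schema. Catalysis, one-step binding (n members associate
in a single step — homo-multimers are nA ⇌ Aₙ, not sequential assembly,
which would need an ordered mechanism the package does not define) and
RNase degradation (target + RNase ⇌ target:RNase → RNase) follow the same
templates. Degenerate inputs that would silently create autocatalysis
(transcript = template, protein = transcript) are rejected.

## Components and mixtures

A component is not a species: it may emit zero, one or many. A DNA
assembly emits its dna species always, transcription iff a promoter is
set, translation iff RBS and protein are set (an RBS without a protein is
rejected as a configuration error); transcript and protein species default
to the assembly/product names with rna/protein materials. Mechanism
resolution is local-first, then mixture, and a component carrying all its
own mechanisms and parameters compiles to the identical sub-CRN in any
mixture — tested by diffing.

Compilation runs seven ordered steps: global enumeration, local
enumeration, component updates (with mechanism and parameter resolution
inside), global mechanisms, assembly. Component iteration follows
declaration order (enumerated components append after their creators),
which fixes the output ordering. Global mechanisms are applied exactly
once per species produced by the earlier steps and never to species they
themselves create; the compiled CRN's metadata records both the trigger of
every global-mechanism reaction and the species created in that step, so
non-recursion is checkable after the fact. Machinery species (polymerase,
ribosome, RNase) in the `txtl_machinery` bundle carry the `"machinery"`
attribute and are exempted from degradation/dilution filters — without the
exemption the context would degrade its own machinery. Initial
concentrations are not part of the CRN proper; they live in the parameter
database under the name `initial_concentration` with the species canonical
name as part_id (default 0) and are written into SBML at export.

## Component enumeration

Enumerators implement g: C → C′ with C ⊆ C′ and are iterated until no new
component appears or a depth cap is reached (default 8; the cap warns only
when a further round would still grow the set). Identity for fixed-point
detection is the component name, which prevents infinite renaming loops but
means two different components may not share a name. The transcript
scanner reads each promoter in its own orientation, collecting
in-orientation RBS/CDS parts up to the first in-orientation terminator
(terminators are absolute; leaky termination is out of scope); opposite-
strand parts are invisible. A promoter with no terminator in frame yields
a run-off transcript to the construct end — or one full revolution on
circular DNA, never more — a permissive choice flagged in the logs. Each
resulting RNA component emits its transcription reaction and one
translation per adjacent (RBS, CDS) pair in transcript order. The scanner
is verified against an independent oracle that ranks candidate terminators
by scan distance, on 500 seeded random constructs up to 12 parts, plus a
mirror-image property (reversing a construct and flipping orientations
mirrors the transcript set).

## SBML export

Documents are SBML Level 3 Version 1 core, one compartment, no packages
and no model history — output is byte-stable, so export → parse → re-export
is identical. Species ids are sanitized canonical names (`:` → `_`, other
illegal characters → `_x<hex>_`, leading digit prefixed); sanitization
preserves injectivity and an id collision is asserted impossible at export.
Mass-action laws are written `k * reactant…` with `k` a local parameter;
Hill and general laws become explicit formulas over reaction-scoped global
parameters (`K_r3`), with off-stoichiometry species (the Hill regulator)
declared as modifiers. Plain core with explicit formulas was chosen over
annotation-based encodings to maximize downstream simulator compatibility.

## Fixtures and what they do (not) show

The worked expression example reconstructs a single assembly `X` with
parameters kb=100, ku=10, ktx=0.1, ktl=0.5 and compiles to a 3-species/
2-reaction network under one-step schemas and a 7-species/6-reaction
network under Michaelis–Menten schemas. Circuit fixtures (repression
cascade, toggle switch, repressilator) use negative Hill transcription
with fixture defaults K=20, n=2, kdil=0.01 on top of the four expression
rates — round ball-park values typical of bacterial gene expression, not
measurements. Random constructs draw part types uniformly (weights
configurable), orientations 50/50 and topology 50/50 from a seeded
generator. These fixtures exercise the compiler's structure — resolution,
enumeration, determinism, export — not biological accuracy: passing tests
show the networks are *assembled* correctly under the stated conventions,
not that the rate values predict any real circuit's dynamics, and no ODE
or stochastic simulation is performed anywhere in the package.

Problem sizes used by the test suite and `scripts/acceptance.py` (500
constructs of ≤ 12 parts, dimerizer closures to depth 3, four exported
fixtures) were chosen to exercise every code path at interactive runtimes.

## Known limitations

No unit checking or parameter uncertainty; no stochastic (combinatoric)
propensity convention; no ordered-polymer species class beyond what the
transcript scanner needs; no leaky terminators or multi-revolution circular
reads; no integrase/recombination model ships (the global-enumerator
framework supports writing one); SBML import of foreign models and SBOL
are out of scope.
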