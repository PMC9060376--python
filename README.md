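# crnforge

Compile part-based biomolecular designs into explicit chemical reaction
networks (CRNs) and export them as SBML.

Synthetic biologists and systems modelers describe circuits in terms of
*parts* (promoters, enzymes, binding complexes) and *contexts* (a cell-free
extract, an idealized expression system), but simulators consume explicit
reaction networks. Writing those networks by hand is error-prone and freezes
one set of modeling assumptions into the model. `crnforge` separates the two
concerns:

* **Components** are parts: an expressible DNA assembly, an enzyme, a
  chemical complex, a multi-part DNA construct.
* **Mechanisms** are reaction schemas — functions *f*(S′, θ) → (S, R) from
  input species and rate parameters to generated species and reactions.
  The same process can be modeled at different resolutions: one-step
  catalytic transcription, explicit Michaelis–Menten polymerase binding, a
  quasi-equilibrium Hill rate law, or multi-occupancy polymerase loading.
* **Mixtures** are contexts: a bundle of components, default mechanisms,
  *global* mechanisms (dilution, RNA degradation — applied once,
  non-recursively, to every compiled species passing a filter), and a
  parameter database with a six-tier defaulting hierarchy, so a handful of
  ball-park rates can drive a full compilation and be refined later.

Compiling the same component under different mechanisms or mixtures yields
different CRNs without rewriting the design. A CRN here is a species set
*S* = {Sᵢ} plus reactions I → O, each carrying a propensity ρ(s; θ)
(mass-action k·∏sᵢ^nᵢ, Hill k·d·Kⁿ/(Kⁿ+rⁿ) and its activating mirror, or a
general expression). Reversible steps are stored as two irreversible
reactions. `crnforge` is a compiler, not a simulator: models are exported
as plain SBML Level 3 Version 1 for the simulator of your choice.

## Worked example

One expressible DNA part `X` (promoter + RBS + CDS) in a four-parameter
context:

```python
from crnforge import DNAassembly, Mixture, SimpleTranscription, SimpleTranslation

G = DNAassembly("X", promoter="prom", rbs="rbs", protein="X")
M = Mixture("mixture", components=[G],
            mechanisms=[SimpleTranscription(), SimpleTranslation()],
            parameters={"kb": 100, "ku": 10, "ktx": 0.1, "ktl": 0.5})
print(M.compile_crn().pretty_print())
```

```
# CRN mixture: 3 species, 2 reactions
# species: dna_X, rna_X, protein_X
dna_X --0.1--> dna_X + rna_X
rna_X --0.5--> protein_X + rna_X
```

The gene transcribes catalytically at 0.1 and the transcript translates at
0.5; binding parameters `kb`/`ku` sit unused in the database. Swap in
explicit machinery — only the two mechanism lines change:

```python
from crnforge import MichaelisMentenTranscription, MichaelisMentenTranslation, Species

M.mechanisms = {}
M.add_mechanism(MichaelisMentenTranscription(rnap=Species("P")))
M.add_mechanism(MichaelisMentenTranslation(ribosome=Species("R")))
print(M.compile_crn().pretty_print())
```

```
# CRN mixture: 7 species, 6 reactions
# species: dna_X, P, dna_X:P, rna_X, R, rna_X:R, protein_X
P + dna_X --100--> dna_X:P
dna_X:P --10--> P + dna_X
dna_X:P --0.1--> P + dna_X + rna_X
R + rna_X --100--> rna_X:R
rna_X:R --10--> R + rna_X
rna_X:R --0.5--> R + protein_X + rna_X
```

Now polymerase `P` and ribosome `R` bind reversibly (100 forward, 10 back,
`:` marks a bound complex) before the same catalytic steps — the identical
design at a finer modeling resolution, with every parameter resolved
through the same defaulting database.

## Command line

Declarative YAML model specs compile from the shell (shipped examples live
in `src/crnforge/examples/`):

```bash
crnforge compile example_2_7.yaml        # writes .xml, .crn.txt, .edges.txt
crnforge inspect toggle_switch.yaml      # print species and reactions
crnforge params-audit example_2_7_mm.yaml  # which key matched each lookup
crnforge --seed 7 fixture random-construct --length 8
```

Beyond gene expression, the library ships Hill-repression circuit fixtures
(repression cascade, toggle switch, repressilator), enzymatic catalysis and
one-step binding schemas, RNase degradation and dilution as global
mechanisms, and compilation-time *component enumeration*: local and global
enumerators iterate g: C → C′ to a fixed point (or depth cap), including a
transcript scanner that reads oriented part lists on linear or circular DNA
constructs and expands every promoter–terminator frame into an RNA
component with its own translation products.

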