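# Single expressible DNA assembly X under one-step transcription/translation.
# Compiles to the two-reaction catalytic expression network:
#   dna_X -> dna_X + rna_X     @ 0.1
#   rna_X -> rna_X + protein_X @ 0.5
name: expression-simple
mixture: expression_simple
components:
  - type: dna_assembly
    name: X
    promoter: prom
    rbs: rbs
    protein: X
parameters:
  values:
    kb: 100
    ku: 10
    ktx: 0.1
    ktl: 0.5
initial_concentrations:
  dna_X: 1.0
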