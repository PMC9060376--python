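# The same assembly X with Michaelis-Menten transcription/translation:
# explicit polymerase (P) and ribosome (R) binding.
#   dna_X + P <-> dna_X:P -> dna_X + P + rna_X        @ 100 / 10 / 0.1
#   rna_X + R <-> rna_X:R -> rna_X + R + protein_X    @ 100 / 10 / 0.5
name: expression-mm
mixture: expression_mm
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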