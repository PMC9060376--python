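# Three-gene ring oscillator: C represses A, A represses B, B represses C.
name: repressilator
mixture: expression_simple
components:
  - type: dna_assembly
    name: A
    promoter: prom
    rbs: rbs
    protein: A
    regulator: protein:C
    mechanisms:
      transcription: negative_hill_transcription
  - type: dna_assembly
    name: B
    promoter: prom
    rbs: rbs
    protein: B
    regulator: protein:A
    mechanisms:
      transcription: negative_hill_transcription
  - type: dna_assembly
    name: C
    promoter: prom
    rbs: rbs
    protein: C
    regulator: protein:B
    mechanisms:
      transcription: negative_hill_transcription
parameters:
  values:
    ktx: 0.1
    ktl: 0.5
    K: 20
    n: 2
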