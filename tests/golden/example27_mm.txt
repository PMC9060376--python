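# CRN mixture: 7 species, 6 reactions
# species: dna_X, P, dna_X:P, rna_X, R, rna_X:R, protein_X
P + dna_X --100--> dna_X:P
dna_X:P --10--> P + dna_X
dna_X:P --0.1--> P + dna_X + rna_X
R + rna_X --100--> rna_X:R
rna_X:R --10--> R + rna_X
rna_X:R --0.5--> R + protein_X + rna_X
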