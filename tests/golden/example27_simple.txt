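# CRN mixture: 3 species, 2 reactions
# species: dna_X, rna_X, protein_X
dna_X --0.1--> dna_X + rna_X
rna_X --0.5--> protein_X + rna_X
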