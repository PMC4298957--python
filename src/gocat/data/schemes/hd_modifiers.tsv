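# Nine broad biological-process categories used for analyses of genetic
# modifiers of Huntington's disease. One seed GO term per category.
cell_cycle	GO:0007049
cytoskeleton	GO:0007010
metabolism	GO:0008152
protein_synthesis	GO:0010467
protein_folding	GO:0006457
proteolysis	GO:0006508
signaling	GO:0007165
splicing	GO:0008380
transport	GO:0006810
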