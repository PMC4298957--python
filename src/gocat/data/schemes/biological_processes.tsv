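# General-purpose biological-process scheme: 27 categories.
# Seed GO IDs are maintainer-curated choices for each named category.
cell_cycle	GO:0007049
cytoskeleton	GO:0007010
metabolism	GO:0008152
transcription	GO:0006351
translation	GO:0006412
protein_folding	GO:0006457
proteolysis	GO:0006508
signaling	GO:0007165
rna_processing	GO:0006396
splicing	GO:0008380
transmembrane_transport	GO:0055085
intracellular_localization	GO:0051649
protein_transport	GO:0015031
nuclear_transport	GO:0051169
vesicles	GO:0016192
golgi_er	GO:0007030
golgi_er	GO:0007029
mitochondria	GO:0007005
endo_exocytosis	GO:0006897
endo_exocytosis	GO:0006887
lysosome	GO:0007040
peroxisome	GO:0007031
ribosomes	GO:0042254
phagocytosis_phagosome	GO:0006909
autophagy	GO:0006914
apoptosis	GO:0006915
dna_repair	GO:0006281
dna_replication	GO:0006260
receptors	GO:0007166
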