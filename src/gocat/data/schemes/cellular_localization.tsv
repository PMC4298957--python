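# Cellular-localization scheme: 8 categories (cellular_component namespace).
# Seed GO IDs are maintainer-curated choices for each named category.
cytoplasm	GO:0005737
mitochondria	GO:0005739
golgi	GO:0005794
nucleus	GO:0005634
cytoskeleton	GO:0005856
vesicle_lysosome	GO:0031982
vesicle_lysosome	GO:0005764
er	GO:0005783
extracellular	GO:0005576
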