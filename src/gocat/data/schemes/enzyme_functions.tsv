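# Enzyme-function scheme: 6 categories (molecular_function namespace).
# Seed GO IDs are maintainer-curated choices for each named category.
hydrolase	GO:0016787
isomerase	GO:0016853
ligase	GO:0016874
lyase	GO:0016829
oxidoreductase	GO:0016491
transferase	GO:0016740
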