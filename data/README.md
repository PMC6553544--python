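# External validation data (not redistributed)

To run the published-pair-table reproduction check, download the rainbow
trout ohnolog pair table (Supplemental File S1 of the source study, FigShare
doi:10.25387/g3.7732358), convert it to the pipeline's pair-table TSV
dialect — tab-separated columns `gene_a`, `gene_b`, `pid`, `mode`
(`disomic`/`tetrasomic`), `block_label` — and save it here as
`published_pair_table.tsv`.

Everything else in the test suite and the acceptance script is generated
synthetically and needs no downloads.
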