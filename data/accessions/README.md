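# Cached accession sequences

Place GenBank nucleotide sequences here as plain FASTA named
`<accession>.fasta` (e.g. `FJ602504.fasta`) to enable the copepod COI
analyses offline.  The four accessions used by the bundled case-study tests
and by `scripts/acceptance.py` targets `t3`/`t4` are:

- `FJ602504` — *Calanus hyperboreus* COI (marine calanoid)
- `EU770508` — *Mastigodiaptomus montezumae* COI (freshwater calanoid)
- `EU599544` — *Oithona similis* COI (marine cyclopoid)
- `EU770551` — *Thermocyclops inversus* COI (freshwater cyclopoid)

With network access you can populate the cache via the CLI:

    dirsel analyze --mode cds-pair --input FJ602504 --input EU770508 \
        --genetic-code 5 --cache-dir data/accessions --allow-network

or with any other tool (e.g. NCBI `efetch`).  Files here are loaded without
any network use.
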