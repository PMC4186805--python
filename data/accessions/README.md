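# GenBank accessions

Place the five study records here as GenBank flat files to enable the
accession-based acceptance tests and targets:

    JX844626.gb  GQ337955.gb  JX844627.gb  JX844628.gb  EU725832.gb

For example:

    for acc in JX844626 GQ337955 JX844627 JX844628 EU725832; do
      curl -o $acc.gb "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=$acc&rettype=gb&retmode=text"
    done

The build and grading environments have no network access, so these files
are absent and the corresponding tests report the missing data.
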