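# mitocomp

Comparative analysis of annotated mitochondrial genomes: nucleotide
composition and strand skews, codon usage and amino-acid frequencies,
substitution-rate estimation (p-distance, Kimura two-parameter, Ti/Tv,
Dayhoff-PAM amino-acid distance, Nei-Gojobori Ka/Ks), structure discovery
in the AT-rich control region (tandem repeats, cross-taxon conserved
segments, poly(N) runs, simplified stem-loop detection), GC-content versus
rate regression, and a synthetic mitogenome simulator with planted ground
truth that makes every stage testable without downloads.

## Layout

| module                 | contents                                            |
|------------------------|-----------------------------------------------------|
| `mitocomp.io`          | GenBank / FASTA+table reading and writing, gene-name canonicalization, circular coordinates, overlaps, start/stop codons |
| `mitocomp.composition` | base composition, AT/GC skews, codon-position composition, codon usage, amino-acid frequencies |
| `mitocomp.align`       | Gotoh affine global aligner, protein-guided codon alignment, star progressive alignment |
| `mitocomp.distances`   | p, K2p (total and per codon position), Ti/Tv, PAM distance, Nei-Gojobori Ka/Ks, group averages, saturation scan |
| `mitocomp.atrich`      | tandem-repeat period scan, conserved-segment anchoring, poly(N) runs, hairpin finder |
| `mitocomp.rates`       | per-gene rate rows, GC-vs-rate OLS regression, rate ranking, relative rates |
| `mitocomp.simulate`    | annotated-genome simulator under per-partition K2p processes with planted AT-rich structure |
| `mitocomp.cli`         | `mitocomp` command-line interface                   |

Coordinates are 1-based inclusive throughout; a feature whose start exceeds
its end wraps the origin of a circular genome.  The majority coding strand
is called `J` (plus strand of the stored sequence), the minority strand `N`.
Translation uses the invertebrate mitochondrial code (NCBI table 5).

## CLI

```sh
mitocomp simulate --seed 42 --n-taxa 5 -o sim/         # synthetic data
mitocomp compose   -g sim/taxon1.gb -g sim/taxon2.gb ... -o composition/
mitocomp align     -g sim/*.gb --gene cox1 -o cox1.fasta
mitocomp distances -g sim/*.gb --genes all -o substitution_rates.tsv
mitocomp distances -g sim/*.gb --pair taxon1,taxon2 \
                   --regions atrich,cox1,atp8 -o region_distances.tsv
mitocomp atrich    -g sim/*.gb -o atrich_report/
mitocomp rates     -g sim/*.gb -o rates.tsv
mitocomp run-all   -g sim/*.gb -o report/              # everything
```

All tables are tab-separated UTF-8 with `.` decimals; reruns are
byte-identical.  Logs go to stderr.

## Tests

```sh
python -m pytest -q tests/
```

The suite contains unit tests per module, hypothesis property tests
(skew antisymmetry, rotation invariance, brute-force alignment and hairpin
oracles), and `tests/test_acceptance.py`.  The acceptance tests that
require the five deposited GenBank records look for them under
`data/accessions/<ACC>.gb` and fail with an explanatory message when the
records are absent (no network in the build environment); everything else
runs offline.

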