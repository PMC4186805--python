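import math
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from mitocomp import composition as comp
from mitocomp.io import AnnotatedGenome, GeneFeature, reverse_complement

DNA = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestSkew:
    def test_symmetric_zero(self):
        row = comp.base_composition("AATT")
        assert row.at_skew == 0
        assert row.pct_at == 100

    def test_printed_counts_at_skew(self):
        # A=429, T=281 -> 0.21 at 2 dp
        assert round(comp.skew(429, 281), 2) == 0.21

    def test_printed_counts_gc_skew(self):
        # G=17, C=121 -> -0.75 at 2 dp
        assert round(comp.skew(17, 121), 2) == -0.75

    def test_undefined_skew(self):
        row = comp.base_composition("GGCC")
        assert row.at_skew is None
        assert row.gc_skew is not None

    @given(DNA)
    def test_revcomp_antisymmetry(self, s):
        a = comp.base_composition(s)
        b = comp.base_composition(reverse_complement(s))
        for x, y in ((a.at_skew, b.at_skew), (a.gc_skew, b.gc_skew)):
            if x is None:
                assert y is None
            else:
                assert math.isclose(x, -y, abs_tol=1e-12)

    @given(DNA, st.integers(0, 199))
    def test_rotation_and_case_invariance(self, s, k):
        k %= len(s)
        rot = s[k:] + s[:k]
        a = comp.base_composition(s)
        b = comp.base_composition(rot.lower())
        assert math.isclose(a.pct_at, b.pct_at)
        assert math.isclose(a.pct_a, b.pct_a)


class TestBaseComposition:
    def test_percentages_sum(self):
        row = comp.base_composition("ACGTACGTAA")
        assert math.isclose(row.pct_t + row.pct_c + row.pct_a + row.pct_g,
                            100.0, abs_tol=0.05)

    def test_n_excluded(self):
        row = comp.base_composition("AANN")
        assert row.pct_a == 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            comp.base_composition("NNN")


class TestCodonPositionComposition:
    def test_single_codon(self):
        g = AnnotatedGenome("x", "ATGAAATAA" + "AAA", features=[
            GeneFeature("cox1", "PCG", 1, 9, "J")])
        rows = comp.codon_position_composition([g], "J")
        # stop excluded: codons ATG, AAA
        assert rows[0].pct_a == 100.0
        assert rows[1].pct_t == 50.0
        assert rows[2].pct_g == 50.0

    def test_no_pcgs_on_strand_errors(self):
        g = AnnotatedGenome("x", "ATGAAATAA", features=[
            GeneFeature("cox1", "PCG", 1, 9, "J")])
        with pytest.raises(ValueError):
            comp.codon_position_composition([g], "N")

    def test_recovers_planted_frequencies(self):
        from itertools import product

        from mitocomp.simulate import SimulationConfig, simulate_genomes
        cfg = SimulationConfig(n_taxa=2, seed=3, scale=0.5,
                               branch_pos1=0.0, branch_pos2=0.0,
                               branch_pos3=0.0)
        gs, truth = simulate_genomes(cfg)
        rows = comp.codon_position_composition(gs, "J")
        # the generator samples codons from the planted frequencies but
        # rejects stop codons: condition the expectation on sense codons
        bases = "TCAG"
        weight = {}
        for codon in product(bases, repeat=3):
            codon = "".join(codon)
            if codon in ("TAA", "TAG"):
                continue
            w = 1.0
            for p in range(3):
                w *= truth.pos_freqs[p][bases.index(codon[p])]
            weight[codon] = w
        z = sum(weight.values())
        for i, row in enumerate(rows):
            got = {"T": row.pct_t, "C": row.pct_c,
                   "A": row.pct_a, "G": row.pct_g}
            for b in bases:
                want = 100.0 * sum(w for c, w in weight.items()
                                   if c[i] == b) / z
                # ~2 SE at ~1k independent codons, plus the forced ATG
                # start and junction codons not in the sampling model
                assert abs(want - got[b]) < 4.0


class TestAminoAcids:
    def test_pure_met(self):
        g = AnnotatedGenome("x", "ATGATGATG", features=[
            GeneFeature("cox1", "PCG", 1, 9, "J")])
        table = comp.amino_acid_frequencies([g])
        assert table.aa_pct == {"M": 100.0}

    def test_uniform_codon_soup_matches_degeneracy(self):
        # every sense codon once -> aa percentages proportional to the
        # number of codons per amino acid in translation table 5
        codons = sorted(comp.GENETIC_CODE)
        assert len(codons) == 62
        seq = "ATG" + "".join(c for c in codons if c != "ATG") + "TAA"
        # ensure no internal stop and frame correctness by direct counting
        expected = Counter(comp.GENETIC_CODE[c] for c in codons)
        g = AnnotatedGenome("x", seq, features=[
            GeneFeature("cox1", "PCG", 1, len(seq), "J")])
        table = comp.amino_acid_frequencies([g])
        for aa, n in expected.items():
            assert math.isclose(table.aa_pct[aa], 100.0 * n / 62,
                                abs_tol=1e-9)

    def test_top_share(self):
        g = AnnotatedGenome("x", "ATGATGTTTTAA", features=[
            GeneFeature("cox1", "PCG", 1, 12, "J")])
        table = comp.amino_acid_frequencies([g])
        top, share = table.top_share(1)
        assert top == ["M"]
        assert math.isclose(share, 200.0 / 3, abs_tol=1e-9)


class TestFourfold:
    def test_families_enumerated_from_code(self):
        # independent enumeration over translation table 5
        expected = set()
        for b1 in "ACGT":
            for b2 in "ACGT":
                aas = {comp.GENETIC_CODE.get(b1 + b2 + b3) for b3 in "ACGT"}
                if None not in aas and len(aas) == 1:
                    expected.add(b1 + b2)
        assert set(comp.FOURFOLD_FAMILIES) == expected
        assert "AG" in expected   # AGN is all-Ser under table 5
        assert "TT" not in expected  # Phe/Leu split

    def test_single_family_proportions(self):
        g = AnnotatedGenome("x", "ATG" + "GGA" * 4 + "TAA", features=[
            GeneFeature("cox1", "PCG", 1, 18, "J")])
        df = comp.fourfold_family_usage([g])
        row = df[df["family"] == "GGN"].iloc[0]
        assert row["p_NNA"] == 1.0
        assert row["n"] == 4

    def test_planted_third_position_bias(self, sim5_genomes):
        # simulator's default position-3 frequencies have A >> G
        df = comp.fourfold_family_usage(sim5_genomes)
        pooled = df[df["family"] == "all"].iloc[0]
        assert pooled["p_NNA"] > pooled["p_NNG"]
        ranks = sorted("ATCG", key=lambda b: -pooled[f"p_NN{b}"])
        assert ranks[0] == "A"


class TestSummaries:
    def test_genome_table_average_row(self, sim5_genomes):
        df = comp.genome_composition_table(sim5_genomes)
        assert df.iloc[-1]["id"] == "Average"
        sizes = df["size_bp"].iloc[:-1]
        assert df.iloc[-1]["size_bp"] == int(round(sizes.mean()))

    def test_planted_composition_recovered_at_15kb(self):
        from mitocomp.simulate import SimulationConfig, simulate_genomes
        cfg = SimulationConfig(n_taxa=2, seed=5, scale=1.0,
                               branch_pos1=0.0, branch_pos2=0.0,
                               branch_pos3=0.0, branch_trna=0.0,
                               branch_rrna=0.0, branch_atrich=0.0,
                               branch_spacer=0.0)
        gs, truth = simulate_genomes(cfg)
        df = comp.genome_composition_table(gs)
        # planted whole-genome AT% is a length-weighted blend of the
        # partition frequencies; compare genome against genome instead
        assert abs(df.iloc[0]["AT%"] - df.iloc[1]["AT%"]) < 1e-9
        row = comp.base_composition(gs[0].sequence)
        # coding-strand mix of planted partition AT% stays within 0.5 pp
        # of the realized value (multinomial error at 15 kb)
        expected = _expected_genome_at(gs[0], truth)
        assert abs(row.pct_at - expected) < 0.5

    def test_partition_table_shape(self, sim5_genomes):
        df = comp.partition_composition_table(sim5_genomes)
        labels = set(df["label"])
        assert {"PCG_pos1_J", "PCG_pos3_N", "tRNA_J", "rRNA_N",
                "AT_rich_J", "genome_J"} <= labels
        for _, r in df.iterrows():
            assert abs(r["T%"] + r["C%"] + r["A%"] + r["G%"] - 100.0) <= 0.25


def _expected_genome_at(genome, truth):
    """Length-weighted planted AT% over the genome's partitions."""
    n = len(genome.sequence)
    at_frac = 0.0
    covered = [None] * n
    for name, (s, e, strand, kind) in truth.gene_coords.items():
        for p in range(s - 1, e):
            if covered[p] is None:
                covered[p] = (kind, (p - (s - 1)) if strand == "J"
                              else (e - 1 - p), strand)
    pos_at = [f[0] + f[2] for f in truth.pos_freqs]  # T + A per position
    rna_at = truth.rna_freqs[0] + truth.rna_freqs[2]
    atrich_at = truth.atrich_freqs[0] + truth.atrich_freqs[2]
    total = 0.0
    for c in covered:
        if c is None:
            total += atrich_at  # spacers use AT-rich frequencies
        elif c[0] == "PCG":
            total += pos_at[c[1] % 3]
        elif c[0] in ("tRNA", "rRNA"):
            total += rna_at
        else:
            total += atrich_at
    return 100.0 * total / n
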