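import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from mitocomp import distances as dist
from mitocomp import _dayhoff
from mitocomp.align import CodonAlignment, NucAlignment, align_codon
from mitocomp.composition import GENETIC_CODE, STOP_CODONS
from mitocomp.distances import (KaKsResult, PairCounts, SaturationError,
                                count_differences, group_average, k2p,
                                k2p_by_position, k2p_pair, ka_ks, p_distance,
                                pam_distance, pam_expected_identity,
                                saturation_scan)


def nuc_aln(a, b):
    return NucAlignment("r", ["a", "b"], {"a": a, "b": b})


class TestCountDifferences:
    def test_identical(self):
        c = count_differences(nuc_aln("ACGT", "ACGT"), ("a", "b"))
        assert (c.compared_sites, c.differences) == (4, 0)

    def test_gap_excluded(self):
        c = count_differences(nuc_aln("A-GT", "AAGT"), ("a", "b"))
        assert c.compared_sites == 3

    def test_n_excluded(self):
        c = count_differences(nuc_aln("ANGT", "AAGT"), ("a", "b"))
        assert c.compared_sites == 3

    def test_transitions(self):
        c = count_differences(nuc_aln("AG", "GA"), ("a", "b"))
        assert (c.transitions, c.transversions) == (2, 0)

    def test_transversions(self):
        c = count_differences(nuc_aln("AC", "CA"), ("a", "b"))
        assert (c.transitions, c.transversions) == (0, 2)

    def test_all_gaps_errors(self):
        with pytest.raises(SaturationError):
            count_differences(nuc_aln("--", "AA"), ("a", "b"))

    def test_ti_tv_ratio(self):
        c = PairCounts(100, 10, 5)
        assert c.ti_tv == 2.0
        assert PairCounts(10, 3, 0).ti_tv is None


class TestK2p:
    def test_zero(self):
        assert k2p(PairCounts(100, 0, 0)) == 0.0

    def test_closed_form_value(self):
        # K = -1/2 ln((1 - 2*0.1 - 0.05) * sqrt(1 - 2*0.05)) = 0.1702 (4 dp)
        val = k2p(PairCounts(100, 10, 5))
        assert round(val, 4) == 0.1702
        assert val == pytest.approx(
            -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(0.9)))

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            k2p(PairCounts(100, 50, 10))

    def test_k2p_at_least_p(self):
        for ti, tv in [(5, 5), (20, 10), (1, 0), (0, 30)]:
            c = PairCounts(100, ti, tv)
            assert k2p(c) >= p_distance(c)

    def test_equals_jukes_cantor_when_uniform(self):
        # P = Q/2 (all substitution types equally likely)
        for d in (6, 12, 30):
            c = PairCounts(300, d, 2 * d)
            p = p_distance(c)
            jc = -0.75 * math.log(1 - 4 * p / 3)
            assert k2p(c) == pytest.approx(jc, rel=1e-12)

    @given(st.integers(1, 8))
    def test_small_p_first_order(self, ti):
        # balanced substitution types (P = Q/2, uniform) keep the
        # second-order term at (2/3) p^2 < p^2
        c = PairCounts(1000, ti, 2 * ti)
        p = p_distance(c)
        assert abs(k2p(c) - p) < p ** 2

    def test_k2p_pair_helper(self):
        assert k2p_pair("ACGT", "ACGT") == 0.0


class TestK2pRecovery:
    @pytest.mark.parametrize("true_k", [0.05, 0.15, 0.3])
    def test_estimator_unbiased(self, true_k, rng):
        from mitocomp.simulate import evolve_sequence
        n, reps = 10_000, 20
        est = []
        for _ in range(reps):
            anc = "".join(rng.choice(list("ACGT"), size=n))
            a = evolve_sequence(anc, true_k / 2, 2.0, rng)
            b = evolve_sequence(anc, true_k / 2, 2.0, rng)
            est.append(k2p_pair(a, b))
        bias = abs(np.mean(est) - true_k) / true_k
        assert bias < 0.02

    def test_by_position_planted(self, rng):
        from mitocomp.simulate import evolve_sequence
        d = np.tile([0.05, 0.02, 0.3], 3400)
        anc = "".join(rng.choice(list("ACGT"), size=len(d)))
        a = evolve_sequence(anc, d / 2, 2.0, rng)
        b = evolve_sequence(anc, d / 2, 2.0, rng)
        aln = CodonAlignment("g", ["a", "b"], {"a": a, "b": b})
        got = k2p_by_position(aln, ("a", "b"))
        for est, want in zip(got, (0.05, 0.02, 0.3)):
            se = math.sqrt(want / 3400) * 2.5  # generous 2+ SE
            assert abs(est - want) < max(se, 0.01)

    def test_identical_rows_zero(self):
        aln = CodonAlignment("g", ["a", "b"],
                             {"a": "ATGAAA", "b": "ATGAAA"})
        assert k2p_by_position(aln, ("a", "b")) == (0.0, 0.0, 0.0)


class TestPamDistance:
    def test_identical_zero(self):
        assert pam_distance(("MKLV", "MKLV")) == 0.0

    def test_pam100_inversion_oracle(self):
        # independent route: build Q from the raw data, propagate with
        # scipy expm + matrix_power, then invert through pam_distance
        aas = _dayhoff.AMINO_ACIDS
        S = np.zeros((20, 20))
        for i, row in enumerate(_dayhoff.EXCHANGEABILITIES, start=1):
            for j, v in enumerate(row):
                S[i, j] = S[j, i] = v
        pi = np.array(_dayhoff.FREQUENCIES)
        pi /= pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q /= -np.sum(pi * np.diag(Q)) / 0.01
        P1 = expm(Q)
        P100 = np.linalg.matrix_power(P1, 100)
        expected_identity = float(np.sum(pi * np.diag(P100)))
        # synthesize an alignment with exactly that identity fraction
        assert pam_expected_identity(100.0) == pytest.approx(
            expected_identity, rel=1e-6)
        n = 100_000
        same = int(round(expected_identity * n))
        a = "A" * n
        b = "A" * same + "C" * (n - same)
        t = pam_distance((a, b))
        assert t == pytest.approx(1.00, abs=0.01)

    def test_monotone_in_identity(self):
        prev = -1.0
        for same in (95, 80, 60, 40):
            a = "A" * 100
            b = "A" * same + "C" * (100 - same)
            d = pam_distance((a, b))
            assert d > prev
            prev = d

    def test_gap_deleted_pairwise(self):
        assert pam_distance(("MK-V", "MKLV")) == 0.0

    def test_saturation(self):
        with pytest.raises(SaturationError):
            pam_distance(("A" * 50, "C" * 50))


def oracle_ng86_sites(codon):
    """Independent re-derivation of NG86 site counts for one codon."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        changes = [codon[:pos] + b + codon[pos + 1:]
                   for b in "ACGT" if b != codon[pos]]
        changes = [c for c in changes if c not in STOP_CODONS]
        if changes:
            s += sum(GENETIC_CODE[c] == aa for c in changes) / len(changes)
    return s, 3.0 - s


def oracle_ng86_path(ca, cb):
    """Average syn/nonsyn steps over mutational orderings (stop paths
    dropped; every step scored if all paths are blocked)."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    results, blocked_results = [], []
    for order in itertools.permutations(diffs):
        cur, sd, nd, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                blocked = True
                nd += 1
            elif GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_results if blocked else results).append((sd, nd))
    use = results or blocked_results or [(0, 0)]
    if not results and blocked_results:
        use = blocked_results + results
    return (sum(r[0] for r in use) / len(use),
            sum(r[1] for r in use) / len(use))


def codon_aln(a_codons, b_codons):
    return CodonAlignment("g", ["a", "b"],
                          {"a": "".join(a_codons), "b": "".join(b_codons)})


class TestKaKs:
    def test_identical(self):
        res = ka_ks(codon_aln(["ATG", "AAA"], ["ATG", "AAA"]), ("a", "b"))
        assert (res.ka, res.ks) == (0.0, 0.0)
        assert res.ratio is None

    def test_synonymous_only(self):
        # a second invariant codon keeps pS below the 0.75 saturation
        # threshold while the GTT -> GTC change stays purely synonymous
        res = ka_ks(codon_aln(["GTT", "GTT"], ["GTC", "GTT"]), ("a", "b"))
        assert res.ka == 0.0
        assert res.ks > 0.0
        assert res.syn_diffs == 1.0

    def test_single_codon_gtt_gtc_saturates(self):
        # with one codon the synonymous proportion is 1.0: the estimator
        # must report saturation rather than a distance
        with pytest.raises(SaturationError):
            ka_ks(codon_aln(["GTT"], ["GTC"]), ("a", "b"))

    def test_nonsynonymous_only(self):
        res = ka_ks(codon_aln(["AAA"], ["GAA"]), ("a", "b"))
        assert res.ks == 0.0
        assert res.ka > 0.0

    def test_sites_sum_to_three_per_codon(self):
        codons = ["ATG", "TTT", "GGG", "TGA", "CTT"]
        s, n = dist.count_syn_nonsyn_sites(codons)
        assert s + n == pytest.approx(3 * len(codons))

    @pytest.mark.parametrize("codon", ["ATG", "TTT", "TGG", "CTA", "AGA",
                                       "TAT", "TGT"])
    def test_site_counts_match_oracle(self, codon):
        assert dist.count_syn_nonsyn_sites([codon]) == \
            pytest.approx(oracle_ng86_sites(codon))

    def test_mixed_codon_path_oracle(self):
        # TTT -> GTA differs at positions 1 and 3: two orderings
        sd, nd = dist.count_syn_nonsyn_diffs(["TTT"], ["GTA"])
        osd, ond = oracle_ng86_path("TTT", "GTA")
        assert (sd, nd) == pytest.approx((osd, ond))

    @settings(max_examples=120, deadline=None)
    @given(st.sampled_from(sorted(GENETIC_CODE)),
           st.sampled_from(sorted(GENETIC_CODE)))
    def test_path_counts_match_oracle(self, ca, cb):
        sd, nd = dist.count_syn_nonsyn_diffs([ca], [cb])
        osd, ond = oracle_ng86_path(ca, cb)
        assert (sd, nd) == pytest.approx((osd, ond))
        assert sd + nd == pytest.approx(sum(x != y for x, y in zip(ca, cb)))

    def test_saturation(self):
        a = ["TTT"] * 30
        b = ["AGG"] * 30
        with pytest.raises(SaturationError):
            ka_ks(codon_aln(a, b), ("a", "b"))

    def test_purifying_selection_below_one(self):
        from mitocomp.io import extract_gene
        from mitocomp.simulate import SimulationConfig, simulate_genomes
        cfg = SimulationConfig(n_taxa=2, seed=7, scale=0.4,
                               nonsyn_scaling=0.1)
        gs, _ = simulate_genomes(cfg)
        cds = {g.id: extract_gene(g, "cox1") for g in gs}
        aln = align_codon(cds, gene="cox1")
        res = ka_ks(aln, tuple(cds))
        assert res.ratio is not None and res.ratio < 1.0


class TestGroupAverage:
    def test_two_taxa_is_identity(self):
        r = dist.DistanceResult("g", ("a", "b"), p=0.1, k2p=0.11,
                                k2p_pos=(0.1, 0.05, 0.2))
        avg = group_average([r])
        assert avg.k2p == 0.11
        assert avg.k2p_pos == (0.1, 0.05, 0.2)

    def test_star_tree_recovery(self, rng):
        from mitocomp.simulate import evolve_sequence
        n, r_true = 8000, 0.06
        anc = "".join(rng.choice(list("ACGT"), size=n))
        taxa = {f"t{i}": evolve_sequence(anc, r_true, 2.0, rng)
                for i in range(5)}
        results = []
        for a, b in itertools.combinations(taxa, 2):
            results.append(dist.DistanceResult(
                "g", (a, b), k2p=k2p_pair(taxa[a], taxa[b])))
        avg = group_average(results)
        se = math.sqrt(2 * r_true / n)
        assert abs(avg.k2p - 2 * r_true) < 4 * se

    def test_saturated_pair_flagged(self):
        ok = dist.DistanceResult("g", ("a", "b"), k2p=0.1)
        bad = dist.DistanceResult("g", ("a", "c"), k2p=None)
        avg = group_average([ok, bad])
        assert avg.k2p == 0.1
        assert ("a", "c") in avg.excluded_pairs

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            group_average([])


class TestSaturationScan:
    def test_near_identical_k2p_close_to_p(self):
        a = "ACGT" * 100
        b = a[:-1] + "C"
        df, _ = saturation_scan([nuc_aln(a, b)])
        row = df.iloc[0]
        assert row["k2p"] == pytest.approx(row["p"], rel=0.01)

    def test_low_divergence_high_correlation(self, rng):
        from mitocomp.simulate import evolve_sequence
        alns = []
        for i in range(8):
            anc = "".join(rng.choice(list("ACGT"), size=2000))
            a = evolve_sequence(anc, rng.uniform(0.005, 0.05), 2.0, rng)
            b = evolve_sequence(anc, rng.uniform(0.005, 0.05), 2.0, rng)
            alns.append(NucAlignment(f"g{i}", ["a", "b"], {"a": a, "b": b}))
        df, corr = saturation_scan(alns)
        assert (df["p"] < 0.1).all()
        assert corr > 0.99

    def test_saturated_inflation(self):
        # closed form at p = 0.3: with a transition bias (P = 2Q) the
        # correction inflates K2p/p past 1.3; with P = Q it reaches ~1.29
        c = PairCounts(1000, 200, 100)
        assert k2p(c) / p_distance(c) > 1.3
        c_eq = PairCounts(1000, 150, 150)
        assert k2p(c_eq) / p_distance(c_eq) > 1.29


def test_concat_alignments():
    a1 = nuc_aln("ACGT", "ACGA")
    a2 = nuc_aln("TTTT", "TTTT")
    cat = dist.concat_alignments([a1, a2])
    assert cat.rows["a"] == "ACGTTTTT"
    assert cat.length == 8
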