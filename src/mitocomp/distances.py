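"""Substitution-rate statistics: p-distance, K2p (total and per codon
position), Ti/Tv, Dayhoff-PAM amino-acid distance, Nei-Gojobori Ka/Ks,
group averages and saturation diagnostics.

Gap or N sites are removed pairwise (pairwise deletion), matching the
defaults of the classic distance software this mirrors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _dayhoff
from .align import CodonAlignment, NucAlignment
from .composition import GENETIC_CODE, STOP_CODONS

__all__ = [
    "SaturationError",
    "PairCounts",
    "DistanceResult",
    "KaKsResult",
    "count_differences",
    "p_distance",
    "k2p",
    "k2p_pair",
    "k2p_by_position",
    "pam_distance",
    "pam_expected_identity",
    "ka_ks",
    "count_syn_nonsyn_sites",
    "count_syn_nonsyn_diffs",
    "group_average",
    "saturation_scan",
    "concat_alignments",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """Distance undefined: substitutions saturated the correction formula."""


@dataclass(frozen=True)
class PairCounts:
    """Site and difference counts for one pair of aligned rows."""

    compared_sites: int
    transitions: int
    transversions: int

    @property
    def differences(self) -> int:
        return self.transitions + self.transversions

    @property
    def P(self) -> float:
        return self.transitions / self.compared_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites

    @property
    def ti_tv(self) -> Optional[float]:
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


@dataclass
class DistanceResult:
    """One gene/region distance record for a pair or a group average."""

    label: str
    taxa: tuple[str, ...]
    p: Optional[float] = None
    k2p: Optional[float] = None
    k2p_pos: tuple[Optional[float], ...] = (None, None, None)
    ti_tv: Optional[float] = None
    ka: Optional[float] = None
    ks: Optional[float] = None
    ka_ks: Optional[float] = None
    pam: Optional[float] = None
    excluded_pairs: tuple[tuple[str, str], ...] = ()


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or \
           (a in _PYRIMIDINES and b in _PYRIMIDINES)


def count_differences(aln: NucAlignment | CodonAlignment,
                      pair: tuple[str, str],
                      mask: Optional[np.ndarray] = None) -> PairCounts:
    """Transition/transversion counts with pairwise deletion of gaps and N.

    ``mask`` optionally restricts counting to columns where it is True.
    """
    ra, rb = aln.pair(*pair)
    sites = ti = tv = 0
    for idx, (x, y) in enumerate(zip(ra, rb)):
        if mask is not None and not mask[idx]:
            continue
        if x not in _VALID or y not in _VALID:
            continue
        sites += 1
        if x != y:
            if _is_transition(x, y):
                ti += 1
            else:
                tv += 1
    if sites == 0:
        raise SaturationError(f"{aln.__dict__.get('region', '')}: "
                              f"no comparable sites for pair {pair}")
    return PairCounts(sites, ti, tv)


def p_distance(counts: PairCounts) -> float:
    return counts.differences / counts.compared_sites


def k2p(counts: PairCounts) -> float:
    """Kimura two-parameter distance K = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2p undefined at P={P:.3f}, Q={Q:.3f} (saturated)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_pair(row_a: str, row_b: str) -> float:
    """Convenience: K2p straight from two aligned rows."""
    aln = NucAlignment("", ["a", "b"], {"a": row_a, "b": row_b})
    return k2p(count_differences(aln, ("a", "b")))


def k2p_by_position(aln: CodonAlignment, pair: tuple[str, str],
                    ) -> tuple[float, float, float]:
    """K2p per codon position (independent counts per site class)."""
    masks = aln.position_masks
    out = []
    for pos in (1, 2, 3):
        out.append(k2p(count_differences(aln, pair, mask=masks == pos)))
    return tuple(out)


# ---------------------------------------------------------------------------
# Dayhoff PAM amino-acid distance

_PAM_MAX = 2000.0


def _dayhoff_eig():
    """Eigendecomposition of the Dayhoff rate matrix, scaled so one PAM unit
    equals an expected 1% of sites substituted."""
    aas = _dayhoff.AMINO_ACIDS
    k = len(aas)
    S = np.zeros((k, k))
    for i, row in enumerate(_dayhoff.EXCHANGEABILITIES, start=1):
        for j, v in enumerate(row):
            S[i, j] = S[j, i] = v
    pi = np.asarray(_dayhoff.FREQUENCIES)
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    Q /= rate / 0.01  # 1% expected change per PAM unit
    # reversible: symmetrize with sqrt(pi) for a stable eigendecomposition
    d = np.sqrt(pi)
    B = (Q * d[:, None]) / d[None, :]
    B = (B + B.T) / 2.0
    w, U = np.linalg.eigh(B)
    return pi, d, w, U


_EIG = None


def pam_expected_identity(t: float) -> float:
    """Expected fraction of identical sites after t PAM units of divergence."""
    global _EIG
    if _EIG is None:
        _EIG = _dayhoff_eig()
    pi, d, w, U = _EIG
    diag_p = ((U * np.exp(w * t)) @ U.T).diagonal()  # of D^1/2 P D^-1/2
    return float(np.sum(pi * diag_p))


def pam_distance(protein_aln: Sequence[str] | NucAlignment,
                 pair: Optional[tuple[str, str]] = None) -> float:
    """Amino-acid substitutions/site: t/100 for the PAM-t whose expected
    identity matches the observed identity (monotone bisection).

    Accepts either two aligned protein strings or an alignment plus a taxon
    pair.  Gap/X columns are deleted pairwise.
    """
    if pair is not None:
        ra, rb = protein_aln.pair(*pair)  # type: ignore[union-attr]
    else:
        ra, rb = protein_aln  # type: ignore[misc]
    aas = set(_dayhoff.AMINO_ACIDS)
    sites = same = 0
    for x, y in zip(ra, rb):
        if x not in aas or y not in aas:
            continue
        sites += 1
        if x == y:
            same += 1
    if sites == 0:
        raise SaturationError("no comparable amino-acid sites")
    obs = same / sites
    if obs >= 1.0:
        return 0.0
    if obs <= pam_expected_identity(_PAM_MAX):
        raise SaturationError(
            f"identity {obs:.3f} below PAM-{_PAM_MAX:.0f} expectation"
        )
    lo, hi = 0.0, _PAM_MAX
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if pam_expected_identity(mid) > obs:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0 / 100.0


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks

@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    At each position the three alternative bases are classified; changes that
    create a stop codon are disregarded (dropped from the denominator).
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def count_syn_nonsyn_sites(codons: Iterable[str]) -> tuple[float, float]:
    s_tot = n_tot = 0.0
    for c in codons:
        s, n = _syn_fraction(c)
        s_tot += s
        n_tot += n
    return s_tot, n_tot


def _path_steps(ca: str, cb: str) -> tuple[float, float]:
    """Average (syn, nonsyn) differences between two codons over all
    mutational pathways, equally weighted; paths through stop codons are
    discarded (all paths kept, stop steps scored nonsynonymous, if every
    path is blocked)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = ca
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                blocked = blocked or nxt in STOP_CODONS
                nd += 1.0  # stop-touching steps count as nonsynonymous
            elif GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


def count_syn_nonsyn_diffs(codons_a: Sequence[str], codons_b: Sequence[str],
                           ) -> tuple[float, float]:
    sd_tot = nd_tot = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sd, nd = _path_steps(ca, cb)
        sd_tot += sd
        nd_tot += nd
    return sd_tot, nd_tot


def _jc(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise SaturationError(f"Jukes-Cantor undefined at p={p:.3f}")
    return -0.75 * math.log(arg)


def ka_ks(aln: CodonAlignment, pair: tuple[str, str]) -> KaKsResult:
    """Original Nei-Gojobori Ka/Ks with equal path weighting and
    Jukes-Cantor correction.  Codons with a gap or N in either row are
    deleted pairwise; the ratio is None when Ks = 0."""
    ca = aln.codons(pair[0])
    cb = aln.codons(pair[1])
    keep_a, keep_b = [], []
    for x, y in zip(ca, cb):
        if set(x) <= _VALID and set(y) <= _VALID and \
                x not in STOP_CODONS and y not in STOP_CODONS:
            keep_a.append(x)
            keep_b.append(y)
    if not keep_a:
        raise SaturationError(f"no comparable codons for pair {pair}")
    s_a, n_a = count_syn_nonsyn_sites(keep_a)
    s_b, n_b = count_syn_nonsyn_sites(keep_b)
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    sd, nd = count_syn_nonsyn_diffs(keep_a, keep_b)
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        raise SaturationError(f"pS={ps:.3f}, pN={pn:.3f}: saturated")
    ks = _jc(ps)
    ka = _jc(pn)
    ratio = (ka / ks) if ks > 0 else None
    return KaKsResult(ka, ks, ratio, S, N, sd, nd)


# ---------------------------------------------------------------------------
# group statistics

def group_average(results: Sequence[DistanceResult], label: str = "",
                  ) -> DistanceResult:
    """Arithmetic mean over all pairwise results; saturated (None) pairs are
    excluded and flagged."""
    if not results:
        raise ValueError("no pairwise results to average")
    taxa = tuple(sorted({t for r in results for t in r.taxa}))

    def mean_of(attr):
        vals = [getattr(r, attr) for r in results
                if getattr(r, attr) is not None]
        return (sum(vals) / len(vals)) if vals else None

    pos_means = []
    for i in range(3):
        vals = [r.k2p_pos[i] for r in results if r.k2p_pos[i] is not None]
        pos_means.append(sum(vals) / len(vals) if vals else None)
    excluded = tuple(r.taxa for r in results if r.k2p is None)
    return DistanceResult(
        label=label or (results[0].label + "_avg"),
        taxa=taxa,
        p=mean_of("p"), k2p=mean_of("k2p"), k2p_pos=tuple(pos_means),
        ti_tv=mean_of("ti_tv"), ka=mean_of("ka"), ks=mean_of("ks"),
        ka_ks=mean_of("ka_ks"), pam=mean_of("pam"),
        excluded_pairs=excluded,
    )


def saturation_scan(alns: Iterable[NucAlignment | CodonAlignment],
                    ) -> tuple[pd.DataFrame, float]:
    """(p, K2p) per pair per alignment plus their Pearson correlation."""
    rows = []
    for aln in alns:
        label = getattr(aln, "region", None) or getattr(aln, "gene", "")
        for a, b in itertools.combinations(aln.taxa, 2):
            counts = count_differences(aln, (a, b))
            p = p_distance(counts)
            try:
                k = k2p(counts)
            except SaturationError:
                k = None
            rows.append({"label": label, "taxon_a": a, "taxon_b": b,
                         "p": p, "k2p": k})
    df = pd.DataFrame(rows)
    ok = df.dropna()
    if len(ok) >= 2 and ok["p"].std() > 0 and ok["k2p"].std() > 0:
        r = float(np.corrcoef(ok["p"], ok["k2p"])[0, 1])
    else:
        r = float("nan")
    return df, r


def concat_alignments(alns: Sequence[NucAlignment], region: str = "concat",
                      ) -> NucAlignment:
    """Concatenate alignments sharing the same taxon set (sites pooled)."""
    taxa = list(alns[0].taxa)
    rows = {t: "".join(a.rows[t] for a in alns) for t in taxa}
    return NucAlignment(region, taxa, rows)
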