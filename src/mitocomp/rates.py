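"""Cross-gene synthesis: GC-content vs substitution-rate regression,
rate rankings, and relative-rate ratios."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .align import align_codon
from .composition import base_composition
from .distances import (DistanceResult, SaturationError, count_differences,
                        group_average, k2p, k2p_by_position, ka_ks,
                        p_distance, pam_distance)
from .io import AnnotatedGenome, extract_gene

__all__ = [
    "GeneRateRow",
    "build_gene_rate_rows",
    "pairwise_gene_results",
    "gc_rate_regression",
    "relative_rate",
    "rate_ranking",
]


@dataclass
class GeneRateRow:
    """Per-gene group-average rates plus per-position GC content."""

    gene: str
    strand: str
    gc_pos: tuple[float, float, float]
    k2p_total: float
    k2p_pos: tuple[Optional[float], Optional[float], Optional[float]]
    ti_tv: Optional[float]
    pam: Optional[float]
    ka_ks: Optional[float]


def pairwise_gene_results(genomes: Sequence[AnnotatedGenome], gene: str,
                          ) -> list[DistanceResult]:
    """All pairwise DistanceResults for one PCG across genomes."""
    cds = {g.id: extract_gene(g, gene) for g in genomes}
    aln = align_codon(cds, gene=gene)
    out = []
    for a, b in itertools.combinations(aln.taxa, 2):
        counts = count_differences(aln, (a, b))
        res = DistanceResult(label=gene, taxa=(a, b), p=p_distance(counts),
                             ti_tv=counts.ti_tv)
        try:
            res.k2p = k2p(counts)
        except SaturationError:
            pass
        try:
            res.k2p_pos = k2p_by_position(aln, (a, b))
        except SaturationError:
            pass
        try:
            res.pam = pam_distance(
                (aln.protein_rows[a], aln.protein_rows[b]))
        except SaturationError:
            pass
        try:
            kk = ka_ks(aln, (a, b))
            res.ka, res.ks, res.ka_ks = kk.ka, kk.ks, kk.ratio
        except SaturationError:
            pass
        out.append(res)
    return out


def build_gene_rate_rows(genomes: Sequence[AnnotatedGenome],
                         genes: Optional[Iterable[str]] = None,
                         ) -> list[GeneRateRow]:
    """One row per PCG: group-average rates and pooled per-position GC%."""
    if genes is None:
        genes = [f.name for f in genomes[0].features_of_kind("PCG")]
    rows = []
    for gene in genes:
        strand = genomes[0].feature(gene).strand
        pos_seqs = ["", "", ""]
        for g in genomes:
            cds = extract_gene(g, gene)
            cds = cds[:len(cds) - len(cds) % 3]
            for i in range(3):
                pos_seqs[i] += cds[i::3]
        gc = tuple(100.0 - base_composition(s).pct_at for s in pos_seqs)
        avg = group_average(pairwise_gene_results(genomes, gene), label=gene)
        rows.append(GeneRateRow(
            gene=gene, strand=strand, gc_pos=gc,
            k2p_total=avg.k2p, k2p_pos=avg.k2p_pos, ti_tv=avg.ti_tv,
            pam=avg.pam, ka_ks=avg.ka_ks,
        ))
    return rows


def gc_rate_regression(rows: Sequence[GeneRateRow], position: int,
                       ) -> tuple[float, float, float]:
    """OLS of per-position group-average K2p on per-position GC content.

    Returns (slope, intercept, correlation).
    """
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    pts = [(r.gc_pos[position - 1], r.k2p_pos[position - 1])
           for r in rows if r.k2p_pos[position - 1] is not None]
    if len(pts) < 3:
        raise ValueError("need at least three genes for a regression")
    x = [p[0] for p in pts]
    y = [p[1] for p in pts]
    if max(x) == min(x):
        raise ValueError("degenerate GC values: zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def relative_rate(numerator: DistanceResult,
                  denominator: DistanceResult) -> float:
    """K2p ratio of two regions measured on the same taxon pair."""
    if set(numerator.taxa) != set(denominator.taxa):
        raise ValueError("results compare different taxon pairs")
    if not denominator.k2p:
        raise ValueError("denominator distance is zero or undefined")
    return numerator.k2p / denominator.k2p


def rate_ranking(rows: Sequence[GeneRateRow]) -> list[str]:
    """Genes by descending total K2p; ties broken alphabetically."""
    return [r.gene for r in sorted(rows, key=lambda r: (-r.k2p_total, r.gene))]
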