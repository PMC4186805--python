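"""Nucleotide composition, strand skews, codon usage and amino-acid frequencies.

Skews follow the usual definitions AT-skew = (A-T)/(A+T) and
GC-skew = (G-C)/(G+C); both are undefined (``None``) when the denominator
is zero.  ``N`` characters are excluded from every count.  Translation uses
the invertebrate mitochondrial genetic code (NCBI table 5) throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio.Data import CodonTable

from .io import AnnotatedGenome, extract_gene

__all__ = [
    "CompositionRow",
    "CodonUsageTable",
    "GENETIC_CODE",
    "STOP_CODONS",
    "FOURFOLD_FAMILIES",
    "skew",
    "base_composition",
    "pcg_codons",
    "codon_position_composition",
    "amino_acid_frequencies",
    "fourfold_family_usage",
    "genome_composition_table",
    "partition_composition_table",
]

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
GENETIC_CODE: dict[str, str] = dict(_TABLE5.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE5.stop_codons)  # {TAA, TAG}

#: fourfold-degenerate codon families (first two bases) under table 5
FOURFOLD_FAMILIES: tuple[str, ...] = tuple(sorted(
    prefix for prefix in {c[:2] for c in GENETIC_CODE}
    if len({GENETIC_CODE.get(prefix + b) for b in "ACGT"}) == 1
    and all(prefix + b in GENETIC_CODE for b in "ACGT")
))


@dataclass(frozen=True)
class CompositionRow:
    """Percent composition and skews of one sequence partition."""

    label: str
    pct_t: float
    pct_c: float
    pct_a: float
    pct_g: float
    pct_at: float
    at_skew: Optional[float]
    gc_skew: Optional[float]

    def as_dict(self) -> dict:
        return {
            "label": self.label, "T%": self.pct_t, "C%": self.pct_c,
            "A%": self.pct_a, "G%": self.pct_g, "AT%": self.pct_at,
            "AT_skew": self.at_skew, "GC_skew": self.gc_skew,
        }


def skew(x: float, y: float) -> Optional[float]:
    """(x - y) / (x + y), or None when x + y == 0."""
    total = x + y
    if total == 0:
        return None
    return (x - y) / total


def _counts(seq: str) -> Counter:
    c = Counter(seq.upper())
    c.pop("N", None)
    return c


def base_composition(seq: str, label: str = "") -> CompositionRow:
    """Composition row for one sequence (percentages on non-N length)."""
    c = _counts(seq)
    n = sum(c[b] for b in "ACGT")
    if n == 0:
        raise ValueError("empty or all-N sequence")
    pct = {b: 100.0 * c[b] / n for b in "TCAG"}
    return CompositionRow(
        label=label,
        pct_t=pct["T"], pct_c=pct["C"], pct_a=pct["A"], pct_g=pct["G"],
        pct_at=pct["A"] + pct["T"],
        at_skew=skew(c["A"], c["T"]),
        gc_skew=skew(c["G"], c["C"]),
    )


def pcg_codons(genome: AnnotatedGenome, strand: Optional[str] = None,
               genes: Optional[Iterable[str]] = None) -> list[str]:
    """Complete codons of the genome's PCGs in coding orientation.

    Trailing incomplete codons and the terminal stop codon are dropped.
    """
    out: list[str] = []
    for f in genome.features_of_kind("PCG"):
        if strand is not None and f.strand != strand:
            continue
        if genes is not None and f.name not in genes:
            continue
        cds = extract_gene(genome, f.name)
        cds = cds[:len(cds) - len(cds) % 3]
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        out.extend(cds[i:i + 3] for i in range(0, len(cds), 3))
    return out


def codon_position_composition(genomes: Iterable[AnnotatedGenome],
                               strand_group: Optional[str] = "J",
                               ) -> list[CompositionRow]:
    """Pooled per-codon-position composition of one strand group's PCGs.

    ``strand_group`` of ``None`` pools both strands.  Counts are pooled over
    nucleotides (length-weighted), not averaged per genome.
    """
    pos_seqs = ["", "", ""]
    for g in genomes:
        for codon in pcg_codons(g, strand=strand_group):
            for i in range(3):
                pos_seqs[i] += codon[i]
    if not pos_seqs[0]:
        raise ValueError(f"no PCG codons on strand {strand_group!r}")
    label = strand_group or "JN"
    return [base_composition(pos_seqs[i], label=f"PCG_pos{i + 1}_{label}")
            for i in range(3)]


@dataclass
class CodonUsageTable:
    """Pooled codon counts plus per-genome-averaged amino-acid percentages."""

    codon_counts: dict[str, int]
    aa_pct: dict[str, float]
    grouping: str = "all"
    warnings: tuple[str, ...] = ()

    @property
    def total_codons(self) -> int:
        return sum(self.codon_counts.values())

    def per_thousand(self) -> dict[str, float]:
        t = self.total_codons
        return {c: 1000.0 * k / t for c, k in self.codon_counts.items()}

    def top_share(self, k: int = 5) -> tuple[list[str], float]:
        """The k most frequent amino acids and their cumulative percentage."""
        ranked = sorted(self.aa_pct.items(), key=lambda kv: (-kv[1], kv[0]))
        top = ranked[:k]
        return [aa for aa, _ in top], sum(p for _, p in top)


def amino_acid_frequencies(genomes: Iterable[AnnotatedGenome]) -> CodonUsageTable:
    """Amino-acid percentages averaged over genomes (table-5 translation)."""
    genomes = list(genomes)
    pooled: Counter = Counter()
    per_genome_pct: list[dict[str, float]] = []
    warnings: list[str] = []
    for g in genomes:
        aa_counts: Counter = Counter()
        for codon in pcg_codons(g):
            if "N" in codon:
                continue
            if codon in STOP_CODONS:
                warnings.append(f"{g.id}: in-frame stop codon skipped")
                continue
            pooled[codon] += 1
            aa_counts[GENETIC_CODE[codon]] += 1
        total = sum(aa_counts.values())
        per_genome_pct.append({aa: 100.0 * k / total
                               for aa, k in aa_counts.items()})
    aas = sorted({aa for d in per_genome_pct for aa in d})
    avg = {aa: sum(d.get(aa, 0.0) for d in per_genome_pct) / len(per_genome_pct)
           for aa in aas}
    return CodonUsageTable(dict(pooled), avg, warnings=tuple(warnings))


def fourfold_family_usage(genomes: Iterable[AnnotatedGenome]) -> pd.DataFrame:
    """NNA/NNT/NNC/NNG proportions within each fourfold-degenerate family.

    Returns one row per family plus a pooled ``NN*`` row; proportions per
    family sum to 1.
    """
    counts = {fam: Counter() for fam in FOURFOLD_FAMILIES}
    for g in genomes:
        for codon in pcg_codons(g):
            if "N" in codon:
                continue
            if codon[:2] in counts:
                counts[codon[:2]][codon[2]] += 1
    rows = []
    pooled: Counter = Counter()
    for fam in FOURFOLD_FAMILIES:
        c = counts[fam]
        pooled.update(c)
        total = sum(c.values())
        row = {"family": fam + "N", "n": total}
        for b in "ATCG":
            row[f"p_NN{b}"] = (c[b] / total) if total else float("nan")
        rows.append(row)
    total = sum(pooled.values())
    row = {"family": "all", "n": total}
    for b in "ATCG":
        row[f"p_NN{b}"] = (pooled[b] / total) if total else float("nan")
    rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report-shaped summaries

def genome_composition_table(genomes: Iterable[AnnotatedGenome]) -> pd.DataFrame:
    """Whole-genome size, AT% and skews per genome, plus an Average row.

    Whole-genome values are computed on the stored (J) strand.
    """
    rows = []
    for g in genomes:
        c = base_composition(g.sequence, label=g.id)
        rows.append({
            "id": g.id, "taxon": g.taxon, "size_bp": len(g.sequence),
            "AT%": round(c.pct_at, 1),
            "AT_skew": round(c.at_skew, 3) if c.at_skew is not None else None,
            "GC_skew": round(c.gc_skew, 3) if c.gc_skew is not None else None,
        })
    df = pd.DataFrame(rows)
    avg = {
        "id": "Average", "taxon": "-",
        "size_bp": int(round(df["size_bp"].mean())),
        "AT%": round(df["AT%"].mean(), 1),
        "AT_skew": round(df["AT_skew"].mean(), 3),
        "GC_skew": round(df["GC_skew"].mean(), 3),
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def _pooled_row(label: str, seqs: list[str]) -> Optional[dict]:
    pooled = "".join(seqs)
    if not pooled.replace("N", ""):
        return None
    c = base_composition(pooled, label=label)
    d = c.as_dict()
    for k in ("T%", "C%", "A%", "G%", "AT%"):
        d[k] = round(d[k], 1)
    for k in ("AT_skew", "GC_skew"):
        if d[k] is not None:
            d[k] = round(d[k], 2)
    return d


def partition_composition_table(genomes: Iterable[AnnotatedGenome]) -> pd.DataFrame:
    """Composition and skews per partition: PCG codon positions by strand,
    tRNAs and rRNAs by strand, the AT-rich region and the total genome.

    Nucleotide counts are pooled over genomes (length-weighted).  RNA genes
    and the AT-rich region are measured in coding orientation; the total
    genome on the J strand as stored.
    """
    genomes = list(genomes)
    rows: list[dict] = []
    for strand in ("J", "N"):
        try:
            for row in codon_position_composition(genomes, strand):
                rows.append(_round_row(row))
        except ValueError:
            pass
    for kind, prefix in (("tRNA", "tRNA"), ("rRNA", "rRNA")):
        for strand in ("J", "N"):
            seqs = [extract_gene(g, f.name)
                    for g in genomes
                    for f in g.features_of_kind(kind) if f.strand == strand]
            row = _pooled_row(f"{prefix}_{strand}", seqs)
            if row:
                rows.append(row)
    at = [extract_gene(g, "AT_rich") for g in genomes if g.has_feature("AT_rich")]
    row = _pooled_row("AT_rich_J", at)
    if row:
        rows.append(row)
    rows.append(_pooled_row("genome_J", [g.sequence for g in genomes]))
    return pd.DataFrame(rows)


def _round_row(row: CompositionRow) -> dict:
    d = row.as_dict()
    for k in ("T%", "C%", "A%", "G%", "AT%"):
        d[k] = round(d[k], 1)
    for k in ("AT_skew", "GC_skew"):
        if d[k] is not None:
            d[k] = round(d[k], 2)
    return d
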