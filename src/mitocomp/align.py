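"""Global alignment: protein-guided codon alignment and plain nucleotide
alignment.

The aligner is a Gotoh affine-gap global aligner with deterministic
traceback (diagonal preferred over a gap in the second sequence, which is
preferred over a gap in the first), so outputs are bit-reproducible.  A
length-k gap costs ``gap_open + (k - 1) * gap_extend``.

Multi-sequence alignments use star progression around the first input
sequence; with five close mitogenome sequences and mostly indel-free genes
this is entirely adequate and keeps the result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
from Bio.Align import substitution_matrices

from .composition import GENETIC_CODE, STOP_CODONS

__all__ = [
    "AlignmentError",
    "CodonAlignment",
    "NucAlignment",
    "NUC_MATCH", "NUC_MISMATCH", "NUC_GAP_OPEN", "NUC_GAP_EXTEND",
    "PROT_GAP_OPEN", "PROT_GAP_EXTEND",
    "global_align",
    "align_nuc",
    "align_codon",
    "translate_cds",
    "write_fasta_alignment",
]

NUC_MATCH = 2.0
NUC_MISMATCH = -1.0
NUC_GAP_OPEN = -5.0
NUC_GAP_EXTEND = -2.0

PROT_GAP_OPEN = -11.0
PROT_GAP_EXTEND = -1.0

_DAYHOFF = substitution_matrices.load("DAYHOFF")


class AlignmentError(ValueError):
    pass


def _nuc_score(a: str, b: str) -> float:
    return NUC_MATCH if a == b else NUC_MISMATCH


def _prot_score(a: str, b: str) -> float:
    try:
        return float(_DAYHOFF[a, b])
    except (KeyError, IndexError):
        return 0.0


def global_align(a: str, b: str, score: Callable[[str, str], float],
                 gap_open: float, gap_extend: float,
                 ) -> tuple[str, str, float]:
    """Optimal global alignment of two strings (Gotoh, affine gaps).

    Returns (aligned_a, aligned_b, score).  Traceback ties prefer diagonal,
    then a gap in ``b`` (consuming ``a``), then a gap in ``a``.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    n, m = len(a), len(b)
    NEG = -np.inf
    # encode sequences and build a dense score table over their alphabet
    alphabet = sorted(set(a) | set(b))
    idx = {ch: i for i, ch in enumerate(alphabet)}
    table = np.array([[score(x, y) for y in alphabet] for x in alphabet])
    ea = np.array([idx[ch] for ch in a])
    eb = np.array([idx[ch] for ch in b])
    M = np.full((n + 1, m + 1), NEG)   # a[i-1] aligned to b[j-1]
    X = np.full((n + 1, m + 1), NEG)   # gap in b (vertical, consumes a)
    Y = np.full((n + 1, m + 1), NEG)   # gap in a (horizontal, consumes b)
    M[0, 0] = 0.0
    X[1:, 0] = gap_open + np.arange(n) * gap_extend
    Y[0, 1:] = gap_open + np.arange(m) * gap_extend
    jj = np.arange(m + 1)
    for i in range(1, n + 1):
        srow = table[ea[i - 1]][eb]
        prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev[:-1] + srow
        X[i] = np.maximum(np.maximum(M[i - 1], Y[i - 1]) + gap_open,
                          X[i - 1] + gap_extend)
        # horizontal gaps: Y[i, j] = max_{k<j} max(M,X)[i, k] + open
        #                            + (j-1-k) * extend, via a running max
        z = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(z - gap_extend * jj)
        Y[i, 1:] = gap_extend * (jj[1:] - 1) + run[:-1] + gap_open
    # traceback; tie-break on final state: M, then X, then Y
    i, j = n, m
    state = "M"
    final = max(M[n, m], X[n, m], Y[n, m])
    for st in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[st][n, m] == final:
            state = st
            break
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = score(a[i - 1], b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i, j] - target) < tol:
                    state = st
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] + gap_open - val) < tol:
                state = "M"
            elif abs(X[i, j] + gap_extend - val) < tol:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] + gap_open - val) < tol:
                state = "M"
            elif abs(Y[i, j] + gap_extend - val) < tol:
                state = "Y"
            else:
                state = "X"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(final)


def _star_merge(center: str, pairs: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise alignments to a common center sequence.

    ``pairs`` holds (aligned_center, aligned_other) per sequence.  Gap columns
    inserted into the center by different pairs are united ("once a gap,
    always a gap").
    """
    k = len(center)
    # gaps[i] = max gap run inserted before center position i (i in 0..k)
    gaps = [0] * (k + 1)
    for ac, _ in pairs:
        pos = 0
        run = 0
        for ch in ac:
            if ch == "-":
                run += 1
            else:
                gaps[pos] = max(gaps[pos], run)
                run = 0
                pos += 1
        gaps[k] = max(gaps[k], run)
    rows = []
    # rebuild each row on the master coordinate system
    master_center = []
    for i in range(k):
        master_center.append("-" * gaps[i])
        master_center.append(center[i])
    master_center.append("-" * gaps[k])
    rows.append("".join(master_center))
    for ac, ao in pairs:
        out = []
        pos = 0            # center position index
        pending = []       # other-sequence chars aligned to center gaps
        for cc, oc in zip(ac, ao):
            if cc == "-":
                pending.append(oc)
            else:
                out.append("".join(pending).rjust(gaps[pos], "-"))
                pending = []
                out.append(oc)
                pos += 1
        out.append("".join(pending).rjust(gaps[k], "-"))
        rows.append("".join(out))
    return rows


@dataclass
class NucAlignment:
    """A gapped nucleotide alignment of one region across taxa."""

    region: str
    taxa: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"{self.region}: unequal row lengths")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def pair(self, a: str, b: str) -> tuple[str, str]:
        return self.rows[a], self.rows[b]

    def degapped(self, taxon: str) -> str:
        return self.rows[taxon].replace("-", "")


@dataclass
class CodonAlignment:
    """Protein-guided codon alignment; gaps come in whole triplets."""

    gene: str
    taxa: list[str]
    rows: dict[str, str]
    protein_rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"{self.gene}: unequal row lengths")
        if self.length % 3:
            raise AlignmentError(f"{self.gene}: length not a codon multiple")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def position_masks(self) -> np.ndarray:
        """Site-class array (1, 2, 3, 1, 2, 3, ...) over alignment columns."""
        return np.tile([1, 2, 3], self.length // 3)

    def pair(self, a: str, b: str) -> tuple[str, str]:
        return self.rows[a], self.rows[b]

    def degapped(self, taxon: str) -> str:
        return self.rows[taxon].replace("-", "")

    def codons(self, taxon: str) -> list[str]:
        r = self.rows[taxon]
        return [r[i:i + 3] for i in range(0, len(r), 3)]

    def to_nuc(self) -> NucAlignment:
        return NucAlignment(self.gene, list(self.taxa), dict(self.rows))


def translate_cds(cds: str, gene: str = "", taxon: str = "") -> tuple[str, str]:
    """Translate a CDS under table 5 for alignment purposes.

    Drops a trailing incomplete codon and the terminal stop codon; returns
    (protein, trimmed_cds).  Raises :class:`AlignmentError` on internal
    stops or untranslatable codons.
    """
    cds = cds.upper()
    cds = cds[:len(cds) - len(cds) % 3]
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if not cds:
        raise AlignmentError(f"{taxon}/{gene}: empty CDS after trimming")
    prot = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            raise AlignmentError(
                f"{taxon}/{gene}: internal stop codon at position {i + 1}"
            )
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            aa = "X"  # codons containing N
        prot.append(aa)
    return "".join(prot), cds


def align_nuc(seqs_by_taxon: Mapping[str, str], region: str = "",
              ) -> NucAlignment:
    """Global nucleotide alignment (pairwise, or star-progressive for >2)."""
    taxa = list(seqs_by_taxon)
    if len(taxa) < 2:
        raise AlignmentError("need at least two sequences")
    for t in taxa:
        if not seqs_by_taxon[t]:
            raise AlignmentError(f"{t}: empty sequence")
    center = taxa[0]
    pairs = []
    for t in taxa[1:]:
        ac, ao, _ = global_align(seqs_by_taxon[center], seqs_by_taxon[t],
                                 _nuc_score, NUC_GAP_OPEN, NUC_GAP_EXTEND)
        pairs.append((ac, ao))
    rows = _star_merge(seqs_by_taxon[center], pairs)
    return NucAlignment(region, taxa, dict(zip(taxa, rows)))


def align_codon(cds_by_taxon: Mapping[str, str], gene: str = "",
                ) -> CodonAlignment:
    """Protein-guided codon alignment of one gene across taxa."""
    taxa = list(cds_by_taxon)
    if len(taxa) < 2:
        raise AlignmentError("need at least two sequences")
    prots: dict[str, str] = {}
    trimmed: dict[str, str] = {}
    for t in taxa:
        prots[t], trimmed[t] = translate_cds(cds_by_taxon[t], gene=gene,
                                             taxon=t)
    center = taxa[0]
    pairs = []
    for t in taxa[1:]:
        ac, ao, _ = global_align(prots[center], prots[t], _prot_score,
                                 PROT_GAP_OPEN, PROT_GAP_EXTEND)
        pairs.append((ac, ao))
    prot_rows = dict(zip(taxa, _star_merge(prots[center], pairs)))
    rows = {}
    for t in taxa:
        codons = [trimmed[t][i:i + 3] for i in range(0, len(trimmed[t]), 3)]
        it = iter(codons)
        rows[t] = "".join("---" if ch == "-" else next(it)
                          for ch in prot_rows[t])
    return CodonAlignment(gene, taxa, rows, protein_rows=prot_rows)


def write_fasta_alignment(aln: NucAlignment | CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for t in aln.taxa:
            fh.write(f">{t}\n{aln.rows[t]}\n")
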