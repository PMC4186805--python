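"""Structure discovery in the AT-rich (control) region: tandem repeats,
cross-taxon conserved segments, poly(N) runs and simplified hairpin
(stem-loop) detection.

All coordinates are 1-based inclusive and relative to the region analysed.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "RepeatAnnotation",
    "ConservedSegment",
    "Hairpin",
    "find_tandem_repeats",
    "find_conserved_segments",
    "poly_n_runs",
    "find_hairpins",
    "self_match_matrix",
    "DEFAULT_REPEAT_PARAMS",
    "DEFAULT_SEGMENT_PARAMS",
    "DEFAULT_HAIRPIN_PARAMS",
]

DEFAULT_REPEAT_PARAMS = {"min_unit": 20, "min_copies": 2.0,
                         "min_identity": 0.85}
# seed length 6: long enough to be specific across five taxa, short enough
# that a ~95%-identity block almost surely contains a near-exact window;
# min_len 18 keeps chance AT-rich look-alikes out at this seed length
DEFAULT_SEGMENT_PARAMS = {"k": 6, "min_len": 18, "min_identity": 0.90}
DEFAULT_HAIRPIN_PARAMS = {"min_stem": 4, "max_loop": 30}


@dataclass(frozen=True)
class RepeatAnnotation:
    start: int
    end: int
    unit_length: int
    copy_number: float
    unit_consensus: str
    mean_unit_identity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConservedSegment:
    segment_id: int
    coords: dict  # taxon -> (start, end)
    consensus: str
    min_pairwise_identity: float

    @property
    def length(self) -> int:
        s, e = next(iter(self.coords.values()))
        return e - s + 1


@dataclass(frozen=True)
class Hairpin:
    start: int
    end: int
    stem_length: int
    loop_length: int
    paired_fraction: float
    score: int


# ---------------------------------------------------------------------------
# tandem repeats

def _identity_at_period(seq: str, start: int, end: int, p: int) -> float:
    """Fraction of positions i in [start, end-p] with seq[i] == seq[i+p]."""
    n = end - start + 1 - p
    if n <= 0:
        return 0.0
    a = np.frombuffer(seq[start:start + n].encode(), dtype=np.uint8)
    b = np.frombuffer(seq[start + p:start + p + n].encode(), dtype=np.uint8)
    return float(np.mean(a == b))


def _scan_period(match: np.ndarray, p: int, min_identity: float,
                 min_run: int) -> list[tuple[int, int]]:
    """Greedy maximal intervals of the self-match array at one period,
    with ends trimmed back to locally well-matching windows."""
    out = []
    n = len(match)
    i = 0
    max_mis = 1.0 - min_identity
    w = max(4, min(p, 20))  # local window used to trim ragged ends
    while i < n:
        if not match[i]:
            i += 1
            continue
        j = i
        mis = 0
        best_j = i
        while j < n:
            if not match[j]:
                mis += 1
            if mis <= max_mis * (j - i + 1):
                best_j = j
            elif mis > max_mis * (j - i + 1) + 2:
                break
            j += 1
        s, e = i, best_j
        # trim ends while the outermost window matches poorly
        while e - s + 1 >= w and np.mean(match[e - w + 1:e + 1]) < min_identity:
            e -= 1
        while e - s + 1 >= w and np.mean(match[s:s + w]) < min_identity:
            s += 1
        while e > s and not match[e]:
            e -= 1
        while s < e and not match[s]:
            s += 1
        if e - s + 1 >= min_run:
            out.append((s, e))
        i = best_j + 1
    return out


def find_tandem_repeats(region: str, min_unit: int = 20,
                        min_copies: float = 2.0,
                        min_identity: float = 0.85,
                        ) -> list[RepeatAnnotation]:
    """Period-scan tandem-repeat detection.

    For every candidate period p the region is compared with itself shifted
    by p; maximal intervals whose self-match fraction exceeds
    ``min_identity`` and span at least ``min_copies`` copies are reported,
    best-first and non-overlapping.  Each reported period is canonicalized
    to its smallest divisor still meeting ``min_identity``.
    """
    region = region.upper()
    L = len(region)
    max_p = int(L // min_copies)
    if L < min_unit * min_copies:
        return []
    arr = np.frombuffer(region.encode(), dtype=np.uint8)
    candidates = []  # (score, start, end, period, identity)
    for p in range(min_unit, max_p + 1):
        match = arr[:-p] == arr[p:]
        min_run = max(int(round(p * (min_copies - 1.0))), 1)
        for (s, e) in _scan_period(match, p, min_identity, min_run):
            length = e - s + 1 + p  # repeat area spans both compared copies
            ident = float(np.mean(match[s:e + 1]))
            if ident < min_identity:
                continue
            candidates.append((length * ident, s, s + length - 1, p, ident))
    candidates.sort(key=lambda c: (-c[0], c[1], c[3]))
    chosen: list[tuple[int, int, int, float]] = []
    for _, s, e, p, ident in candidates:
        if any(not (e < cs or s > ce) for cs, ce, _, _ in chosen):
            continue
        # canonicalize the period to its smallest adequate divisor
        for d in range(min_unit, p):
            if p % d == 0 and \
                    _identity_at_period(region, s, e, d) >= min_identity:
                p = d
                break
        chosen.append((s, e, p, ident))
    out = []
    for s, e, p, ident in sorted(chosen):
        length = e - s + 1
        copies = length / p
        if copies < min_copies:
            continue
        n_full = length // p
        cols = [Counter(region[s + k * p + j] for k in range(n_full))
                for j in range(p)]
        consensus = "".join(c.most_common(1)[0][0] for c in cols)
        out.append(RepeatAnnotation(
            start=s + 1, end=e + 1, unit_length=p,
            copy_number=round(copies, 1), unit_consensus=consensus,
            mean_unit_identity=ident,
        ))
    return out


def self_match_matrix(region: str, other: Optional[str] = None) -> np.ndarray:
    """Boolean dot-plot matrix (region vs itself or vs ``other``)."""
    a = np.frombuffer(region.upper().encode(), dtype=np.uint8)
    b = a if other is None else \
        np.frombuffer(other.upper().encode(), dtype=np.uint8)
    return a[:, None] == b[None, :]


# ---------------------------------------------------------------------------
# conserved segments

def _column_agreement(regions: list[str], offsets: list[int],
                      delta: int) -> float:
    """Fraction of taxa matching the column majority at a common offset."""
    col = [r[o + delta] for r, o in zip(regions, offsets)]
    return Counter(col).most_common(1)[0][1] / len(col)


def find_conserved_segments(regions_by_taxon: Mapping[str, str],
                            k: int = 6, min_len: int = 18,
                            min_identity: float = 0.90,
                            ) -> list[ConservedSegment]:
    """Anchor-and-extend discovery of segments conserved across all taxa.

    Exact k-mers shared by every taxon seed candidate loci, which are then
    extended in both directions while the running mean column agreement
    (fraction of taxa matching the column majority) stays at or above
    ``min_identity``; ends are trimmed back to fully agreeing columns.
    Overlapping candidates are merged and segments are numbered along the
    first taxon's coordinates.
    """
    taxa = list(regions_by_taxon)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    regions = [regions_by_taxon[t].upper() for t in taxa]
    enc = [np.frombuffer(r.encode(), dtype=np.uint8) for r in regions]
    kmer_pos: list[dict[str, list[int]]] = []
    for r in regions:
        d: dict[str, list[int]] = defaultdict(list)
        for i in range(len(r) - k + 1):
            d[r[i:i + k]].append(i)
        kmer_pos.append(d)
    n_tax = len(taxa)
    # a column is "good" when at most this many taxa miss the majority base
    allowed_miss = int(n_tax * (1.0 - min_identity) + 0.5 + 1e-9)

    def col_ok(offsets, delta) -> bool:
        agree = _column_agreement(regions, offsets, delta)
        return (n_tax - round(agree * n_tax)) <= allowed_miss

    def best_occurrence(t_idx: int, occs: list[int], ref_region: str,
                        ref_pos: int) -> int:
        """Pick the occurrence whose +-12 bp context best matches the
        reference taxon's context around its anchor."""
        if len(occs) == 1:
            return occs[0]
        w = 12
        ref = ref_region[max(ref_pos - w, 0):ref_pos + k + w]
        best, best_score = occs[0], -1
        for o in occs:
            ctx = regions[t_idx][max(o - w, 0):o + k + w]
            score = sum(x == y for x, y in zip(ref, ctx))
            if score > best_score:
                best, best_score = o, score
        return best

    ctx_w = 12

    def best_context_position(t_idx: int, ref_pos: int) -> Optional[int]:
        """Best-matching position in a taxon lacking the exact anchor k-mer:
        slide the reference taxon's anchor context along the whole region
        and keep the argmax if it matches well enough."""
        lo_ref = max(ref_pos - ctx_w, 0)
        ref = enc[0][lo_ref:ref_pos + k + ctx_w]
        win = len(ref)
        if len(enc[t_idx]) < win:
            return None
        sw = np.lib.stride_tricks.sliding_window_view(enc[t_idx], win)
        scores = (sw == ref[None, :]).sum(axis=1)
        best = int(np.argmax(scores))
        if scores[best] / win < 0.6:
            return None
        return best + (ref_pos - lo_ref)

    candidates = []
    seen_anchors: set[tuple[int, ...]] = set()
    # anchor on k-mers of the first taxon that have an exact occurrence in
    # all, or all but one, of the remaining taxa
    for kmer in sorted(kmer_pos[0]):
        missing = [i for i in range(1, n_tax) if kmer not in kmer_pos[i]]
        if len(missing) > 1:
            continue
        if any(len(kmer_pos[i].get(kmer, ())) > 16 for i in range(n_tax)):
            continue  # low-complexity k-mer: unreliable anchor
        anchor_sets = []
        for o1 in kmer_pos[0][kmer]:
            offs: list[Optional[int]] = [o1]
            for i in range(1, n_tax):
                if i in missing:
                    offs.append(best_context_position(i, o1))
                else:
                    offs.append(best_occurrence(i, kmer_pos[i][kmer],
                                                regions[0], o1))
            if all(o is not None for o in offs):
                anchor_sets.append(offs)
        for offsets in anchor_sets:
            key = tuple(offsets)
            if key in seen_anchors:
                continue
            seen_anchors.add(key)
            lo, hi = 0, k - 1  # inclusive offsets relative to anchor start
            # extend until two consecutive bad columns (single mutated
            # columns inside a conserved block are absorbed)
            for step in (+1, -1):
                edge = hi if step > 0 else lo
                bad = 0
                while True:
                    nxt = edge + step
                    if any(not (0 <= o + nxt < len(r))
                           for r, o in zip(regions, offsets)):
                        break
                    if col_ok(offsets, nxt):
                        bad = 0
                    else:
                        bad += 1
                        if bad >= 2:
                            break
                    edge = nxt
                if step > 0:
                    hi = edge
                else:
                    lo = edge
            # trim: outermost windows must match well, then end columns
            # must individually be good
            w = 4
            while hi - lo + 1 >= w:
                mean = sum(_column_agreement(regions, offsets, d)
                           for d in range(hi - w + 1, hi + 1)) / w
                if mean >= min_identity:
                    break
                hi -= 1
            while hi - lo + 1 >= w:
                mean = sum(_column_agreement(regions, offsets, d)
                           for d in range(lo, lo + w)) / w
                if mean >= min_identity:
                    break
                lo += 1
            while lo < hi and not col_ok(offsets, lo):
                lo += 1
            while hi > lo and not col_ok(offsets, hi):
                hi -= 1
            if hi - lo + 1 < min_len:
                continue
            total = sum(_column_agreement(regions, offsets, d)
                        for d in range(lo, hi + 1))
            if total / (hi - lo + 1) < min_identity:
                continue
            # every taxon must carry the segment, not just a majority:
            # each row must closely match the consensus of the *other*
            # rows (leave-one-out), so one hitch-hiking taxon cannot pass
            floor = max(0.0, 2.0 * min_identity - 1.0)
            length = hi - lo + 1
            cols = [[r[o + d] for r, o in zip(regions, offsets)]
                    for d in range(lo, hi + 1)]
            quality = 1.0
            ok = True
            for t in range(n_tax):
                same = 0
                for col in cols:
                    rest = col[:t] + col[t + 1:]
                    if col[t] == Counter(rest).most_common(1)[0][0]:
                        same += 1
                if same / length < floor:
                    ok = False
                    break
                quality = min(quality, same / length)
            if not ok:
                continue
            candidates.append((offsets[0] + lo, offsets[0] + hi, offsets,
                               lo, hi, quality))
    # candidates overlapping in most taxa but placed elsewhere in another
    # taxon are rival placements of one locus: keep the better one
    drop = set()
    for a in range(len(candidates)):
        for b in range(len(candidates)):
            if a == b or b in drop or a in drop:
                continue
            ca, cb = candidates[a], candidates[b]
            agree = disagree = 0
            for o_a, o_b in zip(ca[2], cb[2]):
                if o_a + ca[3] <= o_b + cb[4] and o_b + cb[3] <= o_a + ca[4]:
                    agree += 1
                else:
                    disagree += 1
            if agree >= n_tax - 1 and disagree >= 1:
                drop.add(a if ca[5] < cb[5] else b)
    candidates = [c for i, c in enumerate(candidates) if i not in drop]
    # merge candidates overlapping in the first taxon's coordinates
    candidates.sort()
    merged: list[tuple] = []
    for c in candidates:
        if merged and c[0] <= merged[-1][1]:
            if c[1] - c[0] > merged[-1][1] - merged[-1][0]:
                merged[-1] = c
            continue
        merged.append(c)
    out = []
    for (s0, e0, offsets, lo, hi, quality) in merged:
        length = hi - lo + 1
        coords = {t: (o + lo + 1, o + hi + 1)
                  for t, o in zip(taxa, offsets)}
        cols = []
        for delta in range(lo, hi + 1):
            col = [r[o + delta] for r, o in zip(regions, offsets)]
            cols.append(Counter(col).most_common(1)[0][0])
        consensus = "".join(cols)
        min_pid = 1.0
        for i, j in itertools.combinations(range(len(taxa)), 2):
            same = sum(regions[i][offsets[i] + d] == regions[j][offsets[j] + d]
                       for d in range(lo, hi + 1))
            min_pid = min(min_pid, same / length)
        out.append(ConservedSegment(len(out) + 1, coords, consensus, min_pid))
    return out


# ---------------------------------------------------------------------------
# poly(N) runs

def poly_n_runs(region: str, min_len: int = 5) -> list[tuple[str, int, int]]:
    """Maximal single-base runs of length >= min_len as (base, start, length)."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    region = region.upper()
    out = []
    i = 0
    n = len(region)
    while i < n:
        j = i
        while j + 1 < n and region[j + 1] == region[i]:
            j += 1
        run = j - i + 1
        if run >= min_len and region[i] in "ACGT":
            out.append((region[i], i + 1, run))
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# hairpins

_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                    ("G", "T"), ("T", "G")})  # Watson-Crick plus G.U


def _pairs(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def find_hairpins(segment: str, min_stem: int = 4, max_loop: int = 30,
                  ) -> list[Hairpin]:
    """All maximal inverted-repeat hairpins, best-first non-overlapping.

    A hairpin at (start, end) pairs ``stem`` outer bases on each side
    (Watson-Crick or G.U) around a loop of 3..max_loop unpaired bases.
    Stems are maximal: they cannot be extended inward or outward.  The
    score is the number of paired bases (2 x stem).
    """
    seq = segment.upper()
    n = len(seq)
    found = []
    for i in range(n):
        # loop spans [i, j]; stems grow outward from (i-1, j+1)
        for loop in range(3, max_loop + 1):
            j = i + loop - 1
            if j >= n:
                break
            stem = 0
            a, b = i - 1, j + 1
            while a >= 0 and b < n and _pairs(seq[a], seq[b]):
                stem += 1
                a -= 1
                b += 1
            if stem < min_stem:
                continue
            # inward extension impossible by construction only if the bases
            # flanking the loop inside do not pair (else a smaller loop
            # would cover it); enforce maximality explicitly:
            if loop > 3 and _pairs(seq[i], seq[j]):
                continue  # not maximal: stem extends inward
            start, end = a + 2, b  # 1-based outer coordinates
            length = end - start + 1
            found.append(Hairpin(start=start, end=end, stem_length=stem,
                                 loop_length=loop,
                                 paired_fraction=2 * stem / length,
                                 score=2 * stem))
    found.sort(key=lambda h: (-h.score, h.start, h.loop_length))
    chosen: list[Hairpin] = []
    for h in found:
        if any(not (h.end < c.start or h.start > c.end) for c in chosen):
            continue
        chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return chosen
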