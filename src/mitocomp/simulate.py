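"""Synthetic annotated-mitogenome generator with ground truth.

An ancestral ~15.4 kb circular genome is built with the 37-gene ancestral
insect arrangement (23 genes on J, 14 on N), valid invertebrate-
mitochondrial ORFs, three planted protein-gene overlaps, and an AT-rich
region containing planted tandem repeats, conserved blocks, poly(N) runs
and a hairpin.  Descendant taxa are generated by per-site substitution
under a Kimura two-parameter process with per-partition branch lengths; the
planted truth is serialized alongside so every downstream estimator can be
scored against it.

Sequences evolve without indels by default, so alignments are site-wise and
realized distances are directly comparable to the planted branch lengths
(expected pairwise distance = 2 x branch length on the star tree).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .composition import GENETIC_CODE, STOP_CODONS
from .io import (ANCESTRAL_GENE_ORDER, AnnotatedGenome, GeneFeature,
                 reverse_complement, write_genbank)

__all__ = [
    "AtRichPlan",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genomes",
    "evolve_sequence",
    "build_atrich_region",
    "k2p_event_probs",
    "make_fixture_suite",
    "write_simulation",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

#: default gene lengths (bp, coding orientation, incl. start and stop)
_GENE_LENGTHS = {
    "cox1": 1536, "cox2": 684, "cox3": 786, "cytb": 1137, "nad1": 924,
    "nad2": 978, "nad3": 354, "nad4": 1338, "nad4l": 294, "nad5": 1716,
    "nad6": 522, "atp6": 672, "atp8": 159,
    "rrnL": 1285, "rrnS": 780,
}
_TRNA_LENGTH = 66

#: genome-adjacent gene pairs sharing a 7 nt "ATGATAA"-style junction;
#: (first_in_genome, second_in_genome, coding_upstream)
_OVERLAPS = (
    ("atp8", "atp6", "atp8"),
    ("nad4", "nad4l", "nad4l"),
    ("nad6", "cytb", "nad6"),
)
_OVERLAP_LEN = 7


@dataclass
class AtRichPlan:
    """Planted structure of the synthetic AT-rich region."""

    length: int = 1000
    repeat_unit_length: int = 60
    repeat_copies: float = 3.6
    n_conserved: int = 4
    conserved_len_range: tuple[int, int] = (20, 40)
    poly_runs: tuple[tuple[str, int], ...] = (("T", 8), ("A", 7), ("G", 6))
    hairpin_stem: int = 8
    hairpin_loop: int = 5
    #: branch length applied to conserved blocks, repeats and poly runs
    element_rate: float = 0.01


@dataclass
class SimulationConfig:
    n_taxa: int = 5
    seed: int = 0
    taxon_prefix: str = "taxon"
    #: per-partition branch lengths (substitutions/site, root to tip)
    branch_pos1: float = 0.06
    branch_pos2: float = 0.03
    branch_pos3: float = 0.16
    branch_trna: float = 0.05
    branch_rrna: float = 0.045
    branch_atrich: float = 0.30
    branch_spacer: float = 0.30
    ti_tv_kappa: float = 4.0
    #: probability that a proposed amino-acid-changing codon is accepted
    nonsyn_scaling: float = 1.0
    #: (T, C, A, G) frequencies per codon position, coding orientation
    pos_freqs: tuple[tuple[float, ...], ...] = (
        (0.281, 0.132, 0.429, 0.158),
        (0.453, 0.203, 0.214, 0.130),
        (0.340, 0.121, 0.440, 0.099),
    )
    rna_freqs: tuple[float, ...] = (0.356, 0.095, 0.444, 0.105)
    atrich_freqs: tuple[float, ...] = (0.380, 0.109, 0.436, 0.075)
    #: scales all gene lengths (1.0 gives a ~15.4 kb genome)
    scale: float = 1.0
    plant_indels: bool = False
    atrich: AtRichPlan = field(default_factory=AtRichPlan)

    def __post_init__(self) -> None:
        for name in ("branch_pos1", "branch_pos2", "branch_pos3",
                     "branch_trna", "branch_rrna", "branch_atrich",
                     "branch_spacer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for freqs in (*self.pos_freqs, self.rna_freqs, self.atrich_freqs):
            if abs(sum(freqs) - 1.0) > 1e-6:
                raise ValueError("base frequencies must sum to 1")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "atrich" in d and isinstance(d["atrich"], dict):
            at = d["atrich"]
            for key in ("conserved_len_range",):
                if key in at:
                    at[key] = tuple(at[key])
            if "poly_runs" in at:
                at["poly_runs"] = tuple((b, int(n)) for b, n in at["poly_runs"])
            d["atrich"] = AtRichPlan(**at)
        for key in ("pos_freqs", "rna_freqs", "atrich_freqs"):
            if key in d:
                v = d[key]
                d[key] = tuple(tuple(x) if isinstance(x, list) else x
                               for x in v)
        return cls(**d)


@dataclass
class SimulationTruth:
    """Everything needed to score parameter- and element-recovery."""

    branch_lengths: dict
    expected_pair_distance: dict
    kappa: float
    nonsyn_scaling: float
    gene_coords: dict            # name -> [start, end, strand, kind]
    atrich_span: tuple[int, int]
    repeat: Optional[dict]       # region-relative coords, unit, copies
    conserved_blocks: list       # [(start, end), ...] region-relative
    poly_runs: list              # [(base, start, length), ...]
    hairpin: Optional[dict]
    pos_freqs: tuple
    rna_freqs: tuple
    atrich_freqs: tuple

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["atrich_span"] = tuple(d["atrich_span"])
        for key in ("pos_freqs", "rna_freqs", "atrich_freqs"):
            d[key] = tuple(tuple(x) if isinstance(x, list) else x
                           for x in d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# K2p substitution process

def k2p_event_probs(d: np.ndarray | float, kappa: float,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(P_transition, Q_transversion) after branch length d under K2p.

    ``kappa`` is the instantaneous transition/transversion rate ratio
    alpha/beta; d is in expected substitutions/site.
    """
    d = np.asarray(d, dtype=float)
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    P = 0.25 + 0.25 * np.exp(-4.0 * beta_t) \
        - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    Q = 0.5 - 0.5 * np.exp(-4.0 * beta_t)
    return P, Q


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_TO_CODE = np.zeros(256, dtype=np.int8)
for _b, _i in _CODE.items():
    _TO_CODE[ord(_b)] = _i
_FROM_CODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def evolve_sequence(seq: str, d: float | np.ndarray, kappa: float,
                    rng: np.random.Generator) -> str:
    """One descendant of ``seq`` after branch length ``d`` (scalar or
    per-site array) under K2p with the given kappa."""
    codes = _TO_CODE[_encode(seq)].astype(np.int64)
    P, Q = k2p_event_probs(np.broadcast_to(np.asarray(d, dtype=float),
                                           codes.shape), kappa)
    u = rng.random(codes.shape)
    # A=0 C=1 G=2 T=3: transition partner is (c+2)%4, transversions
    # (c+1)%4 and (c+3)%4 at Q/2 each
    out = codes.copy()
    ti = u < P
    tv1 = (~ti) & (u < P + Q / 2.0)
    tv2 = (~ti) & (~tv1) & (u < P + Q)
    out[ti] = (codes[ti] + 2) % 4
    out[tv1] = (codes[tv1] + 1) % 4
    out[tv2] = (codes[tv2] + 3) % 4
    return _FROM_CODE[out].tobytes().decode()


# ---------------------------------------------------------------------------
# ancestral sequence construction

def _sample_bases(freqs, n: int, rng: np.random.Generator) -> str:
    # freqs given as (T, C, A, G)
    return "".join(rng.choice(list("TCAG"), size=n, p=list(freqs)))


def _sample_orf(n_codons: int, pos_freqs, rng: np.random.Generator) -> str:
    """ATG + (n_codons - 2) non-stop codons + TAA."""
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(
                _sample_bases(pos_freqs[i], 1, rng) for i in range(3))
            if codon not in STOP_CODONS:
                break
        body.append(codon)
    return "ATG" + "".join(body) + "TAA"


def _plant_junctions(coding: dict[str, str]) -> None:
    """Force the shared 7 nt 'ATGATAA' junction into each overlap pair."""
    for first, second, upstream in _OVERLAPS:
        down = second if upstream == first else first
        u = coding[upstream]
        coding[upstream] = u[:-9] + "CCA" + "TGA" + "TAA"
        dseq = coding[down]
        coding[down] = "ATG" + "ATA" + "A" + dseq[7:]


def build_atrich_region(plan: AtRichPlan, freqs,
                        rng: np.random.Generator) -> tuple[str, dict]:
    """Assemble the planted AT-rich region; returns (sequence, elements).

    Layout (for four conserved blocks): filler, block 1, filler, repeat
    area, filler, block 2, filler, block 3, filler, poly(N) runs, filler,
    block 4, filler — short blocks at the ends, repeats between blocks 1
    and 2, poly runs between the last two blocks.  Element coordinates are
    region-relative, 1-based inclusive.
    """
    lens = rng.integers(plan.conserved_len_range[0],
                        plan.conserved_len_range[1] + 1,
                        size=plan.n_conserved)
    blocks = [_sample_bases(freqs, int(n), rng) for n in lens]
    hairpin_len = 0
    if plan.hairpin_stem and plan.n_conserved >= 2:
        # embed a perfect stem-loop at the start of the second block
        stem = _sample_bases(freqs, plan.hairpin_stem, rng)
        loop = _sample_bases(freqs, plan.hairpin_loop, rng)
        hp = stem + loop + reverse_complement(stem)
        hairpin_len = len(hp)
        blocks[1] = hp + blocks[1][len(hp):] if len(blocks[1]) > len(hp) \
            else hp
    unit = _sample_bases(freqs, plan.repeat_unit_length, rng)
    rep_len = int(round(plan.repeat_unit_length * plan.repeat_copies))
    repeat_area = (unit * (rep_len // len(unit) + 1))[:rep_len]

    items: list[tuple[str, object]] = [("block", blocks[0]),
                                       ("repeat", repeat_area)]
    items += [("block", b) for b in blocks[1:-1]]
    if plan.poly_runs:
        items.append(("poly", plan.poly_runs))
    if plan.n_conserved >= 2:
        items.append(("block", blocks[-1]))
    planned = sum(len(b) for b in blocks) + rep_len + \
        sum(n for _, n in plan.poly_runs)
    n_fill = len(items) + 1
    filler_total = plan.length - planned
    if filler_total < n_fill * 5:
        raise ValueError("AT-rich plan exceeds region length")
    sizes = 5 + rng.multinomial(filler_total - 5 * n_fill,
                                [1.0 / n_fill] * n_fill)

    parts: list[str] = []
    elements: dict = {"conserved": [], "poly": [], "repeat": None,
                      "hairpin": None}

    def emit(s: str) -> int:
        start = sum(len(p) for p in parts) + 1
        parts.append(s)
        return start

    block_no = 0
    for i, (kind, payload) in enumerate(items):
        emit(_sample_bases(freqs, int(sizes[i]), rng))
        if kind == "block":
            start = emit(payload)
            elements["conserved"].append((start, start + len(payload) - 1))
            if block_no == 1 and hairpin_len:
                elements["hairpin"] = {
                    "start": start, "end": start + hairpin_len - 1,
                    "stem": plan.hairpin_stem, "loop": plan.hairpin_loop}
            block_no += 1
        elif kind == "repeat":
            start = emit(payload)
            elements["repeat"] = {
                "start": start, "end": start + rep_len - 1,
                "unit_length": plan.repeat_unit_length,
                "copies": round(rep_len / plan.repeat_unit_length, 1)}
        else:  # poly runs, back to back (bases differ between runs)
            for b, n in payload:
                start = emit(b * n)
                elements["poly"].append((b, start, n))
    emit(_sample_bases(freqs, int(sizes[-1]), rng))
    seq = "".join(parts)
    assert len(seq) == plan.length
    return seq, elements


def _scaled_lengths(scale: float) -> dict[str, int]:
    out = {}
    for name, L in _GENE_LENGTHS.items():
        if name in ("rrnL", "rrnS"):
            out[name] = max(60, int(round(L * scale)))
        else:
            out[name] = max(12, int(round(L * scale / 3.0)) * 3)
    return out


def _build_ancestor(config: SimulationConfig, rng: np.random.Generator,
                    ) -> tuple[str, list[GeneFeature], dict, dict]:
    lengths = _scaled_lengths(config.scale)
    coding: dict[str, str] = {}
    for name, strand in ANCESTRAL_GENE_ORDER:
        if name == "AT_rich":
            continue
        if name in lengths and name not in ("rrnL", "rrnS"):
            coding[name] = _sample_orf(lengths[name] // 3, config.pos_freqs,
                                       rng)
        elif name in ("rrnL", "rrnS"):
            coding[name] = _sample_bases(config.rna_freqs, lengths[name], rng)
        else:
            coding[name] = _sample_bases(config.rna_freqs, _TRNA_LENGTH, rng)
    _plant_junctions(coding)
    at_seq, at_elements = build_atrich_region(config.atrich,
                                              config.atrich_freqs, rng)
    coding["AT_rich"] = at_seq

    overlap_at = {pair[1]: _OVERLAP_LEN for pair in _OVERLAPS}
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0  # length written so far
    prev_name = None
    for name, strand in ANCESTRAL_GENE_ORDER:
        genomic = coding[name] if strand == "J" else \
            reverse_complement(coding[name])
        if prev_name is not None and overlap_at.get(name) and \
                prev_name == {p[1]: p[0] for p in _OVERLAPS}[name]:
            o = overlap_at[name]
            start = pos - o + 1
            parts.append(genomic[o:])
        else:
            # no spacer before the first gene (trnI abuts the AT-rich
            # region across the origin) nor before the AT-rich region
            spacer = 0 if (not parts or name == "AT_rich") \
                else int(rng.integers(0, 3))
            parts.append(_sample_bases(config.atrich_freqs, spacer, rng))
            start = pos + spacer + 1
            parts.append(genomic)
        pos = sum(len(p) for p in parts)
        kind = ("region" if name == "AT_rich" else
                "rRNA" if name.startswith("rrn") else
                "tRNA" if name.startswith("trn") else "PCG")
        features.append(GeneFeature(name, kind, start, pos, strand))
        prev_name = name
    return "".join(parts), features, at_elements, lengths


def _site_branch_lengths(seq_len: int, features: list[GeneFeature],
                         config: SimulationConfig, at_elements: dict,
                         ) -> np.ndarray:
    d = np.full(seq_len, config.branch_spacer)
    claimed = np.zeros(seq_len, dtype=bool)
    pcg_d = np.array([config.branch_pos1, config.branch_pos2,
                      config.branch_pos3])
    for f in features:
        idx = np.arange(f.start - 1, f.end)
        if f.kind == "PCG":
            rel = np.arange(len(idx))
            if f.strand == "N":
                rel = rel[::-1]
            vals = pcg_d[rel % 3]
        elif f.kind == "tRNA":
            vals = np.full(len(idx), config.branch_trna)
        elif f.kind == "rRNA":
            vals = np.full(len(idx), config.branch_rrna)
        else:  # AT_rich
            vals = np.full(len(idx), config.branch_atrich)
            er = config.atrich.element_rate
            for (s, e) in at_elements["conserved"]:
                vals[s - 1:e] = er
            rep = at_elements["repeat"]
            if rep:
                vals[rep["start"] - 1:rep["end"]] = er
            for (_, s, n) in at_elements["poly"]:
                vals[s - 1:s - 1 + n] = er
        free = ~claimed[idx]
        d[idx[free]] = vals[free]
        claimed[idx] = True
    return d


def _apply_purifying_selection(ancestor: str, descendant: str,
                               features: list[GeneFeature],
                               scaling: float,
                               rng: np.random.Generator) -> str:
    """Reject amino-acid-changing codons with probability 1 - scaling and
    all codons that became stops (proposal-rejection purifying selection)."""
    seq = list(descendant)
    claimed = [False] * len(seq)
    for f in features:
        if f.kind != "PCG":
            continue
        span = list(range(f.start - 1, f.end))
        if f.strand == "N":
            span = span[::-1]
        anc = "".join(ancestor[p] if f.strand == "J"
                      else reverse_complement(ancestor[p]) for p in span)
        cur = "".join(seq[p] if f.strand == "J"
                      else reverse_complement(seq[p]) for p in span)
        for c0 in range(0, len(span) - 2, 3):
            pos3 = span[c0:c0 + 3]
            if any(claimed[p] for p in pos3):
                continue
            a_codon = anc[c0:c0 + 3]
            d_codon = cur[c0:c0 + 3]
            if a_codon == d_codon or a_codon in STOP_CODONS:
                continue
            revert = False
            if d_codon in STOP_CODONS:
                revert = True
            elif GENETIC_CODE.get(d_codon) != GENETIC_CODE.get(a_codon):
                revert = rng.random() >= scaling
            if revert:
                for k, p in enumerate(pos3):
                    base = a_codon[k]
                    seq[p] = base if f.strand == "J" \
                        else reverse_complement(base)
        for p in span:
            claimed[p] = True
    # overlap codons are skipped above; stop codons created there (in the
    # frame of the non-owning gene) are repaired by reverting to the
    # ancestral bases, which are stop-free in every frame
    for _ in range(6):
        changed = False
        for f in features:
            if f.kind != "PCG":
                continue
            span = list(range(f.start - 1, f.end))
            if f.strand == "N":
                span = span[::-1]
            for c0 in range(0, len(span) - 2, 3):
                pos3 = span[c0:c0 + 3]
                codon = "".join(
                    seq[p] if f.strand == "J" else reverse_complement(seq[p])
                    for p in pos3)
                terminal = c0 + 3 >= len(span) - 2
                # internal codons must not be stops; the terminal codon
                # must stay one
                if (codon in STOP_CODONS) != terminal:
                    if "".join(ancestor[p] for p in pos3) == \
                            "".join(seq[p] for p in pos3):
                        continue  # already ancestral (overlap constraint)
                    for p in pos3:
                        seq[p] = ancestor[p]
                    changed = True
        if not changed:
            break
    return "".join(seq)


def simulate_genomes(config: SimulationConfig,
                     ) -> tuple[list[AnnotatedGenome], SimulationTruth]:
    """Simulate ``config.n_taxa`` genomes on a star tree plus ground truth."""
    rng = np.random.default_rng(config.seed)
    anc_seq, features, at_elements, _ = _build_ancestor(config, rng)
    site_d = _site_branch_lengths(len(anc_seq), features, config, at_elements)
    genomes = []
    for i in range(config.n_taxa):
        desc = evolve_sequence(anc_seq, site_d, config.ti_tv_kappa, rng)
        # stop-creating codons are always rejected (keeps ORFs translatable);
        # amino-acid changes are additionally thinned by nonsyn_scaling
        desc = _apply_purifying_selection(anc_seq, desc, features,
                                          config.nonsyn_scaling, rng)
        name = f"{config.taxon_prefix}{i + 1}"
        genomes.append(AnnotatedGenome(
            id=name, sequence=desc, circular=True,
            features=[dataclasses.replace(f) for f in features],
            taxon=name,
        ))
    at = next(f for f in features if f.name == "AT_rich")
    branch = {
        "pos1": config.branch_pos1, "pos2": config.branch_pos2,
        "pos3": config.branch_pos3, "tRNA": config.branch_trna,
        "rRNA": config.branch_rrna, "atrich": config.branch_atrich,
    }
    truth = SimulationTruth(
        branch_lengths=branch,
        expected_pair_distance={k: 2.0 * v for k, v in branch.items()},
        kappa=config.ti_tv_kappa,
        nonsyn_scaling=config.nonsyn_scaling,
        gene_coords={f.name: [f.start, f.end, f.strand, f.kind]
                     for f in features},
        atrich_span=(at.start, at.end),
        repeat=at_elements["repeat"],
        conserved_blocks=list(at_elements["conserved"]),
        poly_runs=list(at_elements["poly"]),
        hairpin=at_elements["hairpin"],
        pos_freqs=config.pos_freqs,
        rna_freqs=config.rna_freqs,
        atrich_freqs=config.atrich_freqs,
    )
    return genomes, truth


def write_simulation(genomes: list[AnnotatedGenome], truth: SimulationTruth,
                     out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_genbank(g, out / f"{g.id}.gb")
    truth.to_json(out / "truth.json")


def make_conserved_test_regions(rng: np.random.Generator, n_taxa: int = 5,
                                n_blocks: int = 4,
                                block_len_range: tuple[int, int] = (20, 40),
                                identity: float = 0.95,
                                background_len: int = 120,
                                freqs=(0.38, 0.109, 0.436, 0.075),
                                ) -> tuple[dict[str, str], list[tuple[int, int]]]:
    """Regions with shared conserved blocks inside unrelated random
    backgrounds: the ground-truth setting for conserved-segment recovery.

    Each taxon gets independent background sequence between the blocks;
    every block copy is mutated site-wise with probability 1 - identity.
    Returns (regions_by_taxon, block_coords) with coordinates valid for
    every taxon (backgrounds have equal lengths).
    """
    lens = rng.integers(block_len_range[0], block_len_range[1] + 1,
                        size=n_blocks)
    blocks = [_sample_bases(freqs, int(n), rng) for n in lens]
    regions = {}
    coords: list[tuple[int, int]] = []
    for t in range(n_taxa):
        parts = []
        pos = 0
        taxon_coords = []
        for b in blocks:
            bg = _sample_bases(freqs, background_len, rng)
            copy = list(b)
            for i in range(len(copy)):
                if rng.random() > identity:
                    copy[i] = "ACGT"[rng.integers(0, 4)]
            parts.append(bg)
            start = pos + background_len + 1
            taxon_coords.append((start, start + len(b) - 1))
            parts.append("".join(copy))
            pos = start + len(b) - 1
        parts.append(_sample_bases(freqs, background_len, rng))
        regions[f"taxon{t + 1}"] = "".join(parts)
        if t == 0:
            coords = taxon_coords
    return regions, coords


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures

def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the small deterministic fixture files used by the test suite."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    small = SimulationConfig(n_taxa=2, seed=seed, scale=0.12,
                             atrich=AtRichPlan(length=420,
                                               repeat_unit_length=30,
                                               repeat_copies=3.0,
                                               conserved_len_range=(16, 24)))
    genomes, truth = simulate_genomes(small)
    paths["toy"] = out / "toy.gb"
    write_genbank(genomes[0], paths["toy"])
    paths["toy_truth"] = out / "toy_truth.json"
    truth.to_json(paths["toy_truth"])

    five = SimulationConfig(n_taxa=5, seed=seed + 1, scale=1.0)
    genomes5, truth5 = simulate_genomes(five)
    fdir = out / "five_taxa"
    fdir.mkdir(exist_ok=True)
    for g in genomes5:
        write_genbank(g, fdir / f"{g.id}.gb")
    truth5.to_json(fdir / "truth.json")
    paths["five_taxa"] = fdir

    rng = np.random.default_rng(seed + 2)
    plan = AtRichPlan(length=900, repeat_unit_length=144, repeat_copies=3.6)
    region, elements = build_atrich_region(plan, five.atrich_freqs, rng)
    paths["repeat_region"] = out / "repeat_region.fasta"
    with open(paths["repeat_region"], "w") as fh:
        fh.write(">repeat_region\n" + region + "\n")
    with open(out / "repeat_region_elements.json", "w") as fh:
        json.dump(elements, fh, indent=1)
    return paths
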