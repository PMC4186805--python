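"""Reading, writing and slicing of annotated mitochondrial genomes.

Coordinates are 1-based inclusive throughout (GenBank convention).  A feature
whose ``start`` is greater than its ``end`` wraps the origin of a circular
genome.  The majority coding strand is called ``J`` and corresponds to the
plus strand of the stored sequence; the minority strand is ``N``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "AnnotatedGenome",
    "OverlapRecord",
    "StartStopRecord",
    "GenomeIOError",
    "canonical_gene_name",
    "read_genbank",
    "write_genbank",
    "read_feature_table",
    "write_feature_table",
    "extract_gene",
    "find_overlaps",
    "start_stop_table",
    "rotate_genome",
    "reverse_complement",
    "genome_summary",
    "ANCESTRAL_GENE_ORDER",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
]


class GenomeIOError(ValueError):
    """Raised for malformed genomes, unresolvable gene names or bad slices."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


PCG_NAMES = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)
RRNA_NAMES = ("rrnL", "rrnS")
TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR", "trnS1",
    "trnS2", "trnT", "trnV", "trnW", "trnY",
)

#: the putative ancestral insect arrangement: (name, strand) in genome order,
#: 23 genes on J and 14 on N, AT_rich between rrnS and trnI
ANCESTRAL_GENE_ORDER = (
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"), ("trnW", "J"),
    ("trnC", "N"), ("trnY", "N"), ("cox1", "J"), ("trnL2", "J"), ("cox2", "J"),
    ("trnK", "J"), ("trnD", "J"), ("atp8", "J"), ("atp6", "J"), ("cox3", "J"),
    ("trnG", "J"), ("nad3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("nad5", "N"), ("trnH", "N"),
    ("nad4", "N"), ("nad4l", "N"), ("trnT", "J"), ("trnP", "N"), ("nad6", "J"),
    ("cytb", "J"), ("trnS2", "J"), ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"),
    ("trnV", "N"), ("rrnS", "N"), ("AT_rich", "J"),
)


@dataclass(frozen=True)
class GeneFeature:
    """A located gene on a genome.

    ``start > end`` denotes a feature wrapping the origin of a circular
    sequence.
    """

    name: str
    kind: str  # PCG | tRNA | rRNA | region
    start: int
    end: int
    strand: str  # J | N

    def __post_init__(self) -> None:
        if self.kind not in ("PCG", "tRNA", "rRNA", "region"):
            raise GenomeIOError(f"bad feature kind {self.kind!r}")
        if self.strand not in ("J", "N"):
            raise GenomeIOError(f"bad strand {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise GenomeIOError(f"{self.name}: coordinates must be >= 1")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Circular (or linear) DNA sequence plus typed gene features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    taxon: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise GenomeIOError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise GenomeIOError(
                f"{self.id}: non-nucleotide characters {sorted(bad)}"
            )
        n = len(self.sequence)
        names = [f.name for f in self.features]
        dup = {x for x in names if names.count(x) > 1}
        if dup:
            raise GenomeIOError(f"{self.id}: duplicate feature names {sorted(dup)}")
        for f in self.features:
            if f.start > n or f.end > n:
                raise GenomeIOError(
                    f"{self.id}: feature {f.name} outside [1, {n}]"
                )
            if f.wraps and not self.circular:
                raise GenomeIOError(
                    f"{self.id}: feature {f.name} wraps a linear sequence"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise GenomeIOError(f"{self.id}: unknown gene {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]


@dataclass(frozen=True)
class OverlapRecord:
    gene_a: str
    gene_b: str
    overlap_length: int
    shared_sequence: str
    pcg_pair: bool = False


@dataclass(frozen=True)
class StartStopRecord:
    gene: str
    start_codon: str
    stop: str  # TAA/TAG, or trailing "T"/"TA"/"" for incomplete stops
    complete: bool
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# gene-name canonicalization

def _norm(raw: str) -> str:
    return re.sub(r"[\s\-_().']+", "", raw).upper()


_SYNONYMS: dict[str, str] = {}


def _add_synonyms(canonical: str, *alts: str) -> None:
    _SYNONYMS[_norm(canonical)] = canonical
    for a in alts:
        _SYNONYMS[_norm(a)] = canonical


_add_synonyms("atp6", "ATP6", "ATPASE6", "ATPASESUBUNIT6",
              "ATPSYNTHASEF0SUBUNIT6", "ATPSYNTHASEFOSUBUNIT6")
_add_synonyms("atp8", "ATP8", "ATPASE8", "ATPASESUBUNIT8",
              "ATPSYNTHASEF0SUBUNIT8", "ATPSYNTHASEFOSUBUNIT8")
_add_synonyms("cox1", "COI", "CO1", "COXI", "CYTOCHROMECOXIDASESUBUNITI",
              "CYTOCHROMECOXIDASESUBUNIT1", "CYTOCHROMEOXIDASESUBUNITI",
              "CYTOCHROMEOXIDASESUBUNIT1")
_add_synonyms("cox2", "COII", "CO2", "COXII", "CYTOCHROMECOXIDASESUBUNITII",
              "CYTOCHROMECOXIDASESUBUNIT2", "CYTOCHROMEOXIDASESUBUNITII",
              "CYTOCHROMEOXIDASESUBUNIT2")
_add_synonyms("cox3", "COIII", "CO3", "COXIII", "CYTOCHROMECOXIDASESUBUNITIII",
              "CYTOCHROMECOXIDASESUBUNIT3", "CYTOCHROMEOXIDASESUBUNITIII",
              "CYTOCHROMEOXIDASESUBUNIT3")
_add_synonyms("cytb", "COB", "CYTOCHROMEB", "CYTB", "CB",
              "CYTOCHROMEBAPOENZYME")
for _i in (1, 2, 3, 4, 5, 6):
    _add_synonyms(f"nad{_i}", f"ND{_i}", f"NADH{_i}",
                  f"NADHDEHYDROGENASESUBUNIT{_i}")
_add_synonyms("nad4l", "ND4L", "NADH4L", "NADHDEHYDROGENASESUBUNIT4L")
_add_synonyms("rrnL", "RRNL", "16S", "16SRRNA", "16SRIBOSOMALRNA", "LRRNA",
              "LARGESUBUNITRIBOSOMALRNA", "LRRNA16S", "RRN16")
_add_synonyms("rrnS", "RRNS", "12S", "12SRRNA", "12SRIBOSOMALRNA", "SRRNA",
              "SMALLSUBUNITRIBOSOMALRNA", "RRN12")
_add_synonyms("AT_rich", "ATRICH", "ATRICHREGION", "DLOOP", "CONTROLREGION",
              "CR", "PUTATIVECONTROLREGION")

_AA3 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y",
}
_TRN_SINGLE = {v: f"trn{v}" for v in "ACDEFGHIKMNPQRTVWY"}

# anticodon -> duplicate-tRNA suffix for Leu and Ser
_LEU_SER_BY_ANTICODON = {
    "TAG": "trnL1", "CAG": "trnL1",          # CUN codons
    "TAA": "trnL2", "CAA": "trnL2",          # UUR codons
    "TCT": "trnS1", "GCT": "trnS1",          # AGN codons
    "TGA": "trnS2", "AGA": "trnS2", "CGA": "trnS2",  # UCN codons
}


def canonical_gene_name(raw: str, anticodon: Optional[str] = None) -> str:
    """Map a raw gene/product label to its canonical symbol.

    Leucine and serine tRNA duplicates are disambiguated by ``anticodon``
    (DNA alphabet) or by an explicit (UUR)/(CUN)/(AGN)/(UCN) tag in the
    label; otherwise :class:`GenomeIOError` is raised for them.
    """
    key = _norm(raw)
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = re.match(r"^TRNA?([A-Z]{3})?([A-Z])?(\d)?$", key)
    tag = None
    for t in ("UUR", "CUN", "AGN", "UCN", "TAA", "TAG", "TCT", "TGA"):
        if t in key:
            tag = t
    aa = None
    m3 = re.search(r"(ALA|ARG|ASN|ASP|CYS|GLN|GLU|GLY|HIS|ILE|LEU|LYS|MET|"
                   r"PHE|PRO|SER|THR|TRP|TYR|VAL)", key)
    if key.startswith("TRN") or key.startswith("TRNA"):
        if m3:
            aa = _AA3[m3.group(1)]
        elif m and m.group(2):
            aa = m.group(2)
        elif re.match(r"^TRNA?([A-Z])\d?$", key):
            aa = re.match(r"^TRNA?([A-Z])\d?$", key).group(1)
        if aa in ("L", "S"):
            num = re.search(r"(\d)", key)
            if num:
                return f"trn{aa}{num.group(1)}"
            if tag in ("UUR", "TAA"):
                return "trnL2"
            if tag in ("CUN", "TAG"):
                return "trnL1"
            if tag in ("AGN", "TCT"):
                return "trnS1"
            if tag in ("UCN", "TGA"):
                return "trnS2"
            if anticodon:
                ac = _norm(anticodon).replace("U", "T")
                if ac in _LEU_SER_BY_ANTICODON:
                    return _LEU_SER_BY_ANTICODON[ac]
            raise GenomeIOError(
                f"ambiguous Leu/Ser tRNA name {raw!r}: anticodon required"
            )
        if aa in _TRN_SINGLE:
            return _TRN_SINGLE[aa]
    raise GenomeIOError(f"cannot canonicalize gene name {raw!r}")


def _kind_for(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name in TRNA_NAMES:
        return "tRNA"
    return "region"


# ---------------------------------------------------------------------------
# slicing helpers

def _slice(genome: AnnotatedGenome, start: int, end: int) -> str:
    """1-based inclusive slice; start > end wraps the origin."""
    s = genome.sequence
    if start <= end:
        return s[start - 1:end]
    if not genome.circular:
        raise GenomeIOError(f"{genome.id}: wrapping slice on linear sequence")
    return s[start - 1:] + s[:end]


def extract_gene(genome: AnnotatedGenome, name: str) -> str:
    """Return a feature's sequence 5'->3' in coding orientation."""
    f = genome.feature(name)
    seq = _slice(genome, f.start, f.end)
    if f.strand == "N":
        seq = reverse_complement(seq)
    return seq


def rotate_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate a circular genome so old position ``offset + 1`` becomes 1."""
    if not genome.circular:
        raise GenomeIOError(f"{genome.id}: cannot rotate a linear genome")
    n = len(genome.sequence)
    offset %= n

    def shift(pos: int) -> int:
        return (pos - 1 - offset) % n + 1

    feats = [replace(f, start=shift(f.start), end=shift(f.end))
             for f in genome.features]
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    return AnnotatedGenome(genome.id, seq, True, feats, genome.taxon)


# ---------------------------------------------------------------------------
# GenBank and feature-table I/O

def _feature_from_biopython(feat: SeqFeature, seqlen: int) -> Optional[GeneFeature]:
    kinds = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
             "misc_feature": "region", "D-loop": "region"}
    if feat.type not in kinds:
        return None
    quals = feat.qualifiers
    label = None
    for q in ("gene", "product", "note", "standard_name"):
        if q in quals and quals[q]:
            label = quals[q][0]
            break
    if feat.type == "D-loop" and label is None:
        label = "AT_rich"
    if label is None:
        raise GenomeIOError(f"unnamed {feat.type} feature at {feat.location}")
    anticodon = None
    if quals.get("anticodon"):
        m = re.search(r"seq\s*:\s*([acgtu]+)", quals["anticodon"][0], re.I)
        anticodon = m.group(1) if m else quals["anticodon"][0]
    try:
        name = canonical_gene_name(label, anticodon=anticodon)
    except GenomeIOError:
        if feat.type == "misc_feature":
            return None  # unrecognized misc features are ignored
        raise
    strand = "N" if feat.location.strand == -1 else "J"
    parts = feat.location.parts
    if len(parts) == 1:
        start, end = int(parts[0].start) + 1, int(parts[0].end)
    else:
        # origin-spanning join(a..L, 1..b)
        parts = sorted(parts, key=lambda p: int(p.start))
        start, end = int(parts[-1].start) + 1, int(parts[0].end)
    kind = kinds[feat.type]
    return GeneFeature(name, kind, start, end, strand)


def _infer_at_rich(genome: AnnotatedGenome) -> Optional[GeneFeature]:
    """The non-coding stretch bounded by rrnS end and trnI start."""
    try:
        rrns = genome.feature("rrnS")
        trni = genome.feature("trnI")
    except GenomeIOError:
        return None
    n = len(genome.sequence)
    gap = (trni.start - rrns.end - 1) % n
    if gap == 0:
        return None
    start = rrns.end % n + 1
    end = (rrns.end + gap - 1) % n + 1
    return GeneFeature("AT_rich", "region", start, end, "J")


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    All gene names are canonicalized; an unannotated AT-rich region is
    inferred as the gap between rrnS and trnI.  Unresolvable CDS/tRNA/rRNA
    names raise :class:`GenomeIOError` listing the offending label.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    circular = record.annotations.get("topology", "circular") == "circular"
    feats: list[GeneFeature] = []
    errors: list[str] = []
    for bf in record.features:
        try:
            f = _feature_from_biopython(bf, len(seq))
        except GenomeIOError as exc:
            errors.append(str(exc))
            continue
        if f is not None and not any(x.name == f.name for x in feats):
            feats.append(f)
    if errors:
        raise GenomeIOError(
            f"{path}: unresolved features: " + "; ".join(errors)
        )
    taxon = record.annotations.get("organism", "") or ""
    genome = AnnotatedGenome(record.id or record.name, seq, circular, feats,
                             taxon=taxon)
    if not genome.has_feature("AT_rich"):
        at = _infer_at_rich(genome)
        if at is not None:
            genome.features.append(at)
    return genome


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write a genome back to a GenBank flat file (round-trip safe)."""
    n = len(genome.sequence)
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description=genome.taxon or genome.id)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    if genome.taxon:
        record.annotations["organism"] = genome.taxon
    types = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "region": "misc_feature"}
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, n, strand),
                SimpleLocation(0, f.end, strand),
            ])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        record.features.append(
            SeqFeature(loc, type=types[f.kind], qualifiers={"gene": [f.name]})
        )
    SeqIO.write([record], str(path), "genbank")


def read_feature_table(fasta_path: str | Path, table_path: str | Path) -> AnnotatedGenome:
    """Alternative input: FASTA plus a TSV of (name, kind, start, end, strand)."""
    record = SeqIO.read(str(fasta_path), "fasta")
    feats = []
    with open(table_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, kind, start, end, strand = line.split("\t")
            if name not in TRNA_NAMES + ("AT_rich",) + PCG_NAMES + RRNA_NAMES:
                name = canonical_gene_name(name)
            feats.append(GeneFeature(name, kind, int(start), int(end), strand))
    genome = AnnotatedGenome(record.id, str(record.seq), True, feats)
    if not genome.has_feature("AT_rich"):
        at = _infer_at_rich(genome)
        if at is not None:
            genome.features.append(at)
    return genome


def write_feature_table(genome: AnnotatedGenome, fasta_path: str | Path,
                        table_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i:i + 70] + "\n")
    with open(table_path, "w") as fh:
        fh.write("#name\tkind\tstart\tend\tstrand\n")
        for f in genome.features:
            fh.write(f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\n")


# ---------------------------------------------------------------------------
# overlaps and start/stop codons

def _segments(f: GeneFeature, n: int) -> list[tuple[int, int]]:
    if f.wraps:
        return [(f.start, n), (1, f.end)]
    return [(f.start, f.end)]


def find_overlaps(genome: AnnotatedGenome) -> list[OverlapRecord]:
    """All pairs of features with intersecting coordinates."""
    n = len(genome.sequence)
    out = []
    feats = genome.features
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            ov = 0
            pieces = []
            for (s1, e1) in _segments(a, n):
                for (s2, e2) in _segments(b, n):
                    lo, hi = max(s1, s2), min(e1, e2)
                    if lo <= hi:
                        ov += hi - lo + 1
                        pieces.append(genome.sequence[lo - 1:hi])
            if ov:
                out.append(OverlapRecord(
                    a.name, b.name, ov, "".join(pieces),
                    pcg_pair=(a.kind == "PCG" and b.kind == "PCG"),
                ))
    out.sort(key=lambda r: genome.feature(r.gene_a).start)
    return out


_STOPS = ("TAA", "TAG")  # invertebrate mitochondrial code: TGA is Trp


def start_stop_table(genome: AnnotatedGenome) -> list[StartStopRecord]:
    """Start codon and (complete or incomplete) stop codon for every PCG."""
    from .composition import GENETIC_CODE  # local import avoids a cycle

    out = []
    for f in genome.features_of_kind("PCG"):
        cds = extract_gene(genome, f.name)
        if len(cds) < 3:
            raise GenomeIOError(f"{genome.id}: {f.name} shorter than one codon")
        start = cds[:3]
        r = len(cds) % 3
        warnings: list[str] = []
        if r == 0 and cds[-3:] in _STOPS:
            stop, complete = cds[-3:], True
            body = cds[:-3]
        else:
            stop, complete = cds[len(cds) - r:] if r else "", False
            if not complete and r and not stop.startswith("T"):
                warnings.append(f"trailing {stop!r} is not T/TA")
            body = cds[:len(cds) - r]
        for i in range(3, len(body), 3):
            if body[i:i + 3] in _STOPS:
                warnings.append(f"internal stop at codon {i // 3 + 1}")
                break
        out.append(StartStopRecord(f.name, start, stop, complete,
                                   tuple(warnings)))
    return out


def genome_summary(genomes: Iterable[AnnotatedGenome]):
    """Per-genome summary table: id, length, gene counts and strand counts."""
    import pandas as pd

    rows = []
    for g in genomes:
        genes = [f for f in g.features if f.kind != "region"]
        rows.append({
            "id": g.id,
            "taxon": g.taxon,
            "length_bp": len(g.sequence),
            "n_genes": len(genes),
            "n_J": sum(1 for f in genes if f.strand == "J"),
            "n_N": sum(1 for f in genes if f.strand == "N"),
        })
    return pd.DataFrame(rows)
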