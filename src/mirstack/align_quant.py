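"""Tag alignment, partitioning and known-miRNA quantification.

Collapsed tags are aligned ungapped and full-length against three
references: known mRNA transcripts, known miRNA precursors, and the
genome.  Tags matching a known miRNA precursor are quantified; tags
matching only mRNA are treated as degradation products and discarded; the
remainder ("unannotated") feed novel-miRNA discovery.

Known-miRNA counting allocates each tag's reads fractionally (1/M) across
its M placements inside annotated mature-miRNA windows, and abundance is
normalised as RPM = C/(M*N) x 10^9 with C the (already 1/M-weighted)
read mass on a mature locus and N the number of genome-mapped reads in
the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .preprocess import UniqueTag

__all__ = [
    "GenomicInterval",
    "ReferenceIndex",
    "AlignmentHit",
    "MiRNAAnnotation",
    "ExpressionRecord",
    "TagPartition",
    "read_fasta",
    "reverse_complement",
    "build_index",
    "align_tags",
    "partition_tags",
    "read_mirna_gff3",
    "write_mirna_gff3",
    "count_known_mirnas",
    "rpm_normalize",
    "build_expression_matrix",
    "write_hits_bed",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    seqs: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            sid = title.split()[0]
            if sid in seqs:
                raise ValueError(f"duplicate sequence id {sid!r} in {path}")
            seqs[sid] = seq.upper()
    if not seqs:
        raise ValueError(f"empty FASTA: {path}")
    return seqs


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom and self.start <= other.start
                and other.end <= self.end)


@dataclass
class ReferenceIndex:
    """Exact k-mer seed index over a set of reference sequences."""

    name: str
    k: int
    sequences: dict[str, str]
    lookup: dict[str, list[tuple[str, int]]] = field(repr=False, default=None)

    def __post_init__(self):
        if self.lookup is None:
            self.lookup = {}
            for sid, seq in self.sequences.items():
                for off in range(len(seq) - self.k + 1):
                    kmer = seq[off:off + self.k]
                    if "N" in kmer:
                        continue
                    self.lookup.setdefault(kmer, []).append((sid, off))


def build_index(reference, k: int = 9, name: str = "ref") -> ReferenceIndex:
    """Build a seed index from a FASTA path or an ``{id: seq}`` mapping.

    ``k`` must be at least 8 and no longer than the shortest sequence; for
    1-mismatch alignment of a tag of length L the pigeonhole seeding used
    by :func:`align_tags` needs ``2*k <= L`` (k=9 covers 18 nt tags).
    """
    if not isinstance(reference, dict):
        reference = read_fasta(reference)
    if not reference:
        raise ValueError("empty reference")
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    shortest = min(len(s) for s in reference.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest reference sequence ({shortest} nt)")
    return ReferenceIndex(name=name, k=k,
                          sequences={s: q.upper() for s, q in reference.items()})


@dataclass(frozen=True)
class AlignmentHit:
    """A full-length ungapped placement of a tag on a reference."""

    tag_id: str
    interval: GenomicInterval
    mismatches: int
    multiplicity: int  # number of placements reported for this tag


def _mismatches(a: str, ref: str, start: int, max_mm: int) -> int:
    """Count substitutions of ``a`` against ``ref[start:start+len(a)]``.

    Returns ``max_mm + 1`` as soon as the budget is exceeded; 'N' never
    matches anything.
    """
    mm = 0
    for i, c in enumerate(a):
        r = ref[start + i]
        if c != r or c == "N":
            mm += 1
            if mm > max_mm:
                return mm
    return mm


def _candidate_starts(seq: str, index: ReferenceIndex, max_mm: int):
    """Yield (sid, start) candidates for full-length placements of seq."""
    k = index.k
    L = len(seq)
    out = set()
    if max_mm == 0 or 2 * k <= L:
        seeds = [(seq[:k], 0)]
        if max_mm >= 1:
            seeds.append((seq[L - k:], L - k))
        for kmer, soff in seeds:
            for sid, off in index.lookup.get(kmer, ()):
                start = off - soff
                if 0 <= start and start + L <= len(index.sequences[sid]):
                    out.add((sid, start))
    else:
        # tag too short for pigeonhole seeding: exhaustive scan
        for sid, ref in index.sequences.items():
            for start in range(len(ref) - L + 1):
                out.add((sid, start))
    return out


def align_tags(tags: Sequence[UniqueTag], index: ReferenceIndex,
               max_mismatch: int = 0) -> list[AlignmentHit]:
    """Report every full-length placement of each tag, both strands.

    Placements have at most ``max_mismatch`` substitutions (0 or 1).  Hits
    are sorted by (chrom, start, strand); tags without hits are absent.
    Each hit carries the tag's total placement count (multiplicity).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    hits_by_tag: dict[str, list] = {}
    for tag in tags:
        found = {}
        for strand, seq in (("+", tag.sequence),
                            ("-", reverse_complement(tag.sequence))):
            for sid, start in _candidate_starts(seq, index, max_mismatch):
                mm = _mismatches(seq, index.sequences[sid], start, max_mismatch)
                if mm <= max_mismatch:
                    key = (sid, start, strand)
                    found[key] = mm
        if found:
            hits_by_tag[tag.tag_id] = [
                (sid, start, strand, mm)
                for (sid, start, strand), mm in found.items()
            ]
    out: list[AlignmentHit] = []
    taglen = {t.tag_id: len(t.sequence) for t in tags}
    for tag_id, placements in hits_by_tag.items():
        mult = len(placements)
        for sid, start, strand, mm in placements:
            out.append(AlignmentHit(
                tag_id=tag_id,
                interval=GenomicInterval(sid, start, start + taglen[tag_id], strand),
                mismatches=mm,
                multiplicity=mult,
            ))
    out.sort(key=lambda h: (h.interval.chrom, h.interval.start,
                            h.interval.strand, h.tag_id))
    return out


@dataclass
class TagPartition:
    """Disjoint split of tags by reference membership.

    Precedence: a known-miRNA match outranks an mRNA match; mRNA-only tags
    are degradation products and are excluded from all downstream steps.
    """

    known_mirna_tags: list[str]
    mrna_tags: list[str]
    unannotated_tags: list[str]


def partition_tags(tags: Sequence[UniqueTag], mrna_index: ReferenceIndex,
                   mirna_index: ReferenceIndex,
                   max_mismatch: int = 0) -> TagPartition:
    """Partition tags into known-miRNA / mRNA / unannotated classes."""
    mirna_hit = {h.tag_id for h in align_tags(tags, mirna_index, max_mismatch)}
    rest = [t for t in tags if t.tag_id not in mirna_hit]
    mrna_hit = {h.tag_id for h in align_tags(rest, mrna_index, max_mismatch)}
    return TagPartition(
        known_mirna_tags=sorted(mirna_hit),
        mrna_tags=sorted(mrna_hit),
        unannotated_tags=sorted(t.tag_id for t in rest
                                if t.tag_id not in mrna_hit),
    )


@dataclass
class MiRNAAnnotation:
    """A miRNA precursor locus with its mature product intervals."""

    precursor_name: str
    precursor: GenomicInterval
    matures: list[tuple[str, GenomicInterval]]

    def __post_init__(self):
        for name, iv in self.matures:
            if not self.precursor.contains(iv) or iv.strand != self.precursor.strand:
                raise ValueError(
                    f"mature {name} not contained in precursor "
                    f"{self.precursor_name} on the same strand"
                )


def read_mirna_gff3(path) -> list[MiRNAAnnotation]:
    """Parse a miRBase-dialect GFF3 (miRNA_primary_transcript + miRNA).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Mature ``miRNA`` features are attached to their precursor via the
    ``Derives_from`` attribute.
    """
    precursors: dict[str, MiRNAAnnotation] = {}
    matures: list[tuple[str, str, GenomicInterval]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            name = a.get("Name", a.get("ID", ""))
            if ftype == "miRNA_primary_transcript":
                precursors[a.get("ID", name)] = MiRNAAnnotation(
                    precursor_name=name, precursor=iv, matures=[])
            elif ftype == "miRNA":
                matures.append((name, a.get("Derives_from", ""), iv))
    for name, parent, iv in matures:
        if parent not in precursors:
            raise ValueError(f"mature {name}: unknown precursor {parent!r}")
        ann = precursors[parent]
        ann.matures.append((name, iv))
        MiRNAAnnotation(ann.precursor_name, ann.precursor, ann.matures)
    return list(precursors.values())


def write_mirna_gff3(annotations: Iterable[MiRNAAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ann in enumerate(annotations):
            p = ann.precursor
            pid = f"MI_{i + 1}"
            fh.write("\t".join([
                p.chrom, "mirstack", "miRNA_primary_transcript",
                str(p.start + 1), str(p.end), ".", p.strand, ".",
                f"ID={pid};Name={ann.precursor_name}",
            ]) + "\n")
            for j, (name, iv) in enumerate(ann.matures):
                fh.write("\t".join([
                    iv.chrom, "mirstack", "miRNA",
                    str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                    f"ID={pid}_m{j + 1};Name={name};Derives_from={pid}",
                ]) + "\n")


@dataclass
class ExpressionRecord:
    """Raw 1/M-weighted count C and RPM for one mature miRNA in one sample."""

    mirna_name: str
    raw_count: float
    rpm: float
    sample: str


def _mature_windows(annotations: Sequence[MiRNAAnnotation],
                    upstream: int, downstream: int,
                    reference_lengths: Optional[dict[str, int]] = None):
    windows = []
    for ann in annotations:
        for name, iv in ann.matures:
            if reference_lengths is not None:
                rl = reference_lengths.get(iv.chrom)
                if rl is None or iv.end > rl:
                    raise ValueError(
                        f"annotation {name} ({iv.chrom}:{iv.start}-{iv.end}) "
                        f"falls off the reference"
                    )
            win = GenomicInterval(iv.chrom, max(0, iv.start - upstream),
                                  iv.end + downstream, iv.strand)
            windows.append((name, win))
    return windows


def count_known_mirnas(hits: Sequence[AlignmentHit],
                       annotations: Sequence[MiRNAAnnotation],
                       tag_counts: dict[str, int],
                       upstream: int = 2, downstream: int = 5,
                       reference_lengths: Optional[dict[str, int]] = None,
                       exact: bool = False) -> dict[str, float]:
    """Count reads per mature miRNA with fractional multi-map allocation.

    A placement is assigned to a mature miRNA when it lies fully within
    the window [mature.start - upstream, mature.end + downstream] on the
    same strand (the window absorbs typical isomiR end wobble).  A tag
    whose placements are assigned M times across miRNA windows contributes
    count/M per assignment, so total assigned mass equals the tag mass and
    multi-mappers are not double counted.  With ``exact=True`` counts are
    accumulated as exact rationals (used by conservation checks).
    """
    windows = _mature_windows(annotations, upstream, downstream,
                              reference_lengths)
    zero = Fraction(0) if exact else 0.0
    counts: dict[str, object] = {name: zero for name, _ in windows}
    by_tag: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_tag.setdefault(h.tag_id, []).append(h)
    for tag_id, placements in by_tag.items():
        assigned: list[str] = []
        for h in placements:
            for name, win in windows:
                if win.strand == h.interval.strand and win.contains(h.interval):
                    assigned.append(name)
        m = len(assigned)
        if m == 0:
            continue
        c = tag_counts[tag_id]
        share = Fraction(c, m) if exact else c / m
        for name in assigned:
            counts[name] += share
    return counts


def rpm_normalize(C: float, M: int, N: int, scale: float = 1e9) -> float:
    """Abundance of a miRNA locus: C/(M*N) x scale.

    C is the read mass on the locus, M a multi-mapping factor and N the
    library's genome-mapped read total.  When counts were already
    1/M-weighted at assignment time (the default pipeline), callers must
    pass M=1 -- discounting twice is an error.
    """
    if N <= 0:
        raise ValueError("N (mapped reads) must be positive")
    if M < 1:
        raise ValueError("M must be >= 1")
    if C == 0:
        return 0.0
    return C / (M * N) * scale


def build_expression_matrix(records: Sequence[ExpressionRecord],
                            value: str = "rpm",
                            sample_order: Optional[Sequence[str]] = None
                            ) -> pd.DataFrame:
    """Assemble records into a miRNA x sample matrix (missing entries 0).

    Rows are sorted by miRNA name; columns follow ``sample_order`` when
    given, else sorted sample labels.  Duplicate (miRNA, sample) records
    raise an error.
    """
    seen = set()
    for r in records:
        key = (r.mirna_name, r.sample)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
    samples = list(sample_order) if sample_order is not None else sorted(
        {r.sample for r in records})
    names = sorted({r.mirna_name for r in records})
    mat = pd.DataFrame(0.0, index=names, columns=samples)
    for r in records:
        if r.sample not in mat.columns:
            raise ValueError(f"record sample {r.sample!r} not in sample_order")
        mat.loc[r.mirna_name, r.sample] = getattr(r, value)
    mat.index.name = "mirna"
    return mat


def write_hits_bed(hits: Sequence[AlignmentHit], path) -> None:
    """Write hits as BED6 (score column = mismatches)."""
    with open(path, "w") as fh:
        for h in hits:
            iv = h.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{h.tag_id}"
                     f"\t{h.mismatches}\t{iv.strand}\n")
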