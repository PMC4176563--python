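"""Read filtration, 3' adapter trimming and collapsing into unique tags.

Raw small-RNA reads carry the insert (the ~18-26 nt small RNA) followed by
a 3' sequencing adapter.  A read is usable when it contains no 5' adapter,
no ambiguous base in the insert, no poly-A artifact, and when the 3'
adapter is recognisable either as a full read-through or as a terminal
flank of 6-18 nt of the adapter's 5' end.  Kept inserts are collapsed into
unique tags (sequence + multiplicity), the unit of all downstream work.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "RawRead",
    "FilterRuleSet",
    "FilterReport",
    "UniqueTag",
    "DISCARD_RULES",
    "read_fastq",
    "find_adapter3",
    "apply_filters",
    "collapse_reads",
    "run_preprocess",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "write_filter_report",
]

_DNA = set("ACGTN")

#: Discard rules, in the fixed order they are checked.
DISCARD_RULES = ("adapter5", "no_adapter3", "ambiguous", "polya", "length")


@dataclass
class RawRead:
    """One sequencing read: id, DNA sequence and optional phred string."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass
class FilterRuleSet:
    """Parameters of the filtration cascade.

    ``adapter3`` is required; a read is kept only when its 3' end carries
    either the full adapter (read-through) or a flank of
    ``min_adapter_flank``..``max_adapter_flank`` nt of the adapter's 5'
    end, matched exactly (``max_adapter_mismatch`` substitutions allowed,
    default 0).  The poly-A rule discards inserts that are >= 80% A overall
    or end in an A-run of ``polya_min_run`` nt or more.
    """

    adapter3: str
    adapter5: Optional[str] = None
    min_adapter_flank: int = 6
    max_adapter_flank: int = 18
    polya_min_run: int = 8
    max_ambiguous: int = 0
    min_len: int = 18
    max_len: int = 26
    max_adapter_mismatch: int = 0
    polya_frac: float = 0.8

    def __post_init__(self) -> None:
        self.adapter3 = self.adapter3.upper()
        if self.adapter5 is not None:
            self.adapter5 = self.adapter5.upper()
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")
        if self.min_adapter_flank > self.max_adapter_flank:
            raise ValueError("min_adapter_flank > max_adapter_flank")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        for name in ("min_adapter_flank", "max_adapter_flank", "polya_min_run",
                     "min_len", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterReport:
    """Per-rule read accounting for one library."""

    input_reads: int = 0
    discarded_by_rule: dict = field(
        default_factory=lambda: {r: 0 for r in DISCARD_RULES}
    )
    kept_reads: int = 0

    def check(self) -> None:
        total = self.kept_reads + sum(self.discarded_by_rule.values())
        if total != self.input_reads:
            raise AssertionError(
                f"read accounting violated: {self.input_reads} input != "
                f"{self.kept_reads} kept + {total - self.kept_reads} discarded"
            )


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed read: unique insert sequence plus its read multiplicity."""

    tag_id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


def read_fastq(path) -> Iterator[RawRead]:
    """Stream reads from a FASTQ file (FASTA accepted as a fallback).

    Records are yielded in file order.  A malformed record raises a
    ``ValueError`` naming the approximate line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "":
        return
    if first == ">":
        with open(path) as fh:
            for title, seq in SimpleFastaParser(fh):
                yield RawRead(title.split()[0], seq)
        return
    n = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as err:
                raise ValueError(
                    f"{path}: FASTQ parse error near line {4 * n + 1}: {err}"
                ) from err
            n += 1
            try:
                yield RawRead(title.split()[0], seq, qual)
            except ValueError as err:
                raise ValueError(
                    f"{path}: bad record near line {4 * (n - 1) + 1}: {err}"
                ) from err


def _matches(a: str, b: str, max_mm: int) -> bool:
    if len(a) != len(b):
        return False
    if max_mm == 0:
        return a == b
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


def find_adapter3(sequence: str, rules: FilterRuleSet) -> Optional[int]:
    """Locate the 3' adapter; return the trim position or ``None``.

    Returns the leftmost position ``p`` such that ``sequence[p:]`` either
    starts with the full adapter (read-through) or is exactly a prefix of
    the adapter of length ``min_adapter_flank``..``max_adapter_flank``.
    Absence of an adapter is a value (``None``), not an error.
    """
    seq = sequence.upper()
    adapter = rules.adapter3
    alen = len(adapter)
    mm = rules.max_adapter_mismatch
    n = len(seq)
    for p in range(n):
        tail_len = n - p
        if tail_len >= alen:
            if _matches(seq[p:p + alen], adapter, mm):
                return p
        elif rules.min_adapter_flank <= tail_len <= rules.max_adapter_flank:
            if _matches(seq[p:], adapter[:tail_len], mm):
                return p
    return None


def _is_polya(insert: str, rules: FilterRuleSet) -> bool:
    if not insert:
        return False
    n_a = insert.count("A")
    if n_a / len(insert) >= rules.polya_frac:
        return True
    run = len(insert) - len(insert.rstrip("A"))
    return run >= rules.polya_min_run


def apply_filters(read: RawRead, rules: FilterRuleSet):
    """Run the filtration cascade on one read.

    Returns ``(insert, None)`` for a kept read (``insert`` is the trimmed
    sequence) or ``(None, reason)`` with ``reason`` one of
    :data:`DISCARD_RULES`.  Rules are checked in that fixed order: 5'
    adapter contamination, missing 3' adapter, ambiguous bases, poly-A
    artifact, insert length window.
    """
    seq = read.sequence
    if rules.adapter5:
        idx = seq.find(rules.adapter5)
        if 0 <= idx < rules.max_adapter_flank:
            return None, "adapter5"
    p = find_adapter3(seq, rules)
    if p is None:
        return None, "no_adapter3"
    insert = seq[:p]
    ambiguous = sum(1 for c in insert if c not in "ACGT")
    if ambiguous > rules.max_ambiguous:
        return None, "ambiguous"
    if _is_polya(insert, rules):
        return None, "polya"
    if not (rules.min_len <= len(insert) <= rules.max_len):
        return None, "length"
    return insert, None


def collapse_reads(sequences: Iterable[str]) -> list[UniqueTag]:
    """Collapse identical sequences into unique tags.

    Tags are ordered by count descending then sequence, and numbered
    ``t1``, ``t2``, ...  The result is independent of input order.
    """
    counts = Counter(sequences)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        UniqueTag(tag_id=f"t{i + 1}", sequence=seq, count=c)
        for i, (seq, c) in enumerate(ordered)
    ]


def run_preprocess(reads: Iterable[RawRead],
                   rules: FilterRuleSet) -> tuple[list[UniqueTag], FilterReport]:
    """Filter and collapse a read stream; returns tags plus the accounting."""
    report = FilterReport()
    kept: list[str] = []
    for read in reads:
        report.input_reads += 1
        insert, reason = apply_filters(read, rules)
        if reason is not None:
            report.discarded_by_rule[reason] += 1
        else:
            kept.append(insert)
            report.kept_reads += 1
    report.check()
    tags = collapse_reads(kept)
    assert sum(t.count for t in tags) == report.kept_reads
    return tags, report


def write_collapsed_fasta(tags: Iterable[UniqueTag], path) -> None:
    """Write tags as FASTA with ``>tagid_xCOUNT`` headers."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f">{t.tag_id}_x{t.count}\n{t.sequence}\n")


def read_collapsed_fasta(path) -> list[UniqueTag]:
    tags = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            tag_id, _, count = title.rpartition("_x")
            tags.append(UniqueTag(tag_id, seq.upper(), int(count)))
    return tags


def write_filter_report(report: FilterReport, path) -> None:
    """Write the per-rule accounting as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("rule\treads\n")
        fh.write(f"input\t{report.input_reads}\n")
        for rule in DISCARD_RULES:
            fh.write(f"discarded_{rule}\t{report.discarded_by_rule[rule]}\n")
        fh.write(f"kept\t{report.kept_reads}\n")
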