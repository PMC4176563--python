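"""Consensus novel-miRNA discovery from unannotated genomic read stacks.

Unannotated tags that align to the genome are clustered into read stacks;
around each stack's dominant read two candidate precursor windows are
excised (one assuming the dominant product comes from the 5' arm, one
from the 3' arm).  Each window is folded with a maximum-weight
base-pairing dynamic program, the stack is partitioned into
mature/star/loop evidence against the fold, and two independent
predictors — a weighted additive scorer and a hard rule filter — are
applied.  Candidates accepted by BOTH predictors are consensus novel
miRNAs, merged across overlapping windows and provisionally named
miR-N1, miR-N2, ... in genome order.

The folding model maximises a weighted pair count (GC=3, AU=2, GU=1,
minimum hairpin loop 3 nt, no pseudoknots).  It is not a thermodynamic
MFE folder: the weighted objective admits an exact brute-force oracle by
structure enumeration at small lengths, which pins down every fold the
tests assert.  A thermodynamic folder can be swapped in through the
``folder`` hook of :func:`evaluate_window` for cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .align_quant import AlignmentHit, GenomicInterval, reverse_complement

__all__ = [
    "ReadStack",
    "HairpinFold",
    "PrecursorCandidate",
    "NovelCall",
    "ScoreWeights",
    "RuleThresholds",
    "cluster_stacks",
    "excise_windows",
    "fold_hairpin",
    "partition_stack",
    "score_candidate_A",
    "rule_filter_B",
    "evaluate_window",
    "consensus_and_name",
    "write_novel_gff3",
    "write_structures",
]

#: weighted pairing scores: Watson-Crick strong/weak plus GU wobble
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

MIN_LOOP = 3  # minimum unpaired nucleotides closed by any pair


@dataclass
class ReadStack:
    """Same-strand tag placements clustered into one genomic pile."""

    locus: GenomicInterval
    placements: list[tuple[str, GenomicInterval, int]]
    total_count: int


def cluster_stacks(hits: Sequence[AlignmentHit], tag_counts: dict[str, int],
                   max_gap: int = 30) -> list[ReadStack]:
    """Single-linkage clustering of placements along each (chrom, strand).

    Two placements join the same stack when the gap between them is at
    most ``max_gap`` nt.  Output is ordered by (chrom, start, strand).
    """
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.interval.chrom, h.interval.strand), []).append(h)
    stacks: list[ReadStack] = []
    for (chrom, strand), hs in sorted(groups.items()):
        hs.sort(key=lambda h: (h.interval.start, h.interval.end, h.tag_id))
        current: list[AlignmentHit] = []
        cur_end = None
        for h in hs:
            if current and h.interval.start - cur_end > max_gap:
                stacks.append(_make_stack(chrom, strand, current, tag_counts))
                current = []
                cur_end = None
            current.append(h)
            cur_end = h.interval.end if cur_end is None else max(cur_end,
                                                                 h.interval.end)
        if current:
            stacks.append(_make_stack(chrom, strand, current, tag_counts))
    stacks.sort(key=lambda s: (s.locus.chrom, s.locus.start, s.locus.strand))
    return stacks


def _make_stack(chrom: str, strand: str, hs: list[AlignmentHit],
                tag_counts: dict[str, int]) -> ReadStack:
    start = min(h.interval.start for h in hs)
    end = max(h.interval.end for h in hs)
    placements = [(h.tag_id, h.interval, tag_counts[h.tag_id]) for h in hs]
    return ReadStack(
        locus=GenomicInterval(chrom, start, end, strand),
        placements=placements,
        total_count=sum(c for _, _, c in placements),
    )


def dominant_placement(stack: ReadStack) -> tuple[str, GenomicInterval, int]:
    """Highest-count placement; ties broken by leftmost start, then tag id."""
    return min(stack.placements,
               key=lambda p: (-p[2], p[1].start, p[1].end, p[0]))


def excise_windows(genome: dict[str, str], stack: ReadStack,
                   down_ext: int = 70, up_ext: int = 15,
                   min_window: int = 40):
    """Excise up to two candidate precursor windows around the dominant read.

    Window A assumes the dominant product is the 5' arm mature (extend 70
    nt downstream, 15 upstream in transcript orientation); window B the 3'
    arm (70 upstream, 15 downstream).  Windows are clipped at contig ends
    and skipped (with a reason) when shorter than ``min_window`` nt.
    Returns a list of ``(locus, window_seq, assumed_arm)`` where
    ``window_seq`` is transcript-oriented (reverse-complemented for '-').
    """
    _, dom_iv, _ = dominant_placement(stack)
    chrom_seq = genome[dom_iv.chrom]
    clen = len(chrom_seq)
    out = []
    for arm in ("5p", "3p"):
        # 5p mature: precursor extends mostly downstream of the read;
        # 3p mature: mostly upstream.  Downstream is genomic-right on '+'.
        up, down = (up_ext, down_ext) if arm == "5p" else (down_ext, up_ext)
        if dom_iv.strand == "+":
            lo, hi = dom_iv.start - up, dom_iv.end + down
        else:
            lo, hi = dom_iv.start - down, dom_iv.end + up
        lo, hi = max(0, lo), min(clen, hi)
        if hi - lo < min_window:
            continue
        locus = GenomicInterval(dom_iv.chrom, lo, hi, dom_iv.strand)
        seq = chrom_seq[lo:hi]
        if dom_iv.strand == "-":
            seq = reverse_complement(seq)
        out.append((locus, seq, arm))
    return out


@dataclass
class HairpinFold:
    """A folded sequence: structure, pairing statistics and main hairpin."""

    sequence: str          # RNA alphabet
    structure: str         # dot-bracket
    pairs: list[tuple[int, int]]
    score: int             # total weighted pairing score
    paired_bases: int      # number of base pairs
    longest_stem: int      # longest run of directly stacked pairs
    n_loops: int           # number of terminal (hairpin) loops
    loop_start: int        # main-hairpin loop, [loop_start, loop_end)
    loop_end: int
    loop_size: int
    is_hairpin: bool       # structure has a single terminal loop
    pair_map: dict[int, int] = field(repr=False, default_factory=dict)


def _to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def fold_hairpin(seq: str) -> HairpinFold:
    """Fold by maximum-weight non-crossing base pairing.

    Dynamic program over intervals with minimum loop separation
    :data:`MIN_LOOP`; pair weights from :data:`PAIR_WEIGHTS` (N is
    unpairable).  The traceback is deterministic: on score ties, pairing
    the left end is preferred over leaving it unpaired, and its partner is
    taken as far right as possible.  Reports the dot-bracket, the weighted
    score, the longest stacked helix, and the terminal loop of the
    highest-scoring hairpin branch.
    """
    rna = _to_rna(seq)
    n = len(rna)
    w = [[0] * n for _ in range(n)]
    for i in range(n - 1):
        for j in range(i + 1, n):
            w[i][j] = PAIR_WEIGHTS.get((rna[i], rna[j]), 0)

    # W[i][j] = best score of substring i..j inclusive
    W = [[0] * (n + 1) for _ in range(n + 1)]

    def get(i: int, j: int) -> int:
        return W[i][j] if i <= j else 0

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = get(i + 1, j)  # i unpaired
            row = w[i]
            for k in range(i + MIN_LOOP + 1, j + 1):
                wk = row[k]
                if wk:
                    s = wk + get(i + 1, k - 1) + get(k + 1, j)
                    if s > best:
                        best = s
            W[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or W[i][j] == 0:
            continue
        target = W[i][j]
        # prefer pairing i, with the rightmost partner, over leaving i free
        chosen = None
        for k in range(j, i + MIN_LOOP, -1):
            wk = w[i][k]
            if wk and wk + get(i + 1, k - 1) + get(k + 1, j) == target:
                chosen = k
                break
        if chosen is not None:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    pairs.sort()

    structure = ["."] * n
    pair_map: dict[int, int] = {}
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
        pair_map[i] = j
        pair_map[j] = i

    pair_set = set(pairs)
    longest = run = 0
    for i, j in pairs:
        run = run + 1 if (i - 1, j + 1) in pair_set else 1
        longest = max(longest, run)

    # terminal (hairpin) loops: pairs enclosing no other pair
    hairpin_pairs = [(i, j) for i, j in pairs
                     if not any(i < a and b < j for a, b in pairs)]
    # score of each hairpin branch: walk outward through exclusively
    # enclosing pairs that close no other branch
    best_loop = (-1, 0, 0)  # (branch score, loop bounds)
    for i, j in hairpin_pairs:
        branch = 0
        a, b = i, j
        while True:
            branch += PAIR_WEIGHTS.get((rna[a], rna[b]), 0)
            enclosing = [(x, y) for x, y in pairs if x < a and b < y]
            if not enclosing:
                break
            x, y = max(enclosing)  # immediate (innermost) enclosing pair
            inside = [(p, q) for p, q in pairs if x < p and q < y]
            # stop if the enclosing pair closes more than this branch
            if any(q < a or p > b for p, q in inside):
                break
            a, b = x, y
        if branch > best_loop[0]:
            best_loop = (branch, i, j)

    if hairpin_pairs:
        _, li, lj = best_loop
        loop_start, loop_end = li + 1, lj
        loop_size = lj - li - 1
    else:
        loop_start = loop_end = loop_size = 0

    return HairpinFold(
        sequence=rna,
        structure="".join(structure),
        pairs=pairs,
        score=W[0][n - 1] if n else 0,
        paired_bases=len(pairs),
        longest_stem=longest,
        n_loops=len(hairpin_pairs),
        loop_start=loop_start,
        loop_end=loop_end,
        loop_size=loop_size,
        is_hairpin=len(hairpin_pairs) == 1,
        pair_map=pair_map,
    )


@dataclass
class PrecursorCandidate:
    """An excised window with its fold and partitioned read evidence.

    Intervals are in genomic coordinates; counts partition the stack reads
    that fall fully inside the window.
    """

    locus: GenomicInterval
    window_seq: str
    fold: HairpinFold
    mature_arm: str
    mature_interval: GenomicInterval
    star_interval: Optional[GenomicInterval]
    loop_interval: Optional[GenomicInterval]
    mature_count: int
    star_count: int
    loop_count: int
    inconsistent_count: int

    @property
    def total_in_window(self) -> int:
        return (self.mature_count + self.star_count + self.loop_count
                + self.inconsistent_count)

    @property
    def consistent_fraction(self) -> float:
        t = self.total_in_window
        return 0.0 if t == 0 else (t - self.inconsistent_count) / t

    @property
    def inconsistent_fraction(self) -> float:
        t = self.total_in_window
        return 0.0 if t == 0 else self.inconsistent_count / t


def _to_window_coords(iv: GenomicInterval, locus: GenomicInterval):
    """Map a genomic interval into transcript-oriented window coordinates."""
    if iv.chrom != locus.chrom:
        return None
    if locus.strand == "+":
        return iv.start - locus.start, iv.end - locus.start
    return locus.end - iv.end, locus.end - iv.start


def _to_genomic(lo: int, hi: int, locus: GenomicInterval) -> GenomicInterval:
    lo = max(0, lo)
    hi = min(len(locus), hi)
    if locus.strand == "+":
        return GenomicInterval(locus.chrom, locus.start + lo,
                               locus.start + hi, "+")
    return GenomicInterval(locus.chrom, locus.end - hi, locus.end - lo, "-")


def partition_stack(fold: HairpinFold, stack: ReadStack,
                    locus: GenomicInterval,
                    span_frac: float = 0.8) -> PrecursorCandidate:
    """Partition stack reads into mature / star / loop / inconsistent.

    The mature product is the dominant read.  The star interval is the
    region pairing with the mature across the stem, shifted 2 nt toward
    its 3' end (the Dicer two-nucleotide 3' overhang); the loop is the
    region between the two arms.  A placement is assigned to the category
    containing at least ``span_frac`` of its span; anything else (and any
    read straddling the loop centre) is inconsistent.  Only placements
    fully inside the window are considered.
    """
    wlen = len(locus)
    _, dom_iv, _ = dominant_placement(stack)
    mw = _to_window_coords(dom_iv, locus)
    ms, me = max(0, mw[0]), min(wlen, mw[1])

    # star = partner span of the mature across the stem, shifted 2 nt 3'
    # of the star arm.  Only partners beyond the mature on the loop side
    # count: stray local pairs next to the mature would otherwise smear
    # the star interval across the whole window.
    partners = [fold.pair_map[x] for x in range(ms, me) if x in fold.pair_map]
    partners = [p for p in partners if p >= me or p < ms]
    right = [p for p in partners if p >= me]
    left = [p for p in partners if p < ms]
    partners = right if len(right) >= len(left) else left
    star_w = None
    if partners:
        lo, hi = min(partners), max(partners) + 1
        shift = 2 if lo >= me else -2  # star right of mature -> 3' is right
        star_w = (max(0, lo + shift), min(wlen, hi + shift))
        if star_w[0] >= star_w[1]:
            star_w = None

    loop_w = None
    if star_w is not None:
        if star_w[0] >= me:
            loop_w = (me, star_w[0])
        elif star_w[1] <= ms:
            loop_w = (star_w[1], ms)
        if loop_w is not None and loop_w[0] >= loop_w[1]:
            loop_w = None
    elif fold.n_loops >= 1:
        loop_w = (fold.loop_start, fold.loop_end)

    mature_arm = "5p" if (ms + me) / 2 <= (fold.loop_start
                                           + fold.loop_end) / 2 else "3p"

    def frac_in(span, region):
        if region is None:
            return 0.0
        a, b = span
        lo, hi = region
        ov = max(0, min(b, hi) - max(a, lo))
        return ov / (b - a)

    mature_n = star_n = loop_n = incons_n = 0
    for tag_id, iv, count in stack.placements:
        wcoords = _to_window_coords(iv, locus)
        if wcoords is None or wcoords[0] < 0 or wcoords[1] > wlen:
            continue  # outside the window: not evidence for this candidate
        if frac_in(wcoords, (ms, me)) >= span_frac:
            mature_n += count
        elif frac_in(wcoords, star_w) >= span_frac:
            star_n += count
        elif frac_in(wcoords, loop_w) >= span_frac:
            loop_n += count
        else:
            incons_n += count

    return PrecursorCandidate(
        locus=locus,
        window_seq=fold.sequence,
        fold=fold,
        mature_arm=mature_arm,
        mature_interval=_to_genomic(ms, me, locus),
        star_interval=(_to_genomic(*star_w, locus) if star_w else None),
        loop_interval=(_to_genomic(*loop_w, locus) if loop_w else None),
        mature_count=mature_n,
        star_count=star_n,
        loop_count=loop_n,
        inconsistent_count=incons_n,
    )


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the additive probabilistic-style predictor (predictor A)."""

    w_mature: float = 2.0      # x log2(1 + mature reads)
    w_consistent: float = 4.0  # x fraction of reads consistent with processing
    w_fold: float = 10.0       # x fold score per window nucleotide
    w_star: float = 3.0        # bonus when star reads are observed
    w_inconsistent: float = 6.0  # penalty x inconsistent fraction
    threshold: float = 5.0


def score_candidate_A(candidate: PrecursorCandidate,
                      weights: ScoreWeights = ScoreWeights()
                      ) -> tuple[float, bool]:
    """Additive evidence score (predictor A) and its pass verdict."""
    wlen = max(1, len(candidate.locus))
    score = (
        weights.w_mature * math.log2(1 + candidate.mature_count)
        + weights.w_consistent * candidate.consistent_fraction
        + weights.w_fold * (candidate.fold.score / wlen)
        + weights.w_star * (1.0 if candidate.star_count > 0 else 0.0)
        - weights.w_inconsistent * candidate.inconsistent_fraction
    )
    return score, score >= weights.threshold


@dataclass(frozen=True)
class RuleThresholds:
    """Hard structural/expression rules (predictor B)."""

    mature_min_len: int = 18
    mature_max_len: int = 26
    min_stem: int = 14           # bp, longest stacked helix
    min_loop: int = 3            # nt, terminal loop
    max_loop: int = 20
    min_fold_density: float = 0.25  # fold score per window nt
    min_mature_count: int = 5
    max_inconsistent_fraction: float = 0.2
    max_loop_overlap: int = 2    # nt of mature allowed inside the loop


def rule_filter_B(candidate: PrecursorCandidate,
                  rules: RuleThresholds = RuleThresholds()) -> bool:
    """Rule-based predictor: all structural and expression rules must hold."""
    mlen = len(candidate.mature_interval)
    if not (rules.mature_min_len <= mlen <= rules.mature_max_len):
        return False
    # mature on one arm: at most max_loop_overlap nt inside the terminal
    # loop (maximum-pairing folds can slide the innermost pair by 1-2 nt)
    mw = _to_window_coords(candidate.mature_interval, candidate.locus)
    if candidate.fold.n_loops >= 1:
        ov = (min(mw[1], candidate.fold.loop_end)
              - max(mw[0], candidate.fold.loop_start))
        if ov > rules.max_loop_overlap:
            return False
    if candidate.fold.longest_stem < rules.min_stem:
        return False
    if not (rules.min_loop <= candidate.fold.loop_size <= rules.max_loop):
        return False
    wlen = max(1, len(candidate.locus))
    if candidate.fold.score / wlen < rules.min_fold_density:
        return False
    if candidate.mature_count < rules.min_mature_count:
        return False
    if candidate.inconsistent_fraction > rules.max_inconsistent_fraction:
        return False
    return True


@dataclass
class NovelCall:
    """A candidate with both predictor verdicts and its provisional name."""

    candidate: PrecursorCandidate
    scoreA: float
    passA: bool
    passB: bool
    consensus: bool
    name: str = ""

    @property
    def product_names(self) -> list[str]:
        names = [f"{self.name}-{self.candidate.mature_arm}"]
        if self.candidate.star_interval is not None:
            other = "3p" if self.candidate.mature_arm == "5p" else "5p"
            names.append(f"{self.name}-{other}")
        return names


def evaluate_window(stack: ReadStack, locus: GenomicInterval, window_seq: str,
                    weights: ScoreWeights = ScoreWeights(),
                    rules: RuleThresholds = RuleThresholds(),
                    folder: Callable[[str], HairpinFold] = fold_hairpin
                    ) -> NovelCall:
    """Fold one excised window, partition the stack, run both predictors."""
    fold = folder(window_seq)
    candidate = partition_stack(fold, stack, locus)
    scoreA, passA = score_candidate_A(candidate, weights)
    passB = rule_filter_B(candidate, rules)
    return NovelCall(candidate=candidate, scoreA=scoreA, passA=passA,
                     passB=passB, consensus=passA and passB)


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap(b)
    if ov == 0 or a.strand != b.strand:
        return 0.0
    return min(ov / len(a), ov / len(b))


def consensus_and_name(calls: Sequence[NovelCall],
                       min_reciprocal_overlap: float = 0.5) -> list[NovelCall]:
    """Merge overlapping consensus calls and assign miR-N names.

    Consensus requires both predictors.  Consensus loci overlapping by at
    least ``min_reciprocal_overlap`` (reciprocal) are merged keeping the
    higher scoreA.  Survivors are named miR-N1, miR-N2, ... in genome
    order; naming is independent of input order.
    """
    consensus = [c for c in calls if c.passA and c.passB]
    consensus.sort(key=lambda c: (-c.scoreA, c.candidate.locus))
    kept: list[NovelCall] = []
    for call in consensus:
        if any(_reciprocal_overlap(call.candidate.locus, k.candidate.locus)
               >= min_reciprocal_overlap for k in kept):
            continue
        kept.append(call)
    kept.sort(key=lambda c: c.candidate.locus)
    for i, call in enumerate(kept):
        call.name = f"miR-N{i + 1}"
        call.consensus = True
    return kept


def write_novel_gff3(calls: Sequence[NovelCall], path) -> None:
    """Write consensus calls as GFF3 (precursor + mature features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for call in calls:
            c = call.candidate
            iv = c.locus
            fh.write("\t".join([
                iv.chrom, "mirstack", "miRNA_primary_transcript",
                str(iv.start + 1), str(iv.end), f"{call.scoreA:.3f}",
                iv.strand, ".",
                f"ID={call.name};Name={call.name};scoreA={call.scoreA:.3f}",
            ]) + "\n")
            m = c.mature_interval
            fh.write("\t".join([
                m.chrom, "mirstack", "miRNA", str(m.start + 1), str(m.end),
                ".", m.strand, ".",
                f"ID={call.name}-{c.mature_arm};"
                f"Name={call.name}-{c.mature_arm};Derives_from={call.name}",
            ]) + "\n")
            if c.star_interval is not None:
                s = c.star_interval
                arm = "3p" if c.mature_arm == "5p" else "5p"
                fh.write("\t".join([
                    s.chrom, "mirstack", "miRNA", str(s.start + 1),
                    str(s.end), ".", s.strand, ".",
                    f"ID={call.name}-{arm};Name={call.name}-{arm};"
                    f"Derives_from={call.name}",
                ]) + "\n")


def write_structures(calls: Sequence[NovelCall], path) -> None:
    """Write each call's sequence and dot-bracket structure as plain text."""
    with open(path, "w") as fh:
        for call in calls:
            fh.write(f">{call.name} scoreA={call.scoreA:.3f} "
                     f"arm={call.candidate.mature_arm}\n")
            fh.write(call.candidate.window_seq + "\n")
            fh.write(call.candidate.fold.structure + "\n")
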