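"""Stack clustering, hairpin folding, read partitioning and consensus calls."""

import random

import pytest

from mirstack.align_quant import AlignmentHit, GenomicInterval, \
    reverse_complement
from mirstack.novel_discovery import (PAIR_WEIGHTS, HairpinFold,
                                      PrecursorCandidate,
                                      ScoreWeights, cluster_stacks,
                                      consensus_and_name, evaluate_window,
                                      excise_windows, fold_hairpin,
                                      partition_stack, rule_filter_B,
                                      score_candidate_A, NovelCall, ReadStack)
from mirstack.synthetic_data import make_hairpin


def enumerate_all_structures(seq, i, j):
    """Yield every valid non-crossing pair set of seq[i..j] (min loop 3)."""
    if i >= j:
        yield frozenset()
        return
    yield from enumerate_all_structures(seq, i + 1, j)
    for k in range(i + 4, j + 1):
        if (seq[i], seq[k]) in PAIR_WEIGHTS:
            for left in enumerate_all_structures(seq, i + 1, k - 1):
                for right in enumerate_all_structures(seq, k + 1, j):
                    yield left | right | {(i, k)}


def brute_force_max_score(seq):
    """Independent folding oracle: exhaustive structure enumeration."""
    rna = seq.upper().replace("T", "U")
    return max(
        (sum(PAIR_WEIGHTS[(rna[a], rna[b])] for a, b in s)
         for s in enumerate_all_structures(rna, 0, len(rna) - 1)),
        default=0)


class TestFoldHairpin:
    def test_perfect_gc_hairpin(self):
        f = fold_hairpin("GGGAAAACCC")
        assert f.structure == "(((....)))"
        assert f.paired_bases == 3
        assert f.score == 9
        assert f.loop_size == 4
        assert f.is_hairpin

    def test_unpairable_sequence(self):
        f = fold_hairpin("AAAAAAAAAA")
        assert f.score == 0 and f.paired_bases == 0
        assert f.structure == "." * 10

    def test_dp_equals_enumeration_on_random_sequences(self):
        rng = random.Random(123)
        for _ in range(50):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(8, 14)))
            assert fold_hairpin(seq).score == brute_force_max_score(seq)

    def test_structure_is_well_formed(self):
        rng = random.Random(5)
        for _ in range(50):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(10, 40)))
            f = fold_hairpin(seq)
            depth = 0
            for c in f.structure:
                depth += {"(": 1, ")": -1}.get(c, 0)
                assert depth >= 0
            assert depth == 0
            for i, j in f.pairs:
                assert j - i > 3, "minimum loop separation violated"
                assert (f.sequence[i], f.sequence[j]) in PAIR_WEIGHTS
            # non-crossing
            for a, b in f.pairs:
                for c, d in f.pairs:
                    assert not (a < c < b < d)
            # reported score equals the score of the reported pairs
            assert f.score == sum(PAIR_WEIGHTS[(f.sequence[i], f.sequence[j])]
                                  for i, j in f.pairs)

    def test_n_is_unpairable(self):
        f = fold_hairpin("GGGNAAAANCCC")
        assert all("N" not in (f.sequence[i], f.sequence[j])
                   for i, j in f.pairs)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGTX")

    def test_constructed_hairpin_loop_size(self):
        rng = random.Random(9)
        core, layout = make_hairpin(rng, mature_len=22, loop_len=4, bulges=0)
        f = fold_hairpin(core)
        assert f.is_hairpin
        assert f.loop_size == 4
        assert f.longest_stem >= 22 - 2

    def test_bulged_hairpin_keeps_long_stem(self):
        rng = random.Random(10)
        for bulges in (0, 1, 2):
            core, _ = make_hairpin(rng, 22, 8, bulges)
            f = fold_hairpin(core)
            assert f.longest_stem >= 22 - bulges - 2
            assert f.loop_size == 8


def _hit(tag, start, end, strand="+", chrom="chr1"):
    return AlignmentHit(tag, GenomicInterval(chrom, start, end, strand), 0, 1)


class TestClusterStacks:
    def test_nearby_tags_merge(self):
        hits = [_hit("a", 100, 122), _hit("b", 132, 154)]
        stacks = cluster_stacks(hits, {"a": 5, "b": 3}, max_gap=30)
        assert len(stacks) == 1
        assert stacks[0].total_count == 8
        assert stacks[0].locus == GenomicInterval("chr1", 100, 154, "+")

    def test_distant_tags_split(self):
        hits = [_hit("a", 100, 122), _hit("b", 222, 244)]
        stacks = cluster_stacks(hits, {"a": 5, "b": 3}, max_gap=30)
        assert len(stacks) == 2

    def test_strands_never_merge(self):
        hits = [_hit("a", 100, 122, "+"), _hit("b", 110, 132, "-")]
        assert len(cluster_stacks(hits, {"a": 1, "b": 1})) == 2

    def test_matches_single_linkage_oracle(self):
        rng = random.Random(8)
        hits = []
        counts = {}
        for i in range(200):
            start = rng.randrange(0, 20_000)
            strand = rng.choice("+-")
            hits.append(_hit(f"t{i}", start, start + 22, strand))
            counts[f"t{i}"] = rng.randint(1, 50)
        stacks = cluster_stacks(hits, counts, max_gap=30)
        # naive single-linkage: iterate merging until fixed point
        items = [(h.interval.chrom, h.interval.strand, h.interval.start,
                  h.interval.end, h.tag_id) for h in hits]
        groups = [[it] for it in items]
        merged = True
        while merged:
            merged = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if any(a[0] == b[0] and a[1] == b[1]
                           and a[2] - b[3] <= 30 and b[2] - a[3] <= 30
                           for a in groups[i] for b in groups[j]):
                        groups[i] += groups.pop(j)
                        merged = True
                        break
                if merged:
                    break
        expected = {frozenset(it[4] for it in g) for g in groups}
        got = {frozenset(p[0] for p in s.placements) for s in stacks}
        assert got == expected
        # totals conserved
        assert sum(s.total_count for s in stacks) == sum(counts.values())


class TestExciseWindows:
    def test_plus_strand_arithmetic(self):
        genome = {"chr1": "A" * 2000}
        stack = ReadStack(GenomicInterval("chr1", 1000, 1022, "+"),
                          [("t1", GenomicInterval("chr1", 1000, 1022, "+"), 9)],
                          9)
        wins = excise_windows(genome, stack)
        loci = {arm: locus for locus, _, arm in wins}
        assert (loci["5p"].start, loci["5p"].end) == (985, 1092)
        assert (loci["3p"].start, loci["3p"].end) == (930, 1037)

    def test_clipping_at_contig_start(self):
        genome = {"chr1": "A" * 300}
        stack = ReadStack(GenomicInterval("chr1", 10, 32, "+"),
                          [("t1", GenomicInterval("chr1", 10, 32, "+"), 5)], 5)
        wins = excise_windows(genome, stack)
        assert all(locus.start >= 0 for locus, _, _ in wins)
        assert all(len(locus) >= 40 for locus, _, _ in wins)

    def test_window_below_minimum_skipped(self):
        genome = {"chr1": "A" * 30}
        stack = ReadStack(GenomicInterval("chr1", 2, 24, "+"),
                          [("t1", GenomicInterval("chr1", 2, 24, "+"), 5)], 5)
        assert excise_windows(genome, stack) == []

    def test_minus_strand_window_sequence_is_transcript_oriented(self):
        rng = random.Random(4)
        g = "".join(rng.choice("ACGT") for _ in range(500))
        genome = {"chr1": g}
        stack = ReadStack(GenomicInterval("chr1", 200, 222, "-"),
                          [("t1", GenomicInterval("chr1", 200, 222, "-"), 5)],
                          5)
        for locus, seq, arm in excise_windows(genome, stack):
            assert seq == reverse_complement(g[locus.start:locus.end])


def _planted_candidate(rng_seed=1, mature_n=50, star_n=5, loop_n=0,
                       stray_n=0, arm="5p", flank=12):
    """Build a window around a constructed hairpin with a synthetic stack."""
    rng = random.Random(rng_seed)
    core, layout = make_hairpin(rng, 22, 8, bulges=1, arm=arm)
    left = "".join(rng.choice("ACGT") for _ in range(flank))
    right = "".join(rng.choice("ACGT") for _ in range(flank))
    window = left + core + right
    locus = GenomicInterval("chr1", 5000, 5000 + len(window), "+")
    off = 5000 + flank

    def iv(t_lo, t_hi):
        return GenomicInterval("chr1", off + t_lo, off + t_hi, "+")

    placements = []
    if mature_n:
        placements.append(("m", iv(*layout["mature"]), mature_n))
    if star_n:
        placements.append(("s", iv(*layout["star"]), star_n))
    if loop_n:
        lo, hi = layout["loop"]
        placements.append(("l", iv(lo, hi), loop_n))
    if stray_n:
        # a read straddling the loop centre: consistent with nothing
        mid = sum(layout["loop"]) // 2
        placements.append(("x", iv(mid - 11, mid + 11), stray_n))
    total = sum(c for _, _, c in placements)
    stack = ReadStack(locus, placements, total)
    fold = fold_hairpin(window)
    return partition_stack(fold, stack, locus), stack, locus, window


class TestPartitionStack:
    def test_arm_assignment_and_counts(self):
        cand, *_ = _planted_candidate(mature_n=50, star_n=5)
        assert cand.mature_arm == "5p"
        assert cand.mature_count == 50
        assert cand.star_count == 5
        assert cand.inconsistent_count == 0

    def test_all_reads_on_one_arm(self):
        cand, *_ = _planted_candidate(mature_n=40, star_n=0)
        assert cand.star_count == 0
        assert cand.inconsistent_count == 0

    def test_loop_spanning_read_is_inconsistent(self):
        cand, *_ = _planted_candidate(mature_n=40, star_n=4, stray_n=7)
        assert cand.inconsistent_count == 7

    def test_3p_arm_candidate(self):
        cand, *_ = _planted_candidate(arm="3p", mature_n=30, star_n=3)
        assert cand.mature_arm == "3p"
        assert cand.mature_count == 30
        assert cand.star_count == 3

    def test_counts_partition_window_reads(self):
        cand, stack, locus, _ = _planted_candidate(mature_n=20, star_n=2,
                                                   loop_n=3, stray_n=4)
        in_window = sum(
            c for _, iv, c in stack.placements
            if locus.start <= iv.start and iv.end <= locus.end)
        assert cand.total_in_window == in_window


class TestScoreA:
    def test_zero_consistent_reads_bounded_by_fold_term(self):
        # every observed read is inconsistent with hairpin processing
        cand = _manual_candidate(mature_count=0, inconsistent_count=10)
        w = ScoreWeights()
        score, passed = score_candidate_A(cand, w)
        fold_term = w.w_fold * cand.fold.score / len(cand.locus)
        assert score <= fold_term
        assert not passed

    def test_planted_candidate_passes(self):
        cand, *_ = _planted_candidate(mature_n=50, star_n=5)
        score, passed = score_candidate_A(cand)
        assert passed and score > 5

    def test_zero_weights_zero_score(self):
        cand, *_ = _planted_candidate()
        w = ScoreWeights(0, 0, 0, 0, 0, threshold=0.0)
        score, _ = score_candidate_A(cand, w)
        assert score == 0.0

    def test_monotone_in_mature_reads(self):
        scores = []
        for n in (5, 20, 80, 320):
            cand, *_ = _planted_candidate(mature_n=n, star_n=3)
            scores.append(score_candidate_A(cand)[0])
        assert scores == sorted(scores)


def _manual_candidate(**overrides):
    """A candidate with hand-set statistics for rule-boundary checks."""
    fold = HairpinFold(
        sequence="A" * 100, structure="." * 100, pairs=[],
        score=overrides.pop("fold_score", 25), paired_bases=10,
        longest_stem=overrides.pop("longest_stem", 14),
        n_loops=1, loop_start=overrides.pop("loop_start", 45),
        loop_end=overrides.pop("loop_end", 55),
        loop_size=overrides.pop("loop_size", 10), is_hairpin=True)
    defaults = dict(
        locus=GenomicInterval("chr1", 0, 100, "+"),
        window_seq="A" * 100, fold=fold, mature_arm="5p",
        mature_interval=GenomicInterval("chr1", 10, 32, "+"),
        star_interval=None, loop_interval=None,
        mature_count=5, star_count=0, loop_count=0, inconsistent_count=0)
    defaults.update(overrides)
    return PrecursorCandidate(**defaults)


class TestRuleFilterB:
    def test_boundary_candidate_passes(self):
        # every rule is met exactly at its boundary (inclusive bounds)
        cand = _manual_candidate(mature_count=8, inconsistent_count=2)
        assert cand.inconsistent_fraction == pytest.approx(0.2)
        assert rule_filter_B(cand)

    @pytest.mark.parametrize("override", [
        {"mature_interval": GenomicInterval("chr1", 10, 40, "+")},  # 30 nt
        {"longest_stem": 13},
        {"loop_size": 2},
        {"loop_size": 21},
        {"fold_score": 24},          # density below 0.25
        {"mature_count": 4},
        {"mature_count": 7, "inconsistent_count": 3},  # frac 0.3
        {"loop_start": 20, "loop_end": 40},  # mature deep inside the loop
    ])
    def test_single_rule_violations_fail(self, override):
        assert not rule_filter_B(_manual_candidate(**override))

    def test_decoy_window_fails_structural_rules(self):
        # a random (non-hairpin) window with a healthy stack still fails
        rng = random.Random(77)
        window = "".join(rng.choice("ACGT") for _ in range(100))
        locus = GenomicInterval("chr1", 0, 100, "+")
        stack = ReadStack(
            GenomicInterval("chr1", 30, 52, "+"),
            [("t", GenomicInterval("chr1", 30, 52, "+"), 50)], 50)
        fold = fold_hairpin(window)
        cand = partition_stack(fold, stack, locus)
        assert fold.longest_stem < 14
        assert not rule_filter_B(cand)


class TestConsensus:
    def _call(self, start, end, scoreA, passA=True, passB=True, strand="+"):
        cand = _manual_candidate(
            locus=GenomicInterval("chr1", start, end, strand),
            mature_interval=GenomicInterval("chr1", start + 10, start + 32,
                                            strand))
        return NovelCall(candidate=cand, scoreA=scoreA, passA=passA,
                         passB=passB, consensus=passA and passB)

    def test_consensus_requires_both_predictors(self):
        calls = [self._call(0, 100, 10, passA=True, passB=False),
                 self._call(500, 600, 10, passA=False, passB=True)]
        assert consensus_and_name(calls) == []

    def test_overlapping_calls_merge_keeping_higher_score(self):
        a = self._call(1000, 1100, scoreA=8.0)
        b = self._call(1010, 1110, scoreA=12.0)   # 90% reciprocal overlap
        named = consensus_and_name([a, b])
        assert len(named) == 1
        assert named[0].scoreA == 12.0
        assert named[0].name == "miR-N1"

    def test_names_follow_genome_order(self):
        calls = [self._call(5000, 5100, 9.0), self._call(1000, 1100, 3e1)]
        named = consensus_and_name(calls)
        assert [c.name for c in named] == ["miR-N1", "miR-N2"]
        assert named[0].candidate.locus.start == 1000

    def test_order_independence(self):
        calls = [self._call(1000, 1100, 8.0), self._call(3000, 3100, 6.0),
                 self._call(3010, 3110, 9.0), self._call(7000, 7100, 7.0)]
        n1 = consensus_and_name(calls)
        n2 = consensus_and_name(list(reversed(calls)))
        assert [(c.name, c.candidate.locus) for c in n1] \
            == [(c.name, c.candidate.locus) for c in n2]

    def test_consensus_subset_identity(self, small_sim):
        """On a full simulated run the named set derives from the
        intersection of both predictors' accepted sets."""
        novel = small_sim["results"]["novel"]
        both = {id(c) for c in novel.calls if c.passA and c.passB}
        assert all(id(c) in both for c in novel.named)
        assert len(novel.named) <= len(both)


class TestEvaluateWindow:
    def test_planted_hairpin_end_to_end(self):
        cand, stack, locus, window = _planted_candidate(mature_n=50, star_n=5)
        call = evaluate_window(stack, locus, window)
        assert call.passA and call.passB and call.consensus

    def test_custom_folder_hook(self):
        cand, stack, locus, window = _planted_candidate()
        trivial = lambda seq: HairpinFold(
            sequence=seq.replace("T", "U"), structure="." * len(seq),
            pairs=[], score=0, paired_bases=0, longest_stem=0, n_loops=0,
            loop_start=0, loop_end=0, loop_size=0, is_hairpin=False)
        call = evaluate_window(stack, locus, window, folder=trivial)
        assert not call.passB  # no structure, rule filter must reject
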