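"""Evaluation of pipeline output against simulation ground truth."""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from scipy.stats import spearmanr

from .synthetic_data import SimulatedData, TruthLocus

__all__ = [
    "novel_recovery",
    "known_rank_correlation",
]


def novel_recovery(named_calls: Sequence, data: SimulatedData,
                   min_reads: int = 10,
                   min_overlap_frac: float = 0.5) -> dict:
    """Compare consensus novel calls with the planted novel hairpins.

    A planted locus counts as recovered when some consensus call's mature
    interval overlaps the true mature by at least ``min_overlap_frac`` of
    its length on the same strand.  Calls overlapping no planted novel
    precursor at all are false calls.  Only loci with at least
    ``min_reads`` simulated reads (mature + star, all samples) are
    eligible for the recall denominator.
    """
    truth = data.truth_by_kind("novel")

    def total_reads(t: TruthLocus) -> int:
        return sum(v["mature"] + v["star"] for v in t.realized_counts.values())

    def is_recovered(t: TruthLocus) -> bool:
        return any(
            c.candidate.locus.strand == t.mature.strand
            and c.candidate.mature_interval.overlap(t.mature)
            >= min_overlap_frac * len(t.mature)
            for c in named_calls)

    eligible = [t for t in truth if total_reads(t) >= min_reads]
    recovered = [t.name for t in eligible if is_recovered(t)]
    false_calls = [
        c.name for c in named_calls
        if not any(c.candidate.locus.strand == t.precursor.strand
                   and c.candidate.locus.overlap(t.precursor) > 0
                   for t in truth)
    ]
    return {
        "eligible": [t.name for t in eligible],
        "recovered": recovered,
        "recall": (len(recovered) / len(eligible)) if eligible else float("nan"),
        "false_calls": false_calls,
    }


def known_rank_correlation(rpm_matrix: pd.DataFrame,
                           data: SimulatedData) -> dict[str, float]:
    """Spearman correlation of known-miRNA RPM vs planted profile weights.

    Matrix rows are matched to planted loci by mature name prefix
    (``miR-K<i>-``); every annotated known miRNA must be present.
    """
    mir_loci = [t for t in data.truth if t.kind in ("known", "novel")]
    by_prefix = {}
    for row in rpm_matrix.index:
        by_prefix[row.rsplit("-", 1)[0]] = row
    out = {}
    for cell in data.spec.cell_types:
        weights, rpms = [], []
        for i, t in enumerate(mir_loci):
            if t.kind != "known":
                continue
            prefix = t.name.replace("mir-", "miR-")
            row = by_prefix.get(prefix)
            if row is None:
                raise KeyError(f"no RPM row for planted miRNA {t.name}")
            weights.append(data.cell_profiles[cell][i])
            rpms.append(float(rpm_matrix.loc[row, cell]))
        out[cell] = float(spearmanr(weights, rpms).statistic)
    return out
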