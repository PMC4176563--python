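"""Expression calls, three-cell-type pattern classes and exact rank tests.

The study design compares three endothelial lineage states in a fixed
order: early EPC, late EPC, mature EC.  A miRNA is "expressed" in a cell
type when its RPM strictly exceeds a threshold (default 100).  Expressed
miRNAs are classified by fold change (default 1.5x, computed on RPM plus
a pseudocount) into monotonic increase/decrease along the lineage, a
"late EPC and EC jointly high" class, cell-type-specific classes, or
an unclassified remainder.

Group comparisons use the Mann-Whitney U test (independent groups) and
the Wilcoxon signed-rank test (paired), with exact p-values by complete
enumeration at small sample sizes and a tie/continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "PatternConfig",
    "PATTERN_CLASSES",
    "call_expressed",
    "classify_pattern",
    "classify_matrix",
    "venn_partition",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
]

PATTERN_CLASSES = (
    "monotonic_up_to_EC",
    "monotonic_down_to_EC",
    "late_and_EC_high",
    "specific_early",
    "specific_late",
    "specific_EC",
    "expressed_unclassified",
    "not_expressed",
)

_SPECIFIC = ("specific_early", "specific_late", "specific_EC")


@dataclass
class PatternConfig:
    """Thresholds of the expression-pattern classification.

    ``cell_order`` is the lineage order (early EPC, late EPC, EC); RPM
    fold changes are taken on values plus ``pseudocount`` so ratios stay
    defined at zero.
    """

    expr_threshold: float = 100.0
    fc: float = 1.5
    cell_order: tuple = ("early_EPC", "late_EPC", "EC")
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.fc <= 1:
            raise ValueError("fold change must be > 1")
        if self.expr_threshold < 0:
            raise ValueError("expr_threshold must be >= 0")
        self.cell_order = tuple(self.cell_order)
        if len(self.cell_order) != 3:
            raise ValueError("cell_order must name exactly three cell types")


def call_expressed(matrix: pd.DataFrame,
                   config: PatternConfig = PatternConfig()) -> pd.DataFrame:
    """Boolean expressed matrix: RPM strictly greater than the threshold."""
    return matrix > config.expr_threshold


def classify_pattern(rpm_triple: Sequence[float],
                     config: PatternConfig = PatternConfig()) -> str:
    """Classify one miRNA's (early, late, EC) RPM triple.

    Cell-type specificity (expressed in exactly one cell type) takes
    precedence; then monotonic up/down at >= fc per step, then the
    late/EC-jointly-high class (late vs EC within fc, both >= fc over
    early), then not-expressed, else expressed-unclassified.  Exactly one
    class is returned for every input.
    """
    early, late, ec = (float(v) for v in rpm_triple)
    if min(early, late, ec) < 0:
        raise ValueError("RPM values must be non-negative")
    thr = config.expr_threshold
    expressed = [early > thr, late > thr, ec > thr]
    if sum(expressed) == 1:
        return _SPECIFIC[expressed.index(True)]
    pc = config.pseudocount
    e, l, c = early + pc, late + pc, ec + pc
    fc = config.fc
    if c >= fc * l and l >= fc * e:
        return "monotonic_up_to_EC"
    if e >= fc * l and l >= fc * c:
        return "monotonic_down_to_EC"
    if max(l, c) / min(l, c) < fc and min(l, c) >= fc * e:
        return "late_and_EC_high"
    if not any(expressed):
        return "not_expressed"
    return "expressed_unclassified"


def classify_matrix(matrix: pd.DataFrame,
                    config: PatternConfig = PatternConfig()) -> pd.DataFrame:
    """Classify every row of a miRNA x sample RPM matrix.

    The matrix must contain the three ``config.cell_order`` columns.
    Returns a frame with the RPM triple, the two step fold changes and
    the pattern class per miRNA.
    """
    missing = [c for c in config.cell_order if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks cell-order columns: {missing}")
    sub = matrix[list(config.cell_order)]
    pc = config.pseudocount
    rows = []
    for name, row in sub.iterrows():
        early, late, ec = row.to_numpy(dtype=float)
        rows.append({
            "mirna": name,
            config.cell_order[0]: early,
            config.cell_order[1]: late,
            config.cell_order[2]: ec,
            "fc_late_vs_early": (late + pc) / (early + pc),
            "fc_EC_vs_late": (ec + pc) / (late + pc),
            "pattern": classify_pattern((early, late, ec), config),
        })
    return pd.DataFrame(rows).set_index("mirna")


def venn_partition(expressed: pd.DataFrame) -> dict[str, list]:
    """Partition row labels into the 7 regions of a three-set Venn diagram.

    ``expressed`` is a boolean matrix with exactly three columns.  Region
    keys are '&'-joined column names (e.g. ``"early_EPC&EC"``); rows
    expressed nowhere are omitted, so region sizes sum to the number of
    rows expressed in at least one column.
    """
    if expressed.shape[1] != 3:
        raise ValueError("venn_partition needs exactly three columns")
    cols = list(expressed.columns)
    regions: dict[str, list] = {}
    for r in range(1, 8):
        mask = [(r >> i) & 1 == 1 for i in range(3)]
        key = "&".join(c for c, m in zip(cols, mask) if m)
        regions[key] = []
    for name, row in expressed.iterrows():
        flags = tuple(bool(v) for v in row[cols])
        if not any(flags):
            continue
        key = "&".join(c for c, m in zip(cols, flags) if m)
        regions[key].append(name)
    return regions


def _rank_sum_stat(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum())


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_max_n: int = 10) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns (U, p) with U the statistic of ``x`` computed on midranks.
    When ``len(x) + len(y) <= exact_max_n`` the p-value is exact: every
    C(n1+n2, n1) relabelling is enumerated and p is the probability of a
    U at least as far from its null mean as observed.  Larger samples use
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2
    mean = n1 * n2 / 2
    dev = abs(u1 - mean)
    n = n1 + n2
    if n <= exact_max_n:
        count = total = 0
        base = n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(n), n1):
            u = ranks[list(idx)].sum() - base
            total += 1
            if abs(u - mean) >= dev - 1e-9:
                count += 1
        return u1, count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u1, 1.0
    z = (dev - 0.5) / math.sqrt(var)
    p = min(1.0, 2 * norm.sf(max(0.0, z)))
    return u1, p


def wilcoxon_signed_rank(x: Sequence[float], y: Optional[Sequence[float]] = None,
                         exact_max_n: int = 12) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples, two-sided.

    ``x`` may be the differences directly, or paired with ``y``.  Zero
    differences are dropped (documented standard practice).  Returns
    (W, p) with W the positive-rank sum.  For n <= ``exact_max_n`` the
    p-value is exact over all 2^n sign assignments; otherwise a
    tie/continuity-corrected normal approximation is used.  All-zero
    differences give p = 1 with a warning.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean = ranks.sum() / 2
    dev = abs(w_pos - mean)
    if n <= exact_max_n:
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mean) >= dev - 1e-9:
                count += 1
        return w_pos, count / 2 ** n
    var = float((ranks ** 2).sum()) / 4
    if var <= 0:
        return w_pos, 1.0
    z = (dev - 0.5) / math.sqrt(var)
    p = min(1.0, 2 * norm.sf(max(0.0, z)))
    return w_pos, p
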