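"""Differential TSS coverage between two cohorts.

Per TSS, a two-sided Wilcoxon rank-sum test compares the two groups'
occupancy values and a pseudocounted fold change of group means is
computed; calls require both a p-value below ``p_max`` and a fold change
beyond ``fc_min`` (symmetrically: >= fc_min or <= 1/fc_min), plus —
where a false-discovery criterion applies — a Benjamini–Hochberg q-value
below ``fdr_max``. Hierarchical clustering for heatmap ordering uses
average linkage (UPGMA) on Euclidean distances over per-feature
z-scored values.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .occupancy import OccupancyMatrix

#: pooled sample size at or below which the exact rank-sum null is used
EXACT_WILCOXON_MAX_N = 20


@dataclasses.dataclass
class AnalysisThresholds:
    """Significance thresholds for a two-group contrast.

    ``fc_min`` is the minimum fold change (e.g. 1.5 for the response
    contrasts, 1.2 for cancer-vs-healthy); ``fdr_max`` is optional and
    only applied when set (0.1 for cancer-vs-healthy). ``pseudocount``
    stabilizes the ratio of group means (RPKM units).
    """

    p_max: float = 0.01
    fc_min: float = 1.5
    fdr_max: Optional[float] = None
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ParameterError("p_max must lie in (0, 1)")
        if self.fc_min <= 1:
            raise ParameterError("fc_min must exceed 1")
        if self.fdr_max is not None and not 0 < self.fdr_max < 1:
            raise ParameterError("fdr_max must lie in (0, 1) when present")
        if self.pseudocount < 0:
            raise ParameterError("pseudocount must be >= 0")


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the pooled sample size is at
    most ``EXACT_WILCOXON_MAX_N`` and there are no ties; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction. With no rank information at all (every pooled value
    identical) the p-value is 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= EXACT_WILCOXON_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return min(1.0, float(res.pvalue))


def log_fold_change(group_a, group_b, pseudocount: float = 0.0):
    """Fold change of group means, ``(mean(a) + pc) / (mean(b) + pc)``.

    Returns ``(fold_change, log2 fold_change)``. The significance rule
    downstream compares the fold change symmetrically against
    ``fc_min`` (>= fc_min or <= 1/fc_min), which is log-base-independent.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("groups must be non-empty")
    denom = b.mean() + pseudocount
    if denom == 0:
        raise ParameterError("mean(group_b) + pseudocount is zero; ratio undefined")
    fc = (a.mean() + pseudocount) / denom
    return float(fc), float(np.log2(fc))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_call(p: float, fold_change: float, q: Optional[float],
                  thresholds: AnalysisThresholds) -> str:
    """Apply the significance rule to one TSS; returns the call label."""
    if p >= thresholds.p_max:
        return "ns"
    if thresholds.fdr_max is not None and (q is None or q >= thresholds.fdr_max):
        return "ns"
    if fold_change >= thresholds.fc_min:
        return "up_in_a"
    if fold_change <= 1.0 / thresholds.fc_min:
        return "down_in_a"
    return "ns"


def call_differential(
    occ,
    labels: Mapping,
    thresholds: AnalysisThresholds,
    group_a: Optional[str] = None,
    group_b: Optional[str] = None,
) -> pd.DataFrame:
    """Per-TSS differential table between two labeled sample groups.

    ``labels`` maps sample id -> group name; every labeled sample must
    exist in the matrix and exactly two groups must be present. Fold
    changes are group-A mean over group-B mean (group names sorted
    lexicographically unless given). Returns a DataFrame indexed by TSS
    id with columns ``p_value, fold_change, log_fc, fdr_q, call``.
    """
    df = occ.df if isinstance(occ, OccupancyMatrix) else occ
    labels = dict(labels)
    unknown = [s for s in labels if s not in df.columns]
    if unknown:
        raise ValidationError(f"labels reference unknown samples: {unknown[:3]}")
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    if group_a is None or group_b is None:
        group_a, group_b = groups
    if {group_a, group_b} != set(groups):
        raise ValidationError("group_a/group_b do not match the labels")
    cols_a = [s for s in df.columns if labels.get(s) == group_a]
    cols_b = [s for s in df.columns if labels.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ParameterError("both groups need at least 2 samples")
    A = df[cols_a].to_numpy(dtype=float)
    B = df[cols_b].to_numpy(dtype=float)
    n_tss = df.shape[0]
    p_values = np.empty(n_tss)
    fcs = np.empty(n_tss)
    for i in range(n_tss):
        p_values[i] = wilcoxon_rank_sum(A[i], B[i])
        fcs[i], _ = log_fold_change(A[i], B[i], thresholds.pseudocount)
    log_fcs = np.log2(fcs)
    if thresholds.fdr_max is not None:
        qs = benjamini_hochberg(p_values)
    else:
        qs = np.full(n_tss, np.nan)
    calls = [
        classify_call(p_values[i], fcs[i],
                      None if np.isnan(qs[i]) else qs[i], thresholds)
        for i in range(n_tss)
    ]
    return pd.DataFrame(
        {
            "p_value": p_values,
            "fold_change": fcs,
            "log_fc": log_fcs,
            "fdr_q": qs,
            "call": calls,
        },
        index=df.index,
    )


def average_linkage_order(
    matrix: pd.DataFrame, axis: str = "rows", standardize: bool = True
):
    """UPGMA leaf ordering and merge tree for heatmap layout.

    Features (rows) are z-scored across samples first (zero-variance
    rows are left at 0), then the requested axis is clustered with
    average linkage on Euclidean distance. Returns ``(leaf_ids, Z)``
    where ``Z`` is the scipy linkage matrix.
    """
    if axis not in ("rows", "columns"):
        raise ParameterError("axis must be 'rows' or 'columns'")
    X = matrix.to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0  # zero-variance guard: row left at 0
        X = (X - mu) / sd
    items = X if axis == "rows" else X.T
    ids = list(matrix.index if axis == "rows" else matrix.columns)
    if items.shape[0] < 2:
        raise ParameterError("need at least 2 items to cluster")
    Z = hierarchy.linkage(items, method="average", metric="euclidean")
    order = [ids[i] for i in hierarchy.leaves_list(Z)]
    return order, Z
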