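"""Occupancy/expression categories and permutation-null overlap tests.

Genes are binned by expression (highly expressed: TPM > 10; unexpressed:
TPM = 0) and TSSs by occupancy quartile (HTSS: upper quartile, LTSS:
lower quartile). The significance of an overlap between two gene sets is
assessed against a permutation null: the second set's membership is
resampled uniformly from the universe with its size held fixed, the null
overlap distribution is standardized, and a two-sided p-value is taken
from the standard normal.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateNullError, ParameterError, ValidationError

HIGH_TPM = 10.0


@dataclasses.dataclass
class CategoryAssignment:
    """The four gene categories used in overlap testing."""

    htss: set
    ltss: set
    heg: set
    ueg: set
    universe: set


@dataclasses.dataclass
class OverlapTestResult:
    """Observed overlap of two gene sets against a permutation null."""

    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_two_sided: float
    n_permutations: int
    direction: str  # "enriched" | "depleted" | "none"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def classify_expression(expression: pd.Series, high_tpm: float = HIGH_TPM):
    """Split genes into highly expressed (TPM > high_tpm) and unexpressed (TPM = 0).

    Genes with 0 < TPM <= high_tpm belong to neither set.
    """
    heg = set(expression.index[expression > high_tpm])
    ueg = set(expression.index[expression == 0])
    return heg, ueg


def classify_occupancy_quartiles(occupancy: pd.Series):
    """Upper- and lower-quartile TSS sets by occupancy.

    Ids are ordered by (occupancy, gene_id); the top ``ceil(n / 4)`` form
    the HTSS set and the bottom ``ceil(n / 4)`` the LTSS set. The id
    tie-break makes the split deterministic and the two sets disjoint
    for n >= 4.
    """
    n = len(occupancy)
    if n < 4:
        raise ParameterError("quartile classification needs at least 4 TSSs")
    k = math.ceil(n / 4)
    order = sorted(occupancy.index, key=lambda g: (occupancy[g], str(g)))
    ltss = set(order[:k])
    htss = set(order[-k:])
    return htss, ltss


def assign_categories(occupancy: pd.Series, expression: pd.Series) -> CategoryAssignment:
    """Categorize genes shared between an occupancy and an expression profile."""
    shared = occupancy.index.intersection(expression.index)
    if len(shared) < 4:
        raise ParameterError("need at least 4 shared genes")
    htss, ltss = classify_occupancy_quartiles(occupancy.loc[shared])
    heg, ueg = classify_expression(expression.loc[shared])
    return CategoryAssignment(htss=htss, ltss=ltss, heg=heg, ueg=ueg,
                              universe=set(shared))


def permutation_overlap_test(
    set_a,
    set_b,
    universe,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> OverlapTestResult:
    """Permutation-null test of the overlap between two gene sets.

    The null draws a uniformly random subset of ``|set_b|`` ids from the
    universe ``n_permutations`` times and records its overlap with
    ``set_a``. Implementation detail: after sorting the universe
    canonically, each draw takes the first ``|set_b|`` entries of a
    seeded permutation of ``range(N)`` and counts how many land among
    the first ``|set_a|`` positions — an exchangeable reformulation that
    depends only on the set sizes, making the result invariant to
    relabeling the universe ids.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValidationError("set_a and set_b must be subsets of the universe")
    if n_permutations < 100:
        raise ParameterError("need at least 100 permutations")
    n = len(universe)
    m = len(set_b)
    observed = len(set_a & set_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=np.int64)
    n_a = len(set_a)
    for i in range(n_permutations):
        draw = rng.permutation(n)[:m]
        null[i] = int(np.count_nonzero(draw < n_a))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    if null_sd == 0:
        raise DegenerateNullError(
            "permutation null has zero spread (is set_b the whole universe?)"
        )
    z = (observed - null_mean) / null_sd
    p = min(1.0, float(2.0 * stats.norm.sf(abs(z))))
    if p < alpha:
        direction = "enriched" if z > 0 else "depleted"
    else:
        direction = "none"
    return OverlapTestResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_two_sided=p,
        n_permutations=n_permutations,
        direction=direction,
    )


def spearman_concordance(x: pd.Series, y: pd.Series) -> float:
    """Spearman rank correlation over the intersection of the two indices.

    Mid-ranks are used on ties (Pearson correlation of average ranks).
    """
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        raise ParameterError("need at least 3 shared ids for a rank correlation")
    rho, _ = stats.spearmanr(x.loc[shared].to_numpy(), y.loc[shared].to_numpy())
    return float(rho)
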