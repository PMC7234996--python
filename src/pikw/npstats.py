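"""Nonparametric statistics core.

Midranks, the tie-corrected Kruskal-Wallis H statistic (with a vectorized
form for resampling nulls), Mann-Whitney U (exact for small tie-free samples,
tie-adjusted normal approximation otherwise), nearest-rank empirical
percentiles, and add-one empirical p-values.

The empirical-null containers here are trait-scale-free: H is computed from
ranks only, so a null built from simulated characters does not depend on the
simulation's variance or root state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupedSample",
    "KWResult",
    "MWResult",
    "EmpiricalNull",
    "midranks",
    "kruskal_wallis",
    "kw_h",
    "kw_h_matrix",
    "mann_whitney",
    "empirical_percentile",
    "empirical_p",
]


@dataclass
class GroupedSample:
    """Continuous observations with a categorical group label per value."""

    values: np.ndarray
    group_labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        if self.values.shape != self.group_labels.shape:
            raise ValueError("values and group_labels must have equal length")
        if self.values.size == 0:
            raise ValueError("empty sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in sample")
        if len(np.unique(self.group_labels)) < 2:
            raise ValueError("need at least 2 groups")


@dataclass
class KWResult:
    H: float
    k: int
    n_per_group: dict
    chisq_p: float


@dataclass
class MWResult:
    U: float
    p_two_sided: float
    method: str  # "exact" | "normal-approximation"


@dataclass
class EmpiricalNull:
    """Simulated null H values with replication metadata."""

    h_values: np.ndarray
    n_sims: int
    seed: int
    stratum_id: str

    def __post_init__(self):
        self.h_values = np.asarray(self.h_values, dtype=float)
        if self.h_values.size != self.n_sims:
            raise ValueError("h_values length must equal n_sims")
        if np.any(self.h_values < 0):
            raise ValueError("H values must be >= 0")


def midranks(values) -> np.ndarray:
    """Average ranks; tied values share the mean of the ranks they span."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("midranks requires >= 1 finite values")
    return stats.rankdata(values, method="average")


def _tie_correction(values: np.ndarray) -> float:
    """C = 1 - sum(t^3 - t) / (N^3 - N) over tie groups; C = 0 if all tied."""
    n = values.size
    if n < 2:
        return 1.0
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - (counts**3 - counts).sum() / (n**3 - n)


def kw_h(values: np.ndarray, group_labels: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H (0 when every value is tied)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = midranks(values)
    if len(np.unique(group_labels)) < 2:
        raise ValueError("need at least 2 groups")
    h = 0.0
    for g in np.unique(group_labels):
        mask = group_labels == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        h += ranks[mask].sum() ** 2 / mask.sum()
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    c = _tie_correction(values)
    if c == 0.0:
        warnings.warn("all values identical; H defined as 0", RuntimeWarning)
        return 0.0
    return max(h / c, 0.0)  # clamp float round-off: H >= 0 by definition


def kruskal_wallis(sample: GroupedSample) -> KWResult:
    """Tie-corrected KW test with the chi-square(k-1) tail approximation."""
    groups, counts = np.unique(sample.group_labels, return_counts=True)
    k = len(groups)
    if sample.values.size < 3:
        raise ValueError("Kruskal-Wallis requires total n >= 3")
    h = kw_h(sample.values, sample.group_labels)
    p = float(stats.chi2.sf(h, k - 1))
    return KWResult(
        H=float(h),
        k=k,
        n_per_group={str(g): int(c) for g, c in zip(groups, counts)},
        chisq_p=max(p, np.nextafter(0, 1)),
    )


def kw_h_matrix(values: np.ndarray, group_labels: np.ndarray) -> np.ndarray:
    """KW H for each column of a (n_obs, n_reps) matrix, fixed labels.

    Vectorized over replicates; columns containing ties fall back to the
    scalar tie-corrected path. This is the workhorse for empirical nulls,
    where replicates are continuous simulated characters (ties have
    probability zero but are still handled exactly).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D (n_obs, n_reps) matrix")
    n, n_reps = values.shape
    group_labels = np.asarray(group_labels)
    ranks = stats.rankdata(values, method="average", axis=0)
    h = np.zeros(n_reps)
    for g in np.unique(group_labels):
        mask = group_labels == g
        h += ranks[mask].sum(axis=0) ** 2 / mask.sum()
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)

    srt = np.sort(values, axis=0)
    tied_cols = np.flatnonzero((srt[1:] == srt[:-1]).any(axis=0))
    for c in tied_cols:
        h[c] = kw_h(values[:, c], group_labels)
    return np.maximum(h, 0.0)  # clamp float round-off: H >= 0 by definition


def mann_whitney(a, b) -> MWResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of rank configurations when the combined sample
    size is at most 12 and there are no ties; otherwise the tie-adjusted
    normal approximation with continuity correction. U is referenced to the
    smaller group (the first on a size tie).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    exact = (a.size + b.size) <= 12 and not has_ties
    method = "exact" if exact else "asymptotic"
    x, y = (a, b) if a.size <= b.size else (b, a)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return MWResult(
        U=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal-approximation",
    )


def empirical_percentile(null: EmpiricalNull | Sequence[float], q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    h = null.h_values if isinstance(null, EmpiricalNull) else np.asarray(null, float)
    if not 0 < q < 100:
        raise ValueError(f"percentile q must be in (0, 100), got {q}")
    n = h.size
    if n < 20:
        raise ValueError("need at least 20 simulated values for a percentile")
    m = int(np.ceil(q / 100.0 * n))
    return float(np.sort(h)[m - 1])


def empirical_p(
    null: EmpiricalNull | Sequence[float], observed: float
) -> tuple[float, float]:
    """Empirical upper-tail p of ``observed`` against the null draws.

    Returns ``(add_one, raw)``: the add-one estimator
    (1 + #{h >= observed}) / (1 + n) which can never be 0, and the raw
    proportion #{h >= observed} / n.
    """
    h = null.h_values if isinstance(null, EmpiricalNull) else np.asarray(null, float)
    n = h.size
    if n < 1:
        raise ValueError("empty null")
    count = int(np.sum(h >= observed))
    return (1.0 + count) / (1.0 + n), count / n
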