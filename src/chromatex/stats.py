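"""Two-group comparison tests used throughout the pipeline.

The workhorse is the two-tailed Mann-Whitney U test. For small, tie-free
samples (combined n ≤ 20) the p-value is exact: the null distribution of U
over all C(n_a+n_b, n_a) equally likely rank assignments is computed by a
dynamic program over rank sums, and the two-tailed p is twice the smaller
tail probability, capped at 1. Larger or tied samples use the normal
approximation with midranks, tie correction and a 0.5 continuity
correction. A pooled-variance two-sample Student's t-test is also provided,
with explicit conventions for degenerate zero-variance inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "t_test",
    "compare_texture_groups",
    "exact_u_cdf",
]

EXACT_MAX_COMBINED_N = 20


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group test on a named parameter."""

    parameter: str
    statistic: float
    p_value: float
    method: str  # mann_whitney_exact | mann_whitney_normal | t_test
    n_a: int
    n_b: int
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _rank_sum_counts(n_total: int, k: int) -> np.ndarray:
    """Number of k-subsets of ranks {1..n_total} attaining each rank sum.

    Returns an array c where c[s] counts subsets with sum s
    (s = 0 .. k*n_total). Classic subset-sum DP, O(n_total * k * S).
    """
    max_sum = k * n_total
    counts = np.zeros((k + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        # iterate subset sizes downward so each rank is used at most once
        upper = min(rank, k)
        for size in range(upper, 0, -1):
            counts[size, rank:] += counts[size - 1, :-rank or None]
    return counts[k]


def exact_u_cdf(n_a: int, n_b: int) -> np.ndarray:
    """Null probabilities P(U_a = u) for u = 0..n_a*n_b (tie-free case)."""
    counts = _rank_sum_counts(n_a + n_b, n_a)
    # U_a = R_a - n_a(n_a+1)/2; R_a ranges over [n_a(n_a+1)/2, ...]
    offset = n_a * (n_a + 1) // 2
    probs = counts[offset: offset + n_a * n_b + 1]
    return probs / probs.sum()


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    r_a = ranks[: len(a)].sum()
    u_a = r_a - len(a) * (len(a) + 1) / 2.0
    return float(u_a), pooled


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   parameter: str = "") -> GroupComparison:
    """Two-tailed Mann-Whitney U test of two independent samples.

    Exact enumeration p when the combined sample size is ≤ 20 and the pooled
    data are tie-free; otherwise normal approximation with tie and
    continuity corrections. The reported statistic is U for sample ``a``.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    u_a, pooled = _u_statistic(a, b)
    has_ties = len(np.unique(pooled)) < pooled.size

    if n_a + n_b <= EXACT_MAX_COMBINED_N and not has_ties:
        pmf = exact_u_cdf(n_a, n_b)
        u_int = int(round(u_a))
        p_lo = pmf[: u_int + 1].sum()
        p_hi = pmf[u_int:].sum()
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        method = "mann_whitney_exact"
    else:
        mu = n_a * n_b / 2.0
        n = n_a + n_b
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
        var = n_a * n_b / 12.0 * (n + 1.0 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_a - mu) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * sps.norm.sf(z))
        method = "mann_whitney_normal"
    return GroupComparison(parameter=parameter, statistic=u_a, p_value=float(p),
                           method=method, n_a=n_a, n_b=n_b)


def t_test(a: Sequence[float], b: Sequence[float], parameter: str = "") -> GroupComparison:
    """Pooled-variance two-sample Student's t-test, two-tailed.

    Degenerate inputs follow explicit conventions: zero pooled variance with
    equal means gives t = 0, p = 1; with unequal means, p = 0 (flagged in
    ``notes``).
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs at least two observations per group")
    n_a, n_b = a.size, b.size
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return GroupComparison(parameter, 0.0, 1.0, "t_test", n_a, n_b)
        return GroupComparison(parameter, np.inf if diff > 0 else -np.inf, 0.0,
                               "t_test", n_a, n_b, notes="zero pooled variance")
    t = diff / np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(parameter, float(t), float(min(p, 1.0)), "t_test", n_a, n_b)


FEATURE_COLUMNS = ["asm", "contrast", "correlation", "idm", "entropy"]


def compare_texture_groups(control: pd.DataFrame, treated: pd.DataFrame,
                           features: Sequence[str] | None = None,
                           method: str = "mann_whitney") -> list[GroupComparison]:
    """Compare two texture tables feature by feature.

    The tables are per-sample (one row per sample mean, the default workflow)
    or per-nucleus; each shared feature column yields one comparison.
    Undefined (NaN) values — correlation on zero-variance nuclei — are
    dropped per group, with the dropped counts recorded in ``notes``.
    """
    if control.empty or treated.empty:
        raise ValueError("both tables must be non-empty")
    if features is None:
        features = [f for f in FEATURE_COLUMNS if f in control.columns and f in treated.columns]
    if not features:
        raise ValueError("no shared feature columns between the two tables")
    test = mann_whitney_u if method == "mann_whitney" else t_test
    out: list[GroupComparison] = []
    for feat in features:
        x = control[feat].to_numpy(dtype=np.float64)
        y = treated[feat].to_numpy(dtype=np.float64)
        n_drop = int(np.isnan(x).sum() + np.isnan(y).sum())
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        cmp_ = test(x, y, parameter=feat)
        if n_drop:
            cmp_ = GroupComparison(cmp_.parameter, cmp_.statistic, cmp_.p_value,
                                   cmp_.method, cmp_.n_a, cmp_.n_b,
                                   notes=f"dropped {n_drop} undefined values")
        out.append(cmp_)
    return out
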