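"""Functional two-sample comparison of HRF curves.

The pointwise statistic is the absolute difference of group mean curves
over the Welch-style standard error at each time point; its maximum
over time (max-t) is calibrated with a permutation test that relabels
curves between the two groups.  The permutation p-value is the fraction
of permutations whose max-t strictly exceeds the observed max-t.
Familywise control across many structure/group comparisons uses the
Bonferroni correction, and only comparisons with at least ``min_n``
curves per group are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "CurveSample",
    "FunctionalTestResult",
    "pointwise_t",
    "max_t_permutation_test",
    "bonferroni_threshold",
    "format_threshold",
    "compare_groups",
    "null_calibration",
]

#: relative variance floor guarding t against division by zero when the
#: mean difference is nonzero but sample variances vanish
_VAR_FLOOR = 1e-12

#: mean differences below this fraction of the sample scale are float
#: summation noise and treated as exact ties
_MEAN_TOL = 1e-12


@dataclass
class CurveSample:
    """A group of HRF curves on a common grid (rows = curves)."""

    curves: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))

    @property
    def n(self) -> int:
        return self.curves.shape[0]


@dataclass
class FunctionalTestResult:
    """Result of one functional max-t permutation test."""

    t_curve: np.ndarray
    t_max: float
    p: float
    n_x: int
    n_y: int
    n_permutations: int
    seed: int | None = None
    exhaustive: bool = False


def _t_curve(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|mean_x - mean_y| / sqrt(var_x/n_x + var_y/n_y), per time point.

    Time points where both the numerator and the denominator vanish
    yield t = 0; a vanishing denominator with a nonzero numerator is
    guarded by a variance floor relative to the sample scale.
    """
    nx, ny = x.shape[0], y.shape[0]
    num = np.abs(x.mean(axis=0) - y.mean(axis=0))
    den2 = x.var(axis=0, ddof=1) / nx + y.var(axis=0, ddof=1) / ny
    scale = max(float(np.max(np.abs(x), initial=0)),
                float(np.max(np.abs(y), initial=0)), 1e-300)
    floor = _VAR_FLOOR * scale ** 2
    t = np.zeros_like(num)
    # mean differences at float roundoff level are exact ties
    zero = (num <= _MEAN_TOL * scale) | ((den2 <= floor) & (num <= np.sqrt(floor)))
    live = ~zero
    t[live] = num[live] / np.sqrt(np.maximum(den2[live], floor))
    return t


def pointwise_t(x: CurveSample, y: CurveSample) -> np.ndarray:
    """Pointwise functional t curve between two curve samples."""
    if x.curves.shape[1] != y.curves.shape[1]:
        raise ValueError("samples are on different grids")
    if x.n < 2 or y.n < 2:
        raise ValueError("each sample needs at least 2 curves")
    return _t_curve(x.curves, y.curves)


def _max_t_for_splits(data: np.ndarray, memberships: np.ndarray,
                      nx: int, ny: int) -> np.ndarray:
    """Vectorized max-t for many 0/1 group-membership rows.

    ``memberships`` is (n_splits, n_total) with exactly ``nx`` ones per
    row marking group x.  Group means and variances come from matrix
    products with the data and its square.
    """
    mx = memberships.astype(float)
    my = 1.0 - mx
    s1x = mx @ data
    s2x = mx @ data ** 2
    s1y = my @ data
    s2y = my @ data ** 2
    mean_x = s1x / nx
    mean_y = s1y / ny
    var_x = np.maximum(s2x - nx * mean_x ** 2, 0.0) / (nx - 1) if nx > 1 else np.zeros_like(s1x)
    var_y = np.maximum(s2y - ny * mean_y ** 2, 0.0) / (ny - 1) if ny > 1 else np.zeros_like(s1y)
    num = np.abs(mean_x - mean_y)
    den2 = var_x / nx + var_y / ny
    scale = max(float(np.max(np.abs(data), initial=0)), 1e-300)
    floor = _VAR_FLOOR * scale ** 2
    t = np.zeros_like(num)
    zero = (num <= _MEAN_TOL * scale) | ((den2 <= floor) & (num <= np.sqrt(floor)))
    live = ~zero
    t[live] = num[live] / np.sqrt(np.maximum(den2[live], floor))
    return t.max(axis=1)


def max_t_permutation_test(x: CurveSample, y: CurveSample,
                           n_permutations: int = 10_000,
                           seed: int | None = 0,
                           exhaustive: str | bool = "auto"
                           ) -> FunctionalTestResult:
    """Functional max-t test with permutation inference.

    p = N / B where N counts permutations whose max-t strictly exceeds
    the observed max-t (ties do not count) and B is the number of
    permutations.  Group relabelings are sampled uniformly with
    replacement; when the total number of distinct splits is at most
    ``n_permutations`` (or ``exhaustive=True``) all splits are
    enumerated instead and p is exact.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if x.curves.shape[1] != y.curves.shape[1]:
        raise ValueError("samples are on different grids")
    nx, ny = x.n, y.n
    if nx + ny < 3:
        raise ValueError("need at least 3 curves in total")
    data = np.vstack([x.curves, y.curves])
    t_obs_curve = _t_curve(x.curves, y.curves)
    # observed max-t through the same vectorized path as the permuted
    # ones so that group-preserving relabelings tie bit-exactly
    identity = np.zeros((1, nx + ny), dtype=bool)
    identity[0, :nx] = True
    t_obs = float(_max_t_for_splits(data, identity, nx, ny)[0])

    n_total = nx + ny
    n_splits = comb(n_total, nx)
    use_exhaustive = (exhaustive is True
                      or (exhaustive == "auto" and n_splits <= n_permutations))

    if use_exhaustive:
        members = np.zeros((n_splits, n_total), dtype=bool)
        for i, idx in enumerate(combinations(range(n_total), nx)):
            members[i, list(idx)] = True
        n_done = n_splits
    else:
        rng = np.random.default_rng(seed)
        members = np.zeros((n_permutations, n_total), dtype=bool)
        for i in range(n_permutations):
            members[i, rng.permutation(n_total)[:nx]] = True
        n_done = n_permutations

    t_perm = _max_t_for_splits(data, members, nx, ny)
    n_exceed = int(np.sum(t_perm > t_obs))
    return FunctionalTestResult(
        t_curve=t_obs_curve, t_max=t_obs, p=n_exceed / n_done,
        n_x=nx, n_y=ny, n_permutations=n_done, seed=seed,
        exhaustive=use_exhaustive)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def format_threshold(threshold: float, decimals: int = 4) -> str:
    """Display form of an adjusted threshold, rounded to 4 decimals."""
    return f"{round(threshold, decimals):g}"


def compare_groups(library: pd.DataFrame, curves: dict,
                   min_n: int = 6, alpha: float = 0.05,
                   n_permutations: int = 10_000,
                   seed: int = 0) -> pd.DataFrame:
    """All pairwise functional tests across a tagged HRF library.

    ``library`` has one row per included HRF with a ``group`` column;
    ``curves`` maps group label -> (n, n_time) array of normalized HRF
    curves.  Only pairs with n >= ``min_n`` in both groups are tested;
    the Bonferroni threshold uses the realized number of comparisons.
    """
    groups = sorted(curves)
    eligible = [g for g in groups if curves[g].shape[0] >= min_n]
    pairs = list(combinations(eligible, 2))
    rows = []
    for k, (g1, g2) in enumerate(pairs):
        res = max_t_permutation_test(
            CurveSample(curves[g1], g1), CurveSample(curves[g2], g2),
            n_permutations=n_permutations, seed=seed + k)
        rows.append({"group1": g1, "group2": g2,
                     "n1": res.n_x, "n2": res.n_y,
                     "t_max": res.t_max, "p": res.p})
    table = pd.DataFrame(
        rows, columns=["group1", "group2", "n1", "n2", "t_max", "p"])
    if len(table):
        thr = bonferroni_threshold(alpha, len(table))
        table["threshold"] = thr
        table["significant"] = table["p"] < thr
    else:
        import warnings
        warnings.warn("no eligible comparisons (all group sizes below min_n)")
    return table


def null_calibration(n_per_group: int = 10, n_permutations: int = 1_000,
                     n_replicates: int = 200, alpha: float = 0.05,
                     seed: int = 0, jitter: float = 0.05,
                     grid: np.ndarray | None = None) -> float:
    """Empirical type-I error of the max-t test under the null.

    For each replicate, two groups of ``n_per_group`` HRF curves are
    drawn from one jittered mouse-preset parameter distribution
    (multiplicative Gaussian jitter on b, p1, p2, V) and tested at
    ``alpha``; returns the rejection fraction.
    """
    from .hrf import HRFParams, MOUSE, evaluate_hrf

    if grid is None:
        grid = np.arange(0, 30.0 + 1e-9, 0.1)
    rng = np.random.default_rng(seed)
    rejections = 0
    base = np.array([MOUSE.b, MOUSE.p1, MOUSE.p2, MOUSE.V])
    for _ in range(n_replicates):
        curves = []
        for _ in range(2 * n_per_group):
            while True:
                b, p1, p2, V = base * (1.0 + rng.normal(0, jitter, size=4))
                if b > 0 and p1 > 1 and p2 > p1 and V > 0:
                    break
            c = evaluate_hrf(HRFParams(A=1.0, b=b, p1=p1, p2=p2, V=V), grid)
            curves.append(c.values / c.values.max())
        curves = np.asarray(curves)
        res = max_t_permutation_test(
            CurveSample(curves[:n_per_group]),
            CurveSample(curves[n_per_group:]),
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)), exhaustive=False)
        if res.p < alpha:
            rejections += 1
    return rejections / n_replicates
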