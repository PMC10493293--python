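"""Voxelwise GLM detection of BOLD activation.

Ordinary least squares per voxel against a canonical or FIR design,
significance from a one-sided t (single task regressor) or an F over
all task columns, thresholding at uncorrected p with a cluster-extent
filter (6-connectivity), activation-probability maps, Dice similarity
of binary masks, and per-structure activated-voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import DesignMatrix

__all__ = [
    "StatMap",
    "smooth_spatial",
    "fit_glm",
    "task_statistic",
    "threshold_map",
    "activation_probability",
    "dice",
    "count_activated_voxels",
]

# residual / effect sums of squares below this (relative to problem
# size) are treated as exactly zero: noise-free voxels otherwise yield
# 0/0 statistics
_ZERO_TOL = 1e-9


@dataclass
class StatMap:
    """Voxelwise test statistic with uncorrected p-values."""

    values: np.ndarray          # 3-D statistic
    p: np.ndarray               # 3-D uncorrected p
    kind: str                   # "t" or "F"
    df: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.values.shape != self.p.shape:
            raise ValueError("statistic and p volumes differ in shape")
        if np.nanmin(self.p) < 0 or np.nanmax(self.p) > 1:
            raise ValueError("p-values outside [0, 1]")


def smooth_spatial(data4d: np.ndarray, fwhm: tuple[float, float, float],
                   voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
                   ) -> np.ndarray:
    """Per-volume Gaussian smoothing with per-axis FWHM (same units as
    ``voxel_size``); FWHM 0 on every axis is the identity."""
    fwhm = np.asarray(fwhm, dtype=float)
    if np.any(fwhm < 0):
        raise ValueError("FWHM must be non-negative")
    if np.all(fwhm == 0):
        return data4d.copy()
    sigma = fwhm / np.asarray(voxel_size) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.empty_like(data4d, dtype=float)
    for t in range(data4d.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(data4d[..., t], sigma=sigma)
    return out


def fit_glm(data4d: np.ndarray, design: DesignMatrix
            ) -> tuple[np.ndarray, np.ndarray, int]:
    """Voxelwise OLS fit.

    Returns ``(betas, rss, df)`` with betas shaped (x, y, z, p),
    residual sum of squares per voxel, and df = volumes - columns.
    """
    X = design.matrix
    n, p = X.shape
    if data4d.shape[-1] != n:
        raise ValueError(
            f"data has {data4d.shape[-1]} volumes but design has {n} rows")
    Y = data4d.reshape(-1, n).T            # (n, n_vox)
    pinv = np.linalg.pinv(X)
    B = pinv @ Y                           # (p, n_vox)
    resid = Y - X @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    spatial = data4d.shape[:3]
    return (B.T.reshape(spatial + (p,)), rss.reshape(spatial), n - p)


def task_statistic(betas: np.ndarray, rss: np.ndarray,
                   design: DesignMatrix, kind: str = "auto") -> StatMap:
    """Voxelwise task significance.

    A single task column yields a one-sided t on its coefficient
    (positive BOLD); multiple task columns (canonical order 3, FIR)
    yield an F over the task block via the general linear hypothesis.
    Voxels where both the effect and the residual vanish (noise-free
    non-responders) get statistic 0 and p = 1.
    """
    X = design.matrix
    n, p = X.shape
    df = n - p
    task = design.task_columns
    if not task:
        raise ValueError("design has no task columns")
    if kind == "auto":
        kind = "t" if len(task) == 1 else "F"

    spatial = betas.shape[:3]
    B = betas.reshape(-1, p)
    rssf = rss.reshape(-1)
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rssf / max(df, 1)
    scale = np.maximum(rssf, n) * _ZERO_TOL

    if kind == "t":
        j = task[0]
        beta = B[:, j]
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 0.0))
        tvals = np.zeros_like(beta)
        pvals = np.ones_like(beta)
        degenerate = (se <= scale) & (np.abs(beta) <= np.sqrt(scale))
        exact = (se <= scale) & ~degenerate
        regular = ~degenerate & ~exact
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals[regular] = beta[regular] / se[regular]
        pvals[regular] = stats.t.sf(tvals[regular], df)
        tvals[exact] = np.inf * np.sign(beta[exact])
        pvals[exact] = np.where(beta[exact] > 0, 0.0, 1.0)
        return StatMap(values=tvals.reshape(spatial),
                       p=pvals.reshape(spatial), kind="t", df=(df,))

    if kind != "F":
        raise ValueError(f"unknown statistic kind {kind!r}")
    q = len(task)
    sub = np.ix_(task, task)
    middle = np.linalg.inv(xtx_inv[sub])   # (X'X)^-1 task block, inverted
    BT = B[:, task]
    # RSS0 - RSS1 for H0: all task betas = 0
    num = np.einsum("ij,jk,ik->i", BT, middle, BT)
    fvals = np.zeros_like(rssf)
    pvals = np.ones_like(rssf)
    degenerate = (rssf <= scale) & (num <= scale)
    exact = (rssf <= scale) & ~degenerate
    regular = ~degenerate & ~exact
    with np.errstate(divide="ignore", invalid="ignore"):
        fvals[regular] = (num[regular] / q) / (rssf[regular] / df)
    pvals[regular] = stats.f.sf(fvals[regular], q, df)
    fvals[exact] = np.inf
    pvals[exact] = 0.0
    return StatMap(values=fvals.reshape(spatial),
                   p=pvals.reshape(spatial), kind="F", df=(q, df))


def threshold_map(stat: StatMap, alpha: float = 0.05,
                  min_cluster: int = 5) -> np.ndarray:
    """Binary activation mask: p < alpha, clusters > min_cluster voxels.

    Connected components are defined on the 6-neighborhood (faces);
    components of min_cluster voxels or fewer are removed.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    mask = stat.p < alpha
    structure = ndimage.generate_binary_structure(3, 1)
    labeled, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        return mask
    sizes = np.bincount(labeled.ravel())
    keep = sizes > min_cluster
    keep[0] = False
    return keep[labeled]


def activation_probability(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise mean of binary masks across a group of scans."""
    if not masks:
        raise ValueError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError("masks have inconsistent shapes")
    return np.mean([m.astype(float) for m in masks], axis=0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks give 1."""
    if a.shape != b.shape:
        raise ValueError("masks have different shapes")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def count_activated_voxels(mask: np.ndarray, labels: np.ndarray
                           ) -> pd.DataFrame:
    """Activated-voxel counts per atlas structure.

    Returns one row per structure with its total size and the number of
    voxels inside the activation mask.
    """
    if mask.shape != labels.shape:
        raise ValueError("mask and labels have different shapes")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    for sid in ids:
        sel = labels == sid
        rows.append({"structure": int(sid),
                     "n_voxels": int(sel.sum()),
                     "n_active": int(np.logical_and(sel, mask).sum())})
    return pd.DataFrame(rows, columns=["structure", "n_voxels", "n_active"])
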