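"""Structure-wise BOLD time-course extraction and epoch averaging.

Voxel time courses are taken from the intersection of the activation
mask and each atlas structure, optionally smoothed with a 5 s moving
average, folded over the 30 s paradigm cycles (stimulus onset at 10 s
into the epoch window), converted to percent signal change against the
10 s pre-onset baseline, and classified as positive / negative /
unclassified BOLD responses by amplitude (>= 0.6%) and post-peak decay
(>= 40%) criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BlockParadigm

__all__ = [
    "EpochCurve",
    "extract_voxel_timecourses",
    "smooth_temporal",
    "epoch_average",
    "classify_polarity",
    "structure_mean_curve",
    "write_epoch_curves",
]


@dataclass
class EpochCurve:
    """Cycle-averaged, baseline-normalized response of one voxel/structure.

    ``time`` runs over one paradigm cycle (0..30 s by default) with the
    stimulus onset at ``onset`` seconds into the window; ``values`` are
    percent signal change relative to the pre-onset baseline.
    """

    time: np.ndarray
    values: np.ndarray
    onset: float = 10.0
    n_voxels: int = 1
    structure: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.size != self.values.size:
            raise ValueError("time and values must have the same length")


def extract_voxel_timecourses(data4d: np.ndarray, labels: np.ndarray,
                              active_mask: np.ndarray
                              ) -> dict[int, np.ndarray]:
    """Per-structure matrix of voxel time courses from active voxels.

    Only voxels in ``active_mask ∩ {labels == s}`` are returned, keyed
    by structure id; a structure with no active voxels is omitted.
    """
    if data4d.shape[:3] != labels.shape or labels.shape != active_mask.shape:
        raise ValueError("data, labels and mask have inconsistent shapes")
    out: dict[int, np.ndarray] = {}
    for sid in np.unique(labels[labels > 0]):
        sel = (labels == sid) & active_mask
        if sel.any():
            out[int(sid)] = data4d[sel]          # (n_voxels, n_t)
    return out


def smooth_temporal(series: np.ndarray, window: float, TR: float) -> np.ndarray:
    """Centered moving average over ``window`` seconds.

    The window is rounded to an odd number of samples; edges use
    shrinking (truncated) windows so the output length is unchanged.
    Operates on the last axis.
    """
    if window < TR:
        raise ValueError("smoothing window must be at least one TR")
    w = int(round(window / TR))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return np.asarray(series, dtype=float).copy()
    x = np.asarray(series, dtype=float)
    half = w // 2
    csum = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x],
                                    axis=-1), axis=-1)
    n = x.shape[-1]
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (np.take(csum, hi, axis=-1) - np.take(csum, lo, axis=-1)) / (hi - lo)


def epoch_average(series: np.ndarray, paradigm: BlockParadigm) -> EpochCurve:
    """Fold a voxel series over paradigm cycles and baseline-normalize.

    Epochs of one cycle length are aligned ``pre_window`` seconds before
    each stimulus onset, averaged across cycles, and converted to
    percent change relative to the mean of the pre-onset baseline
    window; the output baseline mean is 0 by construction.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch_average expects a single voxel series")
    n_per_cycle = int(round(paradigm.cycle_duration / paradigm.TR))
    n_cycles = x.shape[-1] // n_per_cycle
    if n_cycles < 2:
        raise ValueError("need at least 2 complete cycles for epoch averaging")
    n_cycles = min(n_cycles, paradigm.n_blocks)
    folded = x[..., :n_cycles * n_per_cycle].reshape(
        x.shape[:-1] + (n_cycles, n_per_cycle))
    mean_cycle = folded.mean(axis=-2)
    n_base = int(round(paradigm.pre_window / paradigm.TR))
    base = mean_cycle[..., :n_base].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("non-positive baseline; cannot express percent change")
    values = (mean_cycle - base) / base * 100.0
    time = np.arange(n_per_cycle) * paradigm.TR
    return EpochCurve(time=time, values=np.squeeze(values),
                      onset=paradigm.pre_window)


def classify_polarity(curve: EpochCurve, amp_min: float = 0.6,
                      decay_min: float = 0.4) -> str:
    """Classify a normalized epoch curve as positive/negative BOLD.

    Positive requires (1) a peak of at least ``amp_min`` percent and
    (2) a decay of at least ``decay_min`` (fraction of the peak) after
    the maximum; negative applies the same rules to the inverted curve;
    anything else is unclassified.
    """
    def _is_responsive(y: np.ndarray) -> bool:
        i_peak = int(np.argmax(y))
        peak = y[i_peak]
        if peak < amp_min:
            return False
        post_min = y[i_peak:].min()
        return post_min <= (1.0 - decay_min) * peak

    y = np.asarray(curve.values, dtype=float)
    if _is_responsive(y):
        return "positive"
    if _is_responsive(-y):
        return "negative"
    return "unclassified"


def structure_mean_curve(curves: list[EpochCurve],
                         min_voxels: int = 4) -> EpochCurve | None:
    """Voxelwise mean curve if strictly more than ``min_voxels`` curves.

    Structures with ``min_voxels`` or fewer positive voxels are
    excluded (returns ``None``).
    """
    if len(curves) <= min_voxels:
        return None
    time = curves[0].time
    for c in curves[1:]:
        if c.time.shape != time.shape or not np.allclose(c.time, time):
            raise ValueError("curves are on different grids")
    values = np.mean([c.values for c in curves], axis=0)
    return EpochCurve(time=time, values=values, onset=curves[0].onset,
                      n_voxels=len(curves), structure=curves[0].structure)


def write_epoch_curves(curves: list[EpochCurve], path) -> None:
    """Export epoch curves as TSV (structure, n_voxels, time, value)."""
    rows = []
    for c in curves:
        for t, v in zip(c.time, c.values):
            rows.append({"structure": c.structure, "n_voxels": c.n_voxels,
                         "time": t, "value": v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
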