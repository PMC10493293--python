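"""Block paradigms, stimulus functions and GLM design matrices.

A block paradigm alternates fixed stimulation and rest epochs; here the
default is the 20-block design with 10 s stimulation / 20 s rest at
TR = 1 s, with 620 acquired volumes of which the first 20 are discarded
(600 analyzed volumes) and the first stimulus onset 10 s into the
analyzed series.  Designs are built either from an HRF-convolved
regressor (canonical basis, optionally with its temporal and dispersion
derivative columns) or from a finite-impulse-response (FIR) set of
contiguous post-onset boxcar bins that estimates the response shape
without assuming an HRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import HRFCurve, HRFParams, evaluate_hrf, hrf_basis_derivatives, default_grid

__all__ = [
    "BlockParadigm",
    "DesignMatrix",
    "boxcar",
    "convolve_with_hrf",
    "task_regressor",
    "build_canonical_design",
    "build_fir_design",
    "read_events",
    "write_events",
]


@dataclass(frozen=True)
class BlockParadigm:
    """Block-design stimulus timing.

    Onsets are ``pre_window + k * (stim_duration + rest_duration)``
    relative to the first analyzed volume.  The 1 Hz / 0.5 s pulse
    substructure within each stimulation block is modeled as a
    continuous boxcar by default (pulse timing is far below HRF
    bandwidth); pulse-level modeling is available via ``boxcar``.
    """

    n_blocks: int = 20
    stim_duration: float = 10.0
    rest_duration: float = 20.0
    TR: float = 1.0
    pre_window: float = 10.0
    pulse_frequency: float = 1.0
    pulse_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.stim_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("stimulus and rest durations must be positive")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.pre_window < 0:
            raise ValueError("pre_window must be non-negative")
        if self.pulse_frequency * self.pulse_duration > 1:
            raise ValueError("pulse duty cycle exceeds 1")

    @property
    def cycle_duration(self) -> float:
        return self.stim_duration + self.rest_duration

    @property
    def onsets(self) -> np.ndarray:
        return self.pre_window + np.arange(self.n_blocks) * self.cycle_duration

    @property
    def total_duration(self) -> float:
        """Duration covered by pre-window plus all block cycles."""
        return self.pre_window + self.n_blocks * self.cycle_duration


@dataclass
class DesignMatrix:
    """GLM design: one row per analyzed volume, labeled columns."""

    matrix: np.ndarray
    names: list[str]
    task_columns: list[int] = field(default_factory=list)
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count and names differ")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.names).to_csv(
            path, sep="\t", index=False)


def boxcar(paradigm: BlockParadigm, dt: float,
           pulse_level: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus indicator on a fine grid covering the whole paradigm.

    Returns ``(time, values)`` with value 1 during stimulation and 0
    otherwise.  With ``pulse_level=True`` each block is rendered as its
    pulse train instead of a continuous envelope.
    """
    ratio = paradigm.TR / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"dt={dt} must divide TR={paradigm.TR} evenly")
    n = int(round(paradigm.total_duration / dt))
    t = np.arange(n) * dt
    values = np.zeros(n)
    for onset in paradigm.onsets:
        if pulse_level:
            n_pulses = int(round(paradigm.stim_duration * paradigm.pulse_frequency))
            for k in range(n_pulses):
                start = onset + k / paradigm.pulse_frequency
                values[(t >= start) & (t < start + paradigm.pulse_duration)] = 1.0
        else:
            values[(t >= onset) & (t < onset + paradigm.stim_duration)] = 1.0
    return t, values


def convolve_with_hrf(stimulus: np.ndarray, hrf: HRFCurve, TR: float,
                      dt: float, n_volumes: int) -> np.ndarray:
    """Convolve a fine-grid stimulus with an HRF and sample at scan times.

    The discrete convolution is computed on the common fine grid
    (spacing ``dt``, shared by stimulus and HRF), truncated to the scan
    window and sampled at the volume acquisition times ``k * TR``.
    """
    if abs(hrf.dt - dt) > 1e-9:
        raise ValueError("stimulus and HRF grids have different spacing")
    full = np.convolve(stimulus, hrf.values) * dt
    idx = np.round(np.arange(n_volumes) * TR / dt).astype(int)
    if idx[-1] >= full.size:
        raise ValueError("scan window extends past the convolved support")
    return full[idx]


def task_regressor(paradigm: BlockParadigm, params: HRFParams,
                   n_volumes: int, dt: float = 0.05,
                   normalize: bool = False) -> np.ndarray:
    """HRF-convolved block regressor sampled at the analyzed volumes."""
    _, stim = boxcar(paradigm, dt)
    hrf_curve = evaluate_hrf(params, default_grid(30.0, dt))
    reg = convolve_with_hrf(stim, hrf_curve, paradigm.TR, dt, n_volumes)
    if normalize:
        m = np.max(np.abs(reg))
        if m > 0:
            reg = reg / m
    return reg


def _nuisance(n_volumes: int, drift: bool) -> tuple[list[np.ndarray], list[str]]:
    cols = [np.ones(n_volumes)]
    names = ["intercept"]
    if drift:
        ramp = np.linspace(-1.0, 1.0, n_volumes)
        cols.append(ramp)
        names.append("drift")
    return cols, names


def build_canonical_design(paradigm: BlockParadigm, params: HRFParams,
                           order: int = 1, n_volumes: int = 600,
                           dt: float = 0.05, drift: bool = True) -> DesignMatrix:
    """Canonical design: HRF regressor, optionally with derivatives.

    Order 1 uses the HRF-convolved paradigm alone; order 3 adds the
    temporal and dispersion derivative regressors.
    """
    if order not in (1, 3):
        raise ValueError(f"canonical order must be 1 or 3, got {order}")
    grid = default_grid(30.0, dt)
    _, stim = boxcar(paradigm, dt)
    hrf_curve = evaluate_hrf(params, grid)
    cols = [convolve_with_hrf(stim, hrf_curve, paradigm.TR, dt, n_volumes)]
    names = ["task_hrf"]
    if order == 3:
        td, dd = hrf_basis_derivatives(params, grid)
        cols.append(convolve_with_hrf(stim, td, paradigm.TR, dt, n_volumes))
        cols.append(convolve_with_hrf(stim, dd, paradigm.TR, dt, n_volumes))
        names += ["task_temporal_deriv", "task_dispersion_deriv"]
    task_idx = list(range(len(cols)))
    nuis, nuis_names = _nuisance(n_volumes, drift)
    frame_times = np.arange(n_volumes) * paradigm.TR
    return DesignMatrix(np.column_stack(cols + nuis), names + nuis_names,
                        task_columns=task_idx, frame_times=frame_times)


def build_fir_design(paradigm: BlockParadigm, order: int = 9,
                     window: float = 30.0, n_volumes: int = 600,
                     drift: bool = True) -> DesignMatrix:
    """FIR design: ``order`` contiguous post-onset boxcar bins.

    Bin ``k`` covers ``[onset + k*window/order, onset + (k+1)*window/order)``
    of every block; its column is 1 for volumes acquired inside that bin.
    The default window of 30 s tiles one block cycle exactly.
    """
    if order < 1:
        raise ValueError("FIR order must be >= 1")
    if window <= 0:
        raise ValueError("FIR window must be positive")
    width = window / order
    if width < paradigm.TR:
        raise ValueError(
            f"FIR bin width {width:.3f}s is below TR={paradigm.TR}s")
    frame_times = np.arange(n_volumes) * paradigm.TR
    cols = np.zeros((n_volumes, order))
    for onset in paradigm.onsets:
        rel = frame_times - onset
        in_window = (rel >= 0) & (rel < window)
        bins = np.floor(rel[in_window] / width).astype(int)
        bins = np.clip(bins, 0, order - 1)
        cols[np.flatnonzero(in_window), bins] = 1.0
    names = [f"fir_{k:02d}" for k in range(order)]
    nuis, nuis_names = _nuisance(n_volumes, drift)
    return DesignMatrix(np.column_stack([cols] + nuis), names + nuis_names,
                        task_columns=list(range(order)),
                        frame_times=frame_times)


def write_events(paradigm: BlockParadigm, path,
                 trial_type: str = "stim") -> None:
    """Write the paradigm as a tab-separated events table."""
    df = pd.DataFrame({
        "onset": paradigm.onsets,
        "duration": np.full(paradigm.n_blocks, paradigm.stim_duration),
        "trial_type": trial_type,
    })
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read a tab-separated events table (onset, duration, trial_type)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration"}
    if not required.issubset(df.columns):
        raise ValueError(f"events table must contain columns {sorted(required)}")
    return df
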