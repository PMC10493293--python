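"""Two-gamma hemodynamic response function (HRF) model.

The HRF is the impulse response linking neural activity to the BOLD
signal.  It is modelled as the difference of two gamma-density-shaped
terms, the first producing the main positive peak and the second the
post-stimulus undershoot::

    HRF(t) = A * exp(-b*t) * ( b**p1 / Gamma(p1) * t**(p1-1)
                             - b**p2 / (V * Gamma(p2)) * t**(p2-1) )

with amplitude ``A``, dispersion/rate ``b`` (1/s), peak shape ``p1``,
undershoot shape ``p2`` and peak-to-undershoot ratio ``V``.  The
whole-brain mouse parameter set and the standard human canonical set
are shipped as presets; rodent presets for other species are loaded
from parameter files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import gammaln

__all__ = [
    "HRFParams",
    "HRFCurve",
    "HRFSummary",
    "MOUSE",
    "HUMAN",
    "evaluate_hrf",
    "hrf_basis_derivatives",
    "characterize_hrf",
    "normalize_to_max",
    "default_grid",
    "save_params",
    "load_params",
]


class ParameterDomainError(ValueError):
    """Raised when HRF parameters violate the model's domain."""


class DegenerateCurveError(ValueError):
    """Raised when a curve lacks the structure an operation requires."""


@dataclass(frozen=True)
class HRFParams:
    """Parameters of the two-gamma HRF.

    A : amplitude scale (dimensionless after normalization)
    b : dispersion/rate parameter, 1/s
    p1 : shape parameter of the peak gamma term (> 1)
    p2 : shape parameter of the undershoot gamma term (> p1)
    V : ratio of peak to undershoot amplitude (> 0)
    """

    A: float = 1.0
    b: float = 1.0
    p1: float = 6.0
    p2: float = 16.0
    V: float = 6.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.A, self.b, self.p1, self.p2, self.V]).all():
            raise ParameterDomainError("HRF parameters must be finite")
        if self.A == 0:
            raise ParameterDomainError("amplitude A must be nonzero")
        if self.b <= 0:
            raise ParameterDomainError(f"dispersion b must be > 0, got {self.b}")
        if self.p1 <= 1:
            raise ParameterDomainError(f"p1 must be > 1, got {self.p1}")
        if self.p2 <= self.p1:
            raise ParameterDomainError(
                f"p2 must exceed p1, got p1={self.p1}, p2={self.p2}"
            )
        if self.V <= 0:
            raise ParameterDomainError(f"ratio V must be > 0, got {self.V}")

    def replace(self, **kwargs) -> "HRFParams":
        d = asdict(self)
        d.update(kwargs)
        return HRFParams(**d)


#: Whole-brain mouse HRF (mechanical hind-paw stimulation under
#: medetomidine/isoflurane sedation).
MOUSE = HRFParams(A=1.0, b=0.9, p1=4.5, p2=7.9, V=1.8)

#: Standard human canonical two-gamma HRF expressed in this
#: parameterization (rate 1/s, peak shape 6, undershoot shape 16,
#: undershoot ratio 6).
HUMAN = HRFParams(A=1.0, b=1.0, p1=6.0, p2=16.0, V=6.0)


@dataclass
class HRFCurve:
    """An HRF (or any response curve) sampled on a uniform time grid."""

    time: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.size == 0:
            raise ValueError("empty time grid")
        if self.time.size != self.values.size:
            raise ValueError("time and values must have the same length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("curve values must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class HRFSummary:
    """Shape descriptors of an HRF curve (all times in seconds)."""

    time_to_peak: float
    peak_value: float
    fwhm: float
    time_to_undershoot: float
    undershoot_value: float


def default_grid(t_max: float = 30.0, dt: float = 0.05) -> np.ndarray:
    """Uniform grid [0, t_max] with spacing dt (sub-TR resolution)."""
    n = int(round(t_max / dt))
    return np.arange(n + 1) * dt


def _eval_at(params: HRFParams, t: np.ndarray) -> np.ndarray:
    """Two-gamma HRF at arbitrary times; 0 for t <= 0."""
    values = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    logt = np.log(tp)
    peak = np.exp(params.p1 * np.log(params.b) - gammaln(params.p1)
                  + (params.p1 - 1.0) * logt - params.b * tp)
    under = np.exp(params.p2 * np.log(params.b) - gammaln(params.p2)
                   + (params.p2 - 1.0) * logt - params.b * tp) / params.V
    values[pos] = params.A * (peak - under)
    return values


def evaluate_hrf(params: HRFParams, grid: np.ndarray) -> HRFCurve:
    """Evaluate the two-gamma HRF on a time grid starting at 0.

    Computed in log space (log-gamma based) for numerical stability at
    large shape parameters; the value at t = 0 is exactly 0 because
    both shape parameters exceed 1.
    """
    t = np.asarray(grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if t[0] != 0.0:
        raise ValueError("grid must start at 0")
    return HRFCurve(time=t, values=_eval_at(params, t))


def hrf_basis_derivatives(
    params: HRFParams,
    grid: np.ndarray,
    time_step: float = 0.1,
    dispersion_step: float = 0.01,
) -> tuple[HRFCurve, HRFCurve]:
    """Temporal and dispersion derivative curves for the canonical basis.

    The temporal derivative is the finite difference of the HRF under a
    small onset shift (``time_step`` seconds); the dispersion derivative
    is the finite difference under a small relative perturbation of the
    rate parameter ``b`` (``dispersion_step`` as a fraction of ``b``).
    Both are returned on the input grid.
    """
    if time_step <= 0 or dispersion_step <= 0:
        raise ValueError("finite-difference steps must be positive")
    t = np.asarray(grid, dtype=float)
    base = evaluate_hrf(params, t)

    # onset shift: HRF evaluated at t - step (zero before onset)
    shifted = _eval_at(params, t - time_step)
    temporal = (base.values - shifted) / time_step

    db = params.b * dispersion_step
    perturbed = evaluate_hrf(params.replace(b=params.b + db), t)
    dispersion = (base.values - perturbed.values) / db

    return (HRFCurve(time=t, values=temporal),
            HRFCurve(time=t, values=dispersion))


def characterize_hrf(curve: HRFCurve) -> HRFSummary:
    """Summarize an HRF curve: peak timing, FWHM and undershoot.

    FWHM is the width of the contiguous interval around the peak where
    the curve is at or above half the maximum, with linear interpolation
    between grid points.  The undershoot is the minimum after the peak.
    """
    y = curve.values
    t = curve.time
    i_peak = int(np.argmax(y))
    peak = y[i_peak]
    if peak <= 0:
        raise DegenerateCurveError("curve has no positive peak")
    half = peak / 2.0

    i = i_peak
    while i > 0 and y[i - 1] >= half:
        i -= 1
    if i == 0:
        t_left = t[0]
    else:
        t_left = t[i - 1] + (half - y[i - 1]) / (y[i] - y[i - 1]) * (t[i] - t[i - 1])

    j = i_peak
    while j < y.size - 1 and y[j + 1] >= half:
        j += 1
    if j == y.size - 1:
        t_right = t[-1]
    else:
        t_right = t[j] + (half - y[j]) / (y[j + 1] - y[j]) * (t[j + 1] - t[j])

    after = y[i_peak:]
    i_min = i_peak + int(np.argmin(after))
    return HRFSummary(
        time_to_peak=float(t[i_peak]),
        peak_value=float(peak),
        fwhm=float(t_right - t_left),
        time_to_undershoot=float(t[i_min]),
        undershoot_value=float(y[i_min]),
    )


def normalize_to_max(curve: HRFCurve) -> HRFCurve:
    """Scale a curve so its maximum equals 1 (shape-preserving)."""
    m = float(np.max(curve.values))
    if m <= 0:
        raise DegenerateCurveError("cannot normalize a curve with non-positive maximum")
    return HRFCurve(time=curve.time.copy(), values=curve.values / m)


def save_params(params: HRFParams, path, species: str = "", source: str = "") -> None:
    """Write an HRF parameter file (JSON) reusable by GLM software."""
    payload = {
        "A": params.A, "b": params.b, "p1": params.p1,
        "p2": params.p2, "V": params.V,
        "species": species, "source": source,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_params(path) -> HRFParams:
    """Read an HRF parameter file written by :func:`save_params`."""
    d = json.loads(Path(path).read_text())
    return HRFParams(A=d["A"], b=d["b"], p1=d["p1"], p2=d["p2"], V=d["V"])
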