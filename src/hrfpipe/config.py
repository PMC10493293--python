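"""Run configuration: paradigm, basis choice, thresholds, seeds.

Defaults are the study conditions this package targets: TR 1 s, 620
volumes (20 discarded), 20 blocks of 10 s stimulation / 20 s rest,
uncorrected p < 0.05 with cluster extent > 5 voxels, amplitude >= 0.6%,
decay >= 40%, NMSE <= 0.1, more than 4 positive voxels per structure,
n >= 6 per group for testing, 10,000 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .design import BlockParadigm
from .hrf import HRFParams, MOUSE, HUMAN, load_params


@dataclass
class RunConfig:
    """Validated configuration of a simulation or analysis run."""

    data_dir: str = "dataset"
    out_dir: str = "results"
    paradigm: BlockParadigm = field(default_factory=BlockParadigm)
    basis: str = "fir9"                   # fir9 | canonical1 | canonical3
    hrf_source: str = "mouse"             # mouse | human | path to JSON
    alpha: float = 0.05
    min_cluster: int = 5
    amp_min: float = 0.6
    decay_min: float = 0.4
    nmse_max: float = 0.1
    min_voxels: int = 4                   # structures need more than this
    min_n: int = 6
    n_permutations: int = 10_000
    smoothing_window: float = 5.0
    smooth_before_fit: bool = False
    seed: int = 0
    # synthetic generation
    dims: tuple[int, int, int] = (24, 24, 12)
    n_structures: int = 30
    n_volumes: int = 620
    n_discard: int = 20
    responder_fraction: float = 0.0836
    response_amplitude_mean: float = 0.838
    response_amplitude_sd: float = 0.1
    noise_sd: float = 1.0
    drift_slope: float = 0.0
    negative_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.basis not in {"fir9", "canonical1", "canonical3"}:
            raise ValueError(f"unknown basis {self.basis!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("min_cluster", "min_voxels", "min_n", "n_permutations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.amp_min < 0 or not (0 <= self.decay_min <= 1):
            raise ValueError("invalid polarity thresholds")
        if self.nmse_max <= 0:
            raise ValueError("nmse_max must be positive")

    def hrf_params(self) -> HRFParams:
        if self.hrf_source == "mouse":
            return MOUSE
        if self.hrf_source == "human":
            return HUMAN
        return load_params(self.hrf_source)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dims"] = list(self.dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "paradigm" in d and isinstance(d["paradigm"], dict):
            d["paradigm"] = BlockParadigm(**d["paradigm"])
        if "dims" in d:
            d["dims"] = tuple(d["dims"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
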