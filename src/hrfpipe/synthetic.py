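"""Synthetic block-design BOLD datasets with known ground truth.

Emulates the study acquisition this package targets: TR 1 s, 620
volumes with the first 20 discarded, a 20-block 10 s / 20 s mechanical
stimulation paradigm, an integer-labeled atlas of 30 brain structures,
~8.4% of in-brain voxels carrying positive BOLD responses of ~0.84%
amplitude around a baseline of 100 (so raw values read directly as
percent signal change + 100).

Responder voxels are placed as contiguous blobs (grown from seeds
inside the brain mask) rather than scattered singletons: real BOLD
activation is spatially clustered, and the cluster-extent filter in
detection presumes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .design import BlockParadigm, task_regressor, write_events
from .hrf import HRFParams, MOUSE

__all__ = [
    "SyntheticSpec",
    "LabeledDataset",
    "generate_atlas",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

BASELINE = 100.0

_NEIGHBOR_OFFSETS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of a synthetic acquisition.

    Fractions are proportions of in-brain voxels; amplitudes and noise
    are in percent signal change around the baseline of 100.
    """

    dims: tuple[int, int, int] = (24, 24, 12)
    n_structures: int = 30
    TR: float = 1.0
    n_volumes: int = 620
    n_discard: int = 20
    responder_fraction: float = 0.0836
    response_amplitude_mean: float = 0.838
    response_amplitude_sd: float = 0.1
    hrf_params: HRFParams = field(default_factory=lambda: MOUSE)
    noise_sd: float = 1.0
    drift_slope: float = 0.0
    negative_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        if not (0 <= self.responder_fraction <= 1):
            raise ValueError("responder_fraction must be in [0, 1]")
        if not (0 <= self.negative_fraction <= 1):
            raise ValueError("negative_fraction must be in [0, 1]")
        if self.n_discard >= self.n_volumes:
            raise ValueError("n_discard must be below n_volumes")
        if self.noise_sd < 0 or self.response_amplitude_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def n_analyzed(self) -> int:
        return self.n_volumes - self.n_discard


@dataclass
class LabeledDataset:
    """4D signal + atlas labels + per-voxel ground truth."""

    data: np.ndarray            # (x, y, z, t), raw signal (baseline 100)
    labels: np.ndarray          # (x, y, z) int, 0 = background
    truth: dict                 # per-voxel responder record
    spec: SyntheticSpec | None = None
    paradigm: BlockParadigm | None = None

    def __post_init__(self) -> None:
        if self.data.shape[:3] != self.labels.shape:
            raise ValueError("data and label volumes have different spatial dims")

    @property
    def analyzed(self) -> np.ndarray:
        """Signal with pre-steady-state volumes discarded."""
        n_discard = self.spec.n_discard if self.spec is not None else 0
        return self.data[..., n_discard:]


def _brain_mask(dims: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid inscribed in the volume, a stand-in skull strip."""
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    r2 = sum(((g - (d - 1) / 2.0) / (d / 2.0)) ** 2
             for g, d in zip(grids, dims))
    return r2 <= 1.0


def _grow_regions(mask: np.ndarray, seeds: np.ndarray,
                  rng: np.random.Generator,
                  max_total: int | None = None) -> np.ndarray:
    """Multi-source seeded region growth on the 6-neighborhood.

    Regions expand one voxel at a time in round-robin random order
    until the mask is exhausted (or ``max_total`` voxels assigned),
    producing contiguous, roughly compact parcels.
    """
    labels = np.zeros(mask.shape, dtype=np.int32)
    frontiers: list[list[tuple[int, int, int]]] = []
    for i, s in enumerate(seeds, start=1):
        labels[tuple(s)] = i
        frontiers.append([tuple(s)])
    assigned = len(seeds)
    dims = np.array(mask.shape)
    active = list(range(len(seeds)))
    while active and (max_total is None or assigned < max_total):
        for li in list(active):
            if max_total is not None and assigned >= max_total:
                break
            frontier = frontiers[li]
            grown = False
            while frontier and not grown:
                j = rng.integers(len(frontier))
                vox = np.array(frontier[j])
                cand = vox + _NEIGHBOR_OFFSETS
                ok = np.all((cand >= 0) & (cand < dims), axis=1)
                free = [tuple(c) for c in cand[ok]
                        if mask[tuple(c)] and labels[tuple(c)] == 0]
                if free:
                    pick = free[rng.integers(len(free))]
                    labels[pick] = li + 1
                    frontier.append(pick)
                    assigned += 1
                    grown = True
                else:
                    frontier[j] = frontier[-1]
                    frontier.pop()
            if not grown:
                active.remove(li)
    return labels


def generate_atlas(dims: tuple[int, int, int], n_structures: int = 30,
                   seed: int = 0) -> np.ndarray:
    """Parcellate an ellipsoidal brain mask into contiguous structures.

    Deterministic given the seed; every structure is a single
    6-connected component of at least 10 voxels.
    """
    mask = _brain_mask(dims)
    n_brain = int(mask.sum())
    if n_structures > n_brain // 10:
        raise ValueError(
            f"cannot fit {n_structures} structures of >=10 voxels into "
            f"{n_brain} in-brain voxels")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask)
    seeds = coords[rng.choice(n_brain, size=n_structures, replace=False)]
    return _grow_regions(mask, seeds, rng)


def _responder_blobs(labels: np.ndarray, n_target: int,
                     rng: np.random.Generator,
                     blob_size_range: tuple[int, int] = (6, 14)) -> np.ndarray:
    """Boolean responder mask: contiguous blobs totalling ~n_target voxels."""
    mask = labels > 0
    responders = np.zeros(mask.shape, dtype=bool)
    coords = np.argwhere(mask)
    placed = 0
    while placed < n_target:
        # every blob >= the minimum size so true activation is never
        # erased by the cluster-extent filter downstream
        size = int(rng.integers(blob_size_range[0], blob_size_range[1]))
        size = max(blob_size_range[0], min(size, n_target - placed))
        free = ~responders & mask
        free_coords = coords[free[tuple(coords.T)]]
        if free_coords.size == 0:
            break
        seed_vox = free_coords[rng.integers(len(free_coords))]
        blob = _grow_regions(free, seed_vox[None, :], rng, max_total=size)
        responders |= blob > 0
        placed = int(responders.sum())
    return responders


def generate_dataset(spec: SyntheticSpec,
                     paradigm: BlockParadigm | None = None) -> LabeledDataset:
    """Generate a labeled 4D BOLD dataset with recorded ground truth.

    Responder voxels carry ``amplitude * peak-normalized (HRF (*)
    paradigm)`` on top of baseline, drift and i.i.d. Gaussian noise;
    a configurable fraction of responders is sign-inverted.  The
    response occupies the analyzed window (volumes after ``n_discard``).
    Bit-reproducible given ``spec.seed``.
    """
    if paradigm is None:
        paradigm = BlockParadigm(TR=spec.TR)
    rng = np.random.default_rng(spec.seed)
    labels = generate_atlas(spec.dims, spec.n_structures,
                            seed=int(rng.integers(2**31)))
    mask = labels > 0
    n_brain = int(mask.sum())
    n_responders = int(round(spec.responder_fraction * n_brain))
    responders = _responder_blobs(labels, n_responders, rng)

    reg = task_regressor(paradigm, spec.hrf_params,
                         n_volumes=spec.n_analyzed, dt=0.05, normalize=True)
    n_t = spec.n_volumes
    data = np.full(spec.dims + (n_t,), BASELINE)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    if spec.drift_slope != 0.0:
        data += spec.drift_slope * np.arange(n_t)

    resp_coords = np.argwhere(responders)
    amplitudes = np.full(len(resp_coords), spec.response_amplitude_mean)
    if spec.response_amplitude_sd > 0:
        amplitudes += rng.normal(0.0, spec.response_amplitude_sd,
                                 size=len(resp_coords))
    signs = np.ones(len(resp_coords))
    if spec.negative_fraction > 0:
        signs[rng.random(len(resp_coords)) < spec.negative_fraction] = -1.0
    for (x, y, z), amp, sign in zip(resp_coords, amplitudes, signs):
        data[x, y, z, spec.n_discard:] += sign * amp * reg

    truth = {
        "responders": [
            {"voxel": [int(x), int(y), int(z)],
             "amplitude": float(a), "sign": int(s),
             "structure": int(labels[x, y, z])}
            for (x, y, z), a, s in zip(resp_coords, amplitudes, signs)
        ],
        "hrf_params": {k: float(v) for k, v in asdict(spec.hrf_params).items()},
        "n_brain_voxels": n_brain,
        "responder_fraction_realized": float(len(resp_coords) / n_brain),
        "seed": spec.seed,
    }
    return LabeledDataset(data=data, labels=labels, truth=truth,
                          spec=spec, paradigm=paradigm)


def write_dataset(dataset: LabeledDataset, outdir) -> dict[str, Path]:
    """Write 4D NIfTI, label NIfTI, events TSV and truth/spec JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": outdir / "bold.nii",
        "labels": outdir / "labels.nii",
        "events": outdir / "events.tsv",
        "truth": outdir / "truth.json",
        "spec": outdir / "spec.json",
    }
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(dataset.data.astype(np.float32), affine),
             paths["bold"])
    nib.save(nib.Nifti1Image(dataset.labels.astype(np.int16), affine),
             paths["labels"])
    paradigm = dataset.paradigm or BlockParadigm()
    write_events(paradigm, paths["events"])
    paths["truth"].write_text(json.dumps(dataset.truth, indent=2) + "\n")
    spec_d = asdict(dataset.spec) if dataset.spec else {}
    if spec_d:
        spec_d["hrf_params"] = asdict(dataset.spec.hrf_params)
    spec_d["paradigm"] = asdict(paradigm)
    paths["spec"].write_text(json.dumps(spec_d, indent=2) + "\n")
    return paths


def read_dataset(outdir) -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`."""
    outdir = Path(outdir)
    data = np.asarray(nib.load(outdir / "bold.nii").dataobj, dtype=np.float64)
    labels = np.asarray(nib.load(outdir / "labels.nii").dataobj).astype(np.int32)
    truth = json.loads((outdir / "truth.json").read_text())
    spec = None
    paradigm = None
    spec_path = outdir / "spec.json"
    if spec_path.exists():
        d = json.loads(spec_path.read_text())
        pd_ = d.pop("paradigm", None)
        if pd_:
            paradigm = BlockParadigm(**pd_)
        if d:
            d["dims"] = tuple(d["dims"])
            d["hrf_params"] = HRFParams(**d["hrf_params"])
            spec = SyntheticSpec(**d)
    return LabeledDataset(data=data, labels=labels, truth=truth,
                          spec=spec, paradigm=paradigm)
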