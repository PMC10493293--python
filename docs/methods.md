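# Methods

## Model

The hemodynamic response function is parameterized as the difference of
two gamma-density-shaped terms,

HRF(t) = A·e^(−bt)·( b^p1/Γ(p1)·t^(p1−1) − b^p2/(V·Γ(p2))·t^(p2−1) ),

evaluated in log space (log-Γ based) for stability at large shape
parameters. The value at t = 0 is exactly 0 because both shape
parameters exceed 1. Parameter domain: b > 0, p1 > 1, p2 > p1, V > 0,
A ≠ 0. The first term produces the positive peak, the second the
post-stimulus undershoot; V sets their amplitude ratio. Time constants:
the mouse preset peaks near 3.5 s with the undershoot minimum near
10 s; the human canonical preset peaks at 5.0 s with a 5.3 s FWHM.

The linear BOLD model assumes the measured response is the convolution
of the HRF with the stimulus envelope. The 1 Hz / 0.5 s pulse train
inside each 10 s stimulation block is modeled as a continuous boxcar:
pulse substructure lies far above the HRF's cutoff frequency and is
invisible after convolution. A pulse-level stimulus is available
(`boxcar(..., pulse_level=True)`) for sensitivity checks.

## Timing conventions

TR 1 s, 620 acquired volumes, first 20 discarded (pre-steady-state),
600 analyzed volumes. The first stimulus onset is placed 10 s into the
analyzed series, so the 20 cycles of 30 s tile the analyzed window
exactly and every cycle carries a 10 s pre-onset context. Epoch curves
live on a 30 s window with the stimulus at 10 s; the baseline is the
10 s pre-onset segment, and percent signal change is taken against the
baseline-window mean. Volumes are stamped at k·TR from the start of the
analyzed series.

Grids: fine grid dt = 0.05 s for convolution (sub-TR resolution, 30 s
HRF support — the two-gamma presets are below 1e−4 of peak by 30 s);
dt = 0.01 s for curve characterization (FWHM interpolation error
< 0.01 s); dt = 0.1 s for functional-test curves (the max-t statistic
is insensitive to grid refinement at HRF smoothness).

## Canonical and FIR bases

The order-1 canonical design has one task regressor (HRF ⊗ paradigm);
order 3 adds the temporal derivative (finite difference under a 0.1 s
onset shift) and dispersion derivative (finite difference under a 1%
perturbation of b) — conventional finite-difference basis construction.
The FIR design uses 9 contiguous post-onset boxcar bins spanning a 30 s
window, i.e. bins of 10/3 s tiling one block cycle; this estimates the
response shape without assuming an HRF. Nuisance columns: intercept
always, linear drift when the data carry drift.

## Detection

Per-voxel OLS. A single task column is tested with a one-sided t (the
extracted responses are positive BOLD); multi-column task sets
(canonical order 3, FIR) with an F over the task block via the general
linear hypothesis. On noise-free voxels both the effect and residual
sums of squares can be exactly zero; these 0/0 voxels get statistic 0
and p = 1 (threshold 1e−9 relative to problem size). Thresholding is
p < 0.05 (strict) with removal of connected components of ≤ 5 voxels on
the 6-neighborhood (faces); the connectivity is a package choice.
Dice similarity between binarized maps uses 2|A∩B|/(|A|+|B|), defined
as 1 for two empty masks; probability maps are binarized at > 0 by
default (configurable — the right binarization level is genuinely open).

## Extraction and polarity

Voxel series from the intersection of the activation mask and each
atlas structure are smoothed with a 5 s centered moving average
(shrinking windows at the edges), epoch-averaged, and classified:
positive requires a peak ≥ 0.6% signal change and a post-peak decay of
≥ 40% of the peak; negative applies the same rules to the inverted
curve. Smoothing is applied before polarity classification only; the
curve passed to HRF fitting is the unsmoothed epoch average (the
smoothed-fit variant is available via `smooth_before_fit`). Structures
enter fitting only with more than four positive voxels (≥ 5).

## Fitting

Bounded nonlinear least squares (scipy trust-region reflective) on
residuals between the measured epoch curve and the model prediction.
The prediction follows the same path as the data: full-paradigm
convolution, folding over cycles, baseline subtraction — so noise-free
curves are recovered to optimizer tolerance. Bounds: b ∈ [0.1, 5],
p1 ∈ [1.5, 15], p2 − p1 ∈ [0.5, 28.5] (internal reparameterization that
keeps p2 > p1 inside a box-bound optimizer), V ∈ [0.2, 20],
A ∈ [1e−4, 1e3]. Eight multi-starts: the first at (peak amplitude,
b=1, p1=5, p2=10, V=2), the rest log-normally jittered (σ = 0.3) under
a fixed seed; the lowest-cost converged solution wins.

Quality control: NMSE = mean squared residual / variance of the
measured curve (so a flat fit at the data mean scores exactly 1);
fits with NMSE > 0.1 are excluded. Onset = first time the fitted curve
exceeds 10% of its peak; onsets before 10 s (response before the
stimulus, which the cycle-wrapped prediction of an implausibly slow HRF
can produce) are excluded. Exclusion is monotone in the NMSE threshold.

The whole-brain HRF is the pointwise mean of the included HRFs after
peak normalization, re-normalized and re-fitted with the two-gamma form
to obtain parameters. Parameter vectors are not averaged: the family is
not closed under parameter averaging, while the mean normalized curve
is the object the downstream GLM consumes.

## Functional statistics

Pointwise statistic t(τ) = |x̄(τ) − ȳ(τ)| / √(var_x(τ)/n_x +
var_y(τ)/n_y) with ddof = 1 variances. Numerics: mean differences below
1e−12 of the sample scale are float-summation noise and treated as
exact ties (t = 0); a vanishing denominator with a real numerator is
guarded by a variance floor of 1e−12 of the squared sample scale.

The max-t over τ is calibrated by permuting group labels. p = N/B with
N the count of permutations whose max-t *strictly* exceeds the observed
(ties do not count); the (N+1)/(B+1) variant is deliberately not the
default. Relabelings are sampled uniformly with replacement; when the
number of distinct splits is at most the permutation budget the test
enumerates all splits and p is exact. The observed max-t is computed
through the same vectorized code path as the permuted ones so that
group-preserving relabelings tie bit-exactly. Note that for two
samples that are identical as multisets, relabelings preserving the
multisets also tie, so the exact p is (C(2n,n) − 2^n)/C(2n,n), slightly
below 1.

Comparisons run only when both groups have n ≥ 6 curves; the Bonferroni
threshold is α divided by the realized number of comparisons, displayed
rounded to 4 decimal places (0.05/210 → 0.0002, 0.05/78 → 0.0006,
0.05/6 → 0.0083, 0.05/10 → 0.005).

## Synthetic data

The generator emulates the target acquisition: baseline 100 (raw
values read as percent change + 100), TR 1 s, 620 volumes (20
discarded), a 30-structure atlas grown by seeded region growth inside
an ellipsoidal brain mask (every structure a connected component of
≥ 10 voxels), 8.36% of in-brain voxels carrying responses of 0.838%
mean amplitude (per-voxel SD 0.1% — within-dataset voxel variability),
i.i.d. Gaussian noise of 1% SD per volume by default (temporal SNR
~100, typical for cryoprobe mouse fMRI), optional linear drift and
sign-inverted responders. Responder voxels are placed as contiguous
blobs of at least 6 voxels: BOLD activation is spatially clustered, and
the cluster-extent filter presumes it — scattered singleton responders
would be erased by design. Everything is bit-reproducible from the
seed.

What the generator does not emulate: spatial autocorrelation of noise,
motion, physiological (cardiac/respiratory) signal, scanner drift
nonlinearity, partial-volume effects, or hemispheric asymmetry. Passing
tests therefore demonstrate correctness of the estimation machinery
under the stated signal model, not robustness to every artifact of real
acquisitions.

## Problem sizes

Test and script runs use small grids (16–24 voxels per axis, ~2–7k
in-brain voxels) with the full 620-volume time dimension; detection,
extraction and fitting behavior is voxel-local, so spatial size only
scales the workload. The null calibration of the max-t test uses 200
replicates of two groups of 10 curves with 1,000 permutations each,
vectorized over permutations via 0/1 membership matrix products.

## Known limitations

- The epoch model fixes the response onset to the stimulus; early
  onsets arise only through cycle wrap-around of slow candidate HRFs,
  so the onset QC rule prunes implausible fits rather than measuring
  a free onset parameter.
- The five-parameter fit is poorly conditioned against a single noisy
  30-sample epoch curve (b and p1 trade off strongly); reliable
  parameter recovery requires the cycle- and voxel-averaging the
  pipeline performs upstream.
- Negative (inverted) responses are classified but not fitted.
- Rat HRF parameters are accepted via parameter files only; no rat
  preset ships with the package.
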