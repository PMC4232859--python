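# Methods

This document records the models implemented, the default parameters, what
the synthetic scenario contains and shows, and the numerical choices and
known limitations.

## Stimulus control: phase scrambling

A control image is built by keeping the 2D Fourier amplitude spectrum of
the original and replacing every phase with the phase of a seeded uniform
white-noise image of the same size. Because the noise image is real, its
phase field is Hermitian-symmetric, so the inverse transform is real up to
rounding. Self-conjugate bins (DC and Nyquist combinations), where a real
image's spectrum must be real, keep the original phases; this also
preserves mean luminance exactly. Original/scrambled pairs are normalized
with one shared affine map whose parameters come from the scrambled
image's minimum and maximum, either as `p → (p − min)/(min + max)`
("as_printed") or the conventional `p → (p − min)/(max − min)`.

## Forward model

The magnetic field of a current dipole in a spherical volume conductor has
a closed form: with positions taken relative to the sphere centre, dipole
at `r0` with moment `q`, field point `r`, `a = r − r0`,

    F  = a (r a + r² − r0·r)
    ∇F = (a²/r + a·r/a + 2a + 2r) r − (a + 2r + a·r/a) r0
    B  = µ0/(4πF²) · (F q×r0 − (q×r0 · r) ∇F)

The result is independent of the sphere radius and exactly zero for radial
moments, so each voxel's leadfield is a two-column matrix spanning the
local tangential plane. The head model is a single origin-centred sphere
(radius 0.09 m) by default, with per-channel local spheres supported;
channels are point magnetometers by default, with an optional two-point
axial gradiometer. Source grids are spheres of radius 0.075 m.

## Sensor-level analysis

- Filtering: Butterworth band-pass applied forward and backward
  (`sosfiltfilt`, zero phase lag). Order 3 for sensor-level inspection,
  order 4 before covariance estimation. Epochs are mirror-padded by 0.5 s
  before filtering.
- ERFs are per-condition trial averages, baseline-corrected over
  (−0.15, 0) s; GFP is the RMS over channels.
- Evoked windows of interest: local minima of the smoothed grand-average
  GFP inside (0.05, 0.4) s partition the post-stimulus interval.
- Induced windows of interest: per-participant Hilbert amplitude
  spectrograms (percent change from a pre-stimulus baseline) are tested
  point-wise across participants with a two-sided exact Wilcoxon
  signed-rank test; p-values are pooled over the whole
  frequency × time × sensor family and thresholded with
  Benjamini–Hochberg FDR at q = 0.05, significant sensors are counted per
  time–frequency cell, and 4-connected supra-threshold components (at
  least 10% of sensors, minimum area 10 cells) become the analysis bands
  and windows.

## Beamformer

The SAM scalar beamformer forms, per voxel, `w = C⁻¹l/(lᵀC⁻¹l)` with
`l = L η`. `C` is the covariance of band-passed, unaveraged trial data
with diagonal regularization `µ·mean(diag(C))·I`, µ = 0.05. The
orientation `η` maximizes the unit-gain source power `1/(lᵀC⁻¹l)` by a
dense angular search in 1° steps (the equivalent minimum-eigenvector
solution of `LᵀC⁻¹L` is implemented as a cross-check). Weights satisfy
`wᵀl = 1` exactly.

Source measures per analysis window, always baseline-corrected:

- Evoked (1–30 Hz band): mean square of the trial-averaged virtual
  timeseries in the window minus the same over the (−0.15, 0) s baseline.
  Because power is a nonlinear functional of the average, its standard
  error is a leave-one-trial-out jackknife, evaluated with closed-form
  leave-one-out sums.
- Induced (window's own band): per-trial mean Hilbert envelope in the
  window minus an equal-length baseline ending 0.2 s before onset
  (clamped to the epoch start if the pre-stimulus span is shorter); the
  standard error is the across-trial standard deviation over √n. The
  analytic transform commutes with the spatial projection, so the Hilbert
  transform is applied in sensor space over whole epochs before windowing.

## Statistics

Within participant, face and scrambled measures are contrasted with
Welch's t, `t = (x_f − x_s)/√(s_f² + s_s²)`. Group inference is a
one-sample sign-flip permutation test on the participant t images:
whole-image sign flips are exchangeable under no condition difference; the
flip set is enumerated exhaustively when `2ⁿ` does not exceed the
requested permutation count, otherwise sampled with the add-one p-value
convention. Family-wise error is controlled by the maximum-statistic
distribution over the grid. Evoked group maps use a pseudo-t: the variance
image is smoothed with a σ = 12 mm Gaussian (edge-renormalized within the
mask) before forming the denominator, which stabilizes the statistic for
focal sources; induced group maps use the unsmoothed t. Tests are
two-sided by default.

## Synthetic scenario

Sessions have 120 point magnetometers on a helmet cap of radius 0.12 m,
600 Hz sampling, epochs from −1.25 to 1.25 s, 100 trials per condition in
alternating order. The default scenario contains three sources:

| source | kind | position (mm) | timing | face : scrambled |
|---|---|---|---|---|
| lateral occipital | induced, 50–90 Hz burst | (40, −55, 0) | envelope 0.05/0.23/0.50 s | 1.5 : 1.0 |
| fusiform | evoked deflection | (35, −50, −25) | Gaussian, peak 140 ms, σ 20 ms | 1.0 : 0.0 |
| parieto-occipital | evoked deflection | (0, −65, 35) | Gaussian, peak 210 ms, σ 25 ms | 0.4 : 1.0 |

Induced bursts are band-passed white noise multiplied by a piecewise-cosine
envelope with per-trial random carrier noise, so they cancel from the
trial average (a sinusoid carrier with per-trial phase is available for
envelope-oracle tests). Background activity comes from 40 random tangential
dipoles carrying 1/f noise plus white sensor noise (15 fT RMS). The
generator returns the complete ground truth (source specs and per-
participant seeds) alongside the data.

What the synthetic data shows: the mid-latency evoked window (116–181 ms)
and the gamma window (50–90 Hz, 100–450 ms) localize their generators to
within the grid spacing at realistic SNR; the late window (181–300 ms)
shows the scrambled > face effect as a negative contrast at its source.
The early window (83–116 ms) is *not* clean even though no source is
centred in it: the fusiform deflection (peak 140 ms, σ 20 ms) still has
about half its peak amplitude at 116 ms, and zero-phase 1–30 Hz filtering
spreads it further, so a genuine face > scrambled effect leaks into the
early window at the fusiform location and can reach family-wise
significance in consistent groups. This is a property of overlapping
component timing, faithfully detected by the pipeline, not an analysis
artifact.

## Problem sizes and numerical choices

Analysis grids default to 4 mm spacing; the shipped validation analyses
use 6 mm for single-group localization (quantization error at most half a
voxel diagonal, ≈ 5.2 mm) and 8 mm for replication sweeps, with groups of
6–8 participants — sizes chosen so the full validation suite runs on one
CPU in minutes while leaving the scientific conclusions unchanged.
Group significance with sign-flip permutations needs at least 6
participants: the two-sided exhaustive floor is 2/2ⁿ, which first drops
below 0.05 at n = 6.

Numerics worth knowing about:

- Covariance uses a BLAS rank-k update (`syrk`) on mean-removed stacked
  trials; filtering chunks trials and supplies its own mirror padding.
- Beamformer projections stream over trials in chunks sized to keep the
  projected block around 200 MB, so memory stays flat as voxel counts grow.
- The evoked jackknife uses closed-form leave-one-out sums (two streaming
  passes) instead of materializing per-trial volumes.
- The sensor-count map computes exact signed-rank p-values vectorized via
  a shared subset-sum null distribution for tie-free columns, falling back
  to the scalar test for ties/zeros.
- All randomness flows through `numpy.random.default_rng` seeds; group
  simulation derives per-participant seeds below 2³¹ from one master seed,
  and identical configurations reproduce outputs bit-identically.

## Limitations

- Spherical conductor only: no realistic anatomy (BEM/FEM surfaces), and
  sources near the sphere centre have vanishing leadfields.
- No artifact models (blinks, cardiac, head movement); amplitude-based
  trial rejection is available but off by default for synthetic data.
- The beamformer assumes uncorrelated sources; strongly correlated
  bilateral sources would partially cancel.
- Talairach/MNI registration is out of scope: coordinates are head-frame
  metres (NIfTI output in mm).
- The two-pass evoked jackknife trades CPU for memory; on very large
  grids the induced Hilbert projection dominates runtime.
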