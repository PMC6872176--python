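# Methods

## Forward model

Each voxel's simulated time series is

```
y(t) = b · (1 + Σ_c e_c · g(v) · 1[v ∈ ROI_c] · x_c(t))
       + drift(t) + Σ_k l_k(v) · s_k(t) + thermal(t)
```

- `b` — baseline intensity, 100 inside the brain and 0 outside, so
  effect sizes read directly as fractional (percent/100) signal change.
- `x_c(t)` — the canonical-HRF response of contrast *c*'s ROI: the sum
  of the HRF-convolved boxcars of the conditions that drive that ROI
  (e.g. both left-press conditions for the left-vs-right ROI). The HRF
  is the standard double-gamma (peak delay 6 s, undershoot delay 16 s,
  unit dispersions, undershoot ratio 1/6, 32 s kernel), sampled on a
  0.1 s grid and peak-normalized; convolution is a Riemann-sum integral
  on that grid, sampled at volume times `i·TR`.
- `g(v)` — grey-matter partial-volume scaling of the activation
  amplitude (optional, on by default): BOLD responses arise in grey
  matter, so the planted amplitude follows the voxel's GM probability.
  This also keeps detection un-saturated across the ROI, which is what
  makes sensitivity-vs-effect-size curves informative.
- `drift(t)` — per-voxel random 2nd-order Legendre polynomial, scaled
  by a profile-level amplitude (default 1% of baseline). Exercised by
  the 128 s high-pass.
- `s_k(t)` — shared unit-variance "physiological" time courses: a
  respiratory-like sinusoid (~0.3 Hz), a cardiac sinusoid (~1 Hz)
  folded into the sampled band by the volume TR, and a smoothed random
  walk. **These frequencies are modelling assumptions**, not measured
  spectra; the empirical physiological spectrum of any given scanner
  and subject differs. Loadings `l_k(v)` are per-tissue amplitudes
  (largest for CSF, then WM, smallest for GM, plus a small global term)
  with ±20% per-component jitter so the components differ spatially.
- `thermal(t)` — stationary AR(1) Gaussian noise (default lag-1
  correlation 0.30) with marginal sd given per profile as a fraction of
  baseline.

The two stock profiles are matched in approximate total grey-matter
variance (~2.3–2.5% of baseline, i.e. raw voxel tSNR ≈ 40, a realistic
high-field value) but differ in composition: `sms_like` has a
physiological/thermal variance ratio of ~0.1 in grey matter,
`epi3d_like` ~2.6. The composition, not the total, is the modelled
difference between the acquisition schemes.

### Phantom

An ellipsoidal brain on an isotropic voxel grid (identity orientation;
the benchmark never needs real-world registration): pure-WM core
(probability exactly 1, so that the "probability = 1" noise masks used
for CompCor exist), two ventricle-like CSF pockets (probability 1), and
a GM shell whose probability peaks at 1 mid-shell and tapers to ~0.3 at
the edges — the partial-volume gradient that `g(v)` picks up. One
compact spherical ROI per contrast is placed mid-shell along
well-separated directions (golden-spiral spacing with seeded jitter);
ROIs are validated non-empty, pairwise disjoint, and inside the GM ≥ 5%
band.

### Paradigm

Ten task types, `events_per_condition` each (default 3, duration 2.5 s,
minimum gap 1 s) in a 320 s (5:20 min) run of 267 volumes at TR 1.2 s.
Order is a seeded shuffle; residual run time is spread over the gaps by
a flat Dirichlet draw. The original localizer's literal stimulus
schedule is not public; the generator reproduces its statistical
structure (condition set, event density, pseudo-random order), which is
what the downstream statistics depend on.

## Analysis model

Design matrix: per condition an HRF-convolved regressor and its
temporal derivative (latency absorption); discrete-cosine drift columns
with `K = floor(2·N·TR/cutoff)` (the convention of the standard
SPM-style high-pass; 5 columns for the default run), optional nuisance
columns, and a constant. Rank deficiency is rejected with the most
collinear column pair named.

CompCor: voxel series in the pure-WM and pure-CSF masks are projected
orthogonal to drift+constant, variance-normalized, and SVD-decomposed;
the top 5 (WM) + 3 (CSF) left temporal singular vectors enter the
design as nuisance regressors.

Prewhitening is two-pass: OLS residuals → pooled noise autocorrelation
→ premultiply data and design by the whitening transform → OLS on the
whitened system; t-statistics use `c'(X_w'X_w)⁻¹c` with the whitened
design, and dof = N − rank(X).

Two details deserve emphasis:

- **Projection-bias correction.** The raw pooled residual lag-1
  autocorrelation systematically underestimates the noise
  autocorrelation, because the residual-forming projection
  `M = I − X(X'X)⁻¹X'` (in particular the smooth DCT columns) absorbs
  low-frequency autocorrelated power; at the default design size the
  raw estimate of a true ρ = 0.4 is ≈ 0.27, and whitening with it
  leaves the false-positive rate inflated. `fit_glm` therefore solves
  the moment equation: it finds the AR model whose *implied residual*
  autocorrelation `tr(U_k M S M)/tr(M S M)` matches the observed one
  (damped fixed-point iteration from the raw estimate). With this
  correction ρ̂ recovers 0.39–0.40 and the p < 0.05 false-positive rate
  is nominal. The plain pooled estimator remains available as
  `estimate_ar1` (used for diagnostics and residual checks), clipped to
  [0, 0.99].
- **The "extended" model** is a pooled AR(3) covariance fitted by
  Yule–Walker to the corrected autocorrelations, whitened through the
  inverse Cholesky factor of the implied Toeplitz correlation matrix
  (with a stationarity guard that shrinks unstable coefficient
  vectors). It is this package's stand-in for proprietary
  multi-component covariance models that capture higher-order temporal
  correlation; it exercises the same pipeline branch but is **not** a
  numerical reproduction of any vendor implementation.

tSNR is mean/sd of the detrended series, computed on the *unsmoothed*
data (the "raw time-series" definition); detrending reuses the same
DCT basis as the GLM high-pass, since no more specific definition of
"detrended" is standard. Zero-variance voxels are NaN.

Smoothing is separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis,
zero-padded convolution (bit-reproducible); FWHM 0 is the identity.

## Detection scoring

- p-values are **one-sided** upper-tail t probabilities: the localizer
  contrasts are directional and one-sided t contrasts are the
  convention of the standard analysis packages.
- "Activated" is the strict inequality `p < α`, matching the
  `p < 0.001` notation; ties break toward non-activation. The α = 0
  endpoint is degenerate (nothing passes), so ROC curves are anchored
  at (0,0) and (1,1) instead of including it.
- The default α grid is 200 points: geometric from 1e−6 to 0.01 (the
  low-α region dominates AUC discretization error) plus linear from
  0.01 to 0.5.
- AUC is the trapezoid over (1−specificity, sensitivity) with the
  anchors appended. When the grid contains every distinct p-value this
  equals the tie-corrected Mann–Whitney statistic exactly (tested by
  brute-force pairwise enumeration).
- d′ uses the 1/(2n) log-linear correction for degenerate rates of
  exactly 0 or 1 (n the relevant voxel count), flagged in the result;
  unclipped degenerate rates raise instead of returning ±∞.
- Aggregation: per subject, sensitivity/specificity averaged across
  the four sensorimotor contrasts at each α → per-subject AUC and d′ →
  mean ± sample sd over subjects; the pooled mean curve is emitted
  separately for plotting. The specificity denominator (analysis mask)
  is an explicit argument — the grey-matter band in the standard
  pipeline.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis
depends on: HRF-shaped activation confined to known ROIs, slow drift,
AR(1) thermal noise, and shared low-rank physiological components
concentrated in WM/CSF with the two noise-composition regimes. It does
not simulate MR physics (no k-space, g-factor, distortion, slice
leakage), motion, habituation, or spatially heterogeneous HRFs, and the
physiological spectrum is assumed, not measured. Passing tests
therefore demonstrate the correctness and calibration of the analysis
and scoring machinery, and the direction of noise-composition effects —
not the absolute detection performance of any real sequence. Absolute
AUC/d′ on the phantom are higher than values observed on real data
(the phantom has no inter-subject variability, registration error, or
ROI mismatch) and depend on grid size and smoothing.

## Numerical choices and degenerate inputs

- Convolution grid 0.1 s; regressors sampled at `t = i·TR` with no
  slice-timing offset (3D-readout convention; the phantom has no
  slices).
- DCT columns are orthonormal; high-pass projection is a single matrix
  product and idempotent.
- Whitening with ρ̂ = 0 reproduces OLS exactly (first-row scaling
  √(1−ρ²) = 1).
- Constant series: tSNR undefined (NaN); CompCor refuses all-constant
  noise masks; zero residual variance yields NaN t-values, flagged by
  the StatMap's missing-value convention.
- Experiment seeds: subject *i* uses `master_seed + i`; every
  stochastic function is a pure function of its arguments including the
  seed.
- Default experiment scale: 16³ voxel phantom, 267 volumes, 5–10
  subjects — small enough for interactive use while leaving every
  statistic estimable; all sizes are configuration.

## Known limitations

- The pooled (global) ρ̂ ignores spatial variation of autocorrelation;
  voxel-wise or tissue-wise AR models are out of scope.
- The AR(3) "extended" model shares the pooled estimate's scope; no
  restricted-maximum-likelihood hyperparameter estimation is
  performed.
- No cluster-level or family-wise-error-corrected inference; scoring
  is purely voxel-wise against the reference ROIs.
- The phantom's reference ROIs are exactly the simulation's activation
  support, so "ground truth" is noiseless — real reference ROIs carry
  their own uncertainty.
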