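# fmri-seqbench

Detection-theory benchmarking of task-fMRI acquisition schemes on
simulated BOLD data.

## The problem

Fast accelerated fMRI sequences differ mainly in the *composition* of
their noise: multiband (SMS) EPI readouts are dominated by thermal
noise, while 3D-EPI readouts are more sensitive to physiological noise
(respiration, cardiac pulsation) that is shared across voxels and
concentrated in white matter and CSF. Raw temporal SNR does not tell
you which sequence detects task activation better — that depends on how
much of the noise the analysis model can remove, and on the temporal
correlation structure the model assumes.

This package provides the full evaluation loop as a tested, seeded
library:

1. **Simulation** (`fmri_seqbench.simulate`, `phantom`, `events`) — a
   digital head phantom (GM/WM/CSF tissue maps, reference ROIs), a
   pseudo-randomized fast event-related localizer paradigm with ten task
   types (sentences, mental computation, left/right button presses cued
   visually or auditorily, flashing checkerboards), and a forward BOLD
   model: canonical-HRF responses confined to known ROIs, slow
   polynomial drift, low-rank physiological components loading on
   WM/CSF, and AR(1)-correlated thermal noise. Two stock noise profiles,
   `sms_like` (thermal-dominated) and `epi3d_like`
   (physiological-dominated), are matched in total grey-matter variance.
2. **Analysis** (`preprocess`, `glm`) — Gaussian smoothing (5 mm FWHM
   default), grey-matter band masking (GM probability ≥ 5%), a
   128 s-period discrete-cosine high-pass, temporal-SNR maps, and the
   mass-univariate GLM: per condition an HRF-convolved regressor plus
   its temporal derivative, CompCor nuisance regressors (3 CSF + 5 WM
   principal components from pure-tissue masks), and prewhitening with a
   pooled AR(1) or an extended pooled AR(3) noise model. Voxel-wise
   contrast t-maps include the *t-score of the mean signal* (the
   constant-regressor contrast), a sequence metric that is sensitive to
   unmodelled temporal correlation.
3. **Benchmarking** (`benchmark`) — with activation defined as
   `p < α`, sensitivity = TP/|ROI| and specificity = 1 − FP/|non-ROI|
   against the reference ROIs; the ROC over thresholds α ∈ (0, 0.5];
   trapezoidal AUC (1 = perfect, 0.5 = random); and

   d′ = Φ⁻¹(sensitivity) − Φ⁻¹(1 − specificity)

   at a fixed threshold (default p < 0.001, uncorrected). Results are
   aggregated the standard way: rates averaged over the four robust
   sensorimotor contrasts within subject, AUC/d′ per subject, then
   mean ± sd over subjects.

## Worked example

```python
from fmri_seqbench import ExperimentConfig, run_experiment

cfg = ExperimentConfig(n_subjects=5, master_seed=1)
report = run_experiment(cfg)
for arm, v in report["arms"].items():
    print(f"{arm}: tSNR {v['mean_tsnr']:.1f}  "
          f"t-of-mean {v['mean_t_of_mean']:.0f}  "
          f"AUC {v['auc_mean']:.3f}+/-{v['auc_sd']:.3f}  "
          f"d' {v['dprime_mean']:.2f}+/-{v['dprime_sd']:.2f}")
```

prints

```
sms_like|ar1|none: tSNR 45.1  t-of-mean 1556  AUC 0.983+/-0.023  d' 3.19+/-0.29
sms_like|ar1|compcor: tSNR 45.1  t-of-mean 2366  AUC 0.997+/-0.003  d' 4.21+/-0.52
epi3d_like|ar1|none: tSNR 56.6  t-of-mean 749  AUC 0.940+/-0.082  d' 2.12+/-0.49
epi3d_like|ar1|compcor: tSNR 56.6  t-of-mean 3788  AUC 0.994+/-0.001  d' 4.53+/-0.06
```

Reading this: each arm is `profile|whitening|nuisance`. The
physiological-noise-dominated arm (`epi3d_like`) has the *higher* raw
tSNR here, yet without nuisance modelling its detection performance
(AUC 0.940, d′ 2.12) is clearly worse than the thermal-dominated arm —
shared physiological fluctuations both inflate false positives and mask
true activation. Adding CompCor regressors raises its d′ by ~2.4, far
more than the ~1.0 gain of the thermal-dominated arm: the benefit of
nuisance regression is differential, and largest where physiological
noise dominates. The `mean_t_of_mean` column shows the same story from
the other side — the t-score of the mean signal jumps once the
structured noise is modelled.

A command-line interface wraps each stage
(`fmri-seqbench simulate | preprocess | fit | benchmark | run`); see
`fmri-seqbench --help`.

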