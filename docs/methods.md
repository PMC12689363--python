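# Methods

## Signal models and units

Both forward models live in `signal_models`.  Diffusivities (D, D\*,
ADC) are stored and reported in µm²/ms and b-values in s/mm², so every
exponent carries a factor of 10⁻³ (1 µm²/ms = 10⁻³ mm²/s).  Parameter
invariants: S0 > 0; 0 ≤ f < 1; 0 < D ≤ 4 µm²/ms (free-water ceiling at
body temperature, configurable); D\* > D whenever f > 0.  With f = 0 the
fast compartment vanishes and D\* is unidentifiable, so the ordering
constraint is not enforced there.

## Voxel-wise fitting

**ADC fits.**  Nonlinear least squares of S0·exp(−b·ADC·10⁻³) on the
linear signal scale, restricted to b ≥ b_min, initialised from the
closed-form log-linear solution.  ADC_b0 uses all b; ADC_b150 uses
b ≥ 150 s/mm² to suppress perfusion contamination.  Fitting on the
linear scale (rather than keeping the log-linear solution) avoids the
variance distortion of log-transformed noise.

**Segmented IVIM fit.**  For each candidate cut-off b\* ∈ {100, 150,
300} s/mm² (defaults chosen so that at least three acquired b-values lie
on each side for the 10-b scheme; the general rule is "cut-offs within
[100, 400] with ≥ 3 points at or above"):

1. log-linear fit on b ≥ b\* → D and intercept A;
2. f = 1 − A/S(0), clamped to [0, 0.999] with negatives set to 0 (the
   clamp count is reported, not an error);
3. with S0 pinned to the measured S(0) and (f, D) fixed, a bounded 1-D
   least squares over D\* ∈ [3, 100] µm²/ms on the full b range;
4. SSR of the full bi-exponential over all b-values.

The cut-off with the lowest full-curve SSR wins; ties go to the lower
cut-off.  S0 is pinned to the measured b = 0 signal rather than
re-estimated — the alternative (refitting S0 jointly with D\*) changes
noiseless recovery by far less than the fit tolerances and would couple
the perfusion stage to the baseline estimate.  A simultaneous
4-parameter nonlinear fit exists only as a test oracle; segmented
fitting is the production path because it is convex per stage, faster,
and far more robust at clinical SNR.

Voxels containing any nonpositive or non-finite signal are flagged
invalid (excluded from maps, medians and p_IVIM denominators) instead of
raising, mirroring dataset-level artefact exclusion applied per voxel.

## Model comparison

AICc = n·ln(SSR/n) + 2k + 2k(k+1)/(n−k−1) with n = 10 b-values, k = 2
(ADC) and k = 4 (IVIM).  The noise-variance parameter is excluded from k
by default (adding 1 to both is a config switch; it shifts both
penalties and mildly strengthens the small-sample correction).  Both
SSRs are computed over the identical full b-value set on the linear
scale.  SSR is floored at n·(ε·S0)² with ε = 10⁻⁶, a per-point relative
noise proxy, so noiseless phantoms cannot produce ln(0); when both
models floor, the strict-inequality rule prefers the simpler ADC model
(parsimony on exact ties).  The analytic preference boundary at n = 10
is SSR_IVIM/SSR_ADC = exp(−(16 − 40/7)/10) ≈ 0.35752, which the tests
exercise from both sides.

p_IVIM for a region = (# IVIM-preferred voxels) / (# valid voxels);
with zero valid voxels the result is NaN (undefined), never 0.

## ROI summaries

Medians run over valid voxels only, with numpy's even-count convention
(mean of the two central order statistics).  δADC is the median of the
voxel-wise ADC_b0 − ADC_b150 differences, not the difference of medians.
Subset summaries condition on the preference map: D, f and D\* over
IVIM-preferred voxels; ADC_b0, ADC_b150 and D over ADC-preferred voxels.
ROI volume = voxel count × voxel volume, reported in cm³, defined on the
DWI grid.  Empty or all-invalid ROIs yield flagged (NaN) summaries and
contribute no biomarker-table records.

## Statistics

**wCV** = sqrt((1/N)·Σ s_i²/m_i²) × 100 — the root mean of squared
per-subject relative SDs (sample SD, ddof = 1).  For the two-session
design this coincides with the paired-difference estimator.  Subjects
with fewer than two sessions are excluded and counted; fewer than two
usable subjects is a hard error.

**Repeated-measures correlation**: within-subject centering of both
variables, Pearson correlation of the pooled residuals, two-sided t-test
with dof = N_obs − n_subjects − 1.  Algebraically identical to the
common-slope ANCOVA with subject indicators (verified against both an
explicit regression oracle and pingouin in the tests).

**Repeated-measures ANOVA**: complete cases only (subjects missing any
timepoint are dropped and counted), classical decomposition SS_total =
SS_subject + SS_time + SS_error, F = MS_time/MS_error on (t−1,
(t−1)(s−1)) degrees of freedom.  Post-hoc paired t-tests per requested
contrast (defaults: first-vs-second and first-vs-third timepoint);
Bonferroni correction multiplies each uncorrected p by the number of
contrasts, capped at 1.  All tests are two-sided with α = 0.05.
Normality, sphericity and rank tests are delegated to scipy.stats
pass-throughs and are not re-implemented.

## Synthetic phantoms

The generator emulates a 10-b pelvic DW acquisition (b = 0, 20, 40, 60,
80, 100, 150, 300, 500, 800 s/mm²; 2.9 × 2.9 × 6.0 mm voxels).  Each
voxel belongs to a tissue class with fixed (S0, f, D, D\*); noise is
Gaussian or Rician (magnitude of a complex Gaussian-perturbed signal)
with σ = S0_ref/SNR(b=0).  Defaults: SNR(b=0) = 50, a typical value for
a 4-average pelvic EPI protocol, logged in every manifest.  Class
presets: free fluid (f = 0, D = 3.0), normal perfused tissue (f = 0.19,
D = 1.3, D\* = 30 — healthy-cervix central values), and a tumour class
(f = 0.10, D = 1.0, D\* = 20) that is a plausible configurable stand-in,
not a measured value.

Cohort generators derive all per-subject/session/visit random streams
from one master seed via `numpy.random.SeedSequence` spawn keys, so
outputs are bit-reproducible.  Test-retest cohorts jitter f, D and D\*
multiplicatively by (1 + N(0, cv)) per session; longitudinal cohorts
scale tumour D per visit and optionally erode the tumour label in-plane
(slices are thick relative to in-plane resolution) to shrink volume.

What the phantoms do **not** emulate: realistic anatomy, partial-volume
mixing, EPI distortion, motion, fat suppression or coil profiles.
Passing tests therefore demonstrate correctness of the estimators and
statistics under the stated noise models — not robustness to real-world
acquisition artefacts.

## Problem sizes

The shipped tests and the acceptance script use deliberately small
problems chosen to exercise every code path at comfortable statistical
power: 500-voxel single-class phantoms per SNR level, a 200-subject ×
2-session perfusion-bias cohort of 9-voxel ROIs, a 2,000-subject wCV
recovery, a 6-subject × 3-visit longitudinal cohort, and one 32 × 32 × 4
phantom for the end-to-end determinism run.

## Known limitations

* No Rician-bias correction during fitting; at SNR ≥ 50 the b = 0 bias
  is below 1% (checked by Monte Carlo), but very low SNR combined with
  high b attenuates into the noise floor and biases D downward.
* D\* is reported as a secondary output; with only five b-values below
  150 s/mm² its per-voxel precision is poor, which is why ROI medians
  are the intended unit of interpretation.
* The AICc k-convention and the SSR floor are conventions, both exposed
  in `FitConfig`; conclusions about p_IVIM magnitudes (not directions)
  can shift under the alternative k-convention at n = 10.
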