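# Methods

Model definitions, parameter choices and numerical details for each
analysis module and its matched generator. Generator presets encode the
published summary statistics of the experiments they model; everything
not pinned by such a statistic is a package choice, recorded here.

## FRAP recovery (`nucleokin.frap`, `simulate.simulate_frap_cohort`)

**Model.** Post-bleach recovery of a bleached nuclear spot is

```
F(t) = y0 + A_fast (1 − e^(−t/τ_fast)) + A_slow (1 − e^(−t/τ_slow)),
```

the standard reaction-dominant two-binding-class description: `y0` is the
residual (immediately recovered plus unbleached) signal, and the two
exponential terms are fast- and slow-exchanging bound pools. Derived
quantities: mobile fraction `(A_fast + A_slow)/(1 − y0)`; slow fraction of
the mobile pool `A_slow/(A_fast + A_slow)`.

**Pipeline.** Raw curves are divided by the single pre-bleach sample
(`normalize_recovery`), screened by bleach depth (first post-bleach value
must be ≤ 0.25 of pre-bleach, boundary inclusive), fitted, and pooled.

**Fitting.** The model is linear in `(y0, A_fast, A_slow)` given the time
constants, so fitting uses variable projection: a 5 × 5 log-spaced
`(τ1, τ2)` multi-start solves the amplitudes by linear least squares at
each start, and the best start is polished with bounded trust-region
least squares (`y0 ∈ [0, 1]`, `A ∈ [0, 2]`, `τ ∈ [0.05, 100] s`).
Components are relabelled so `τ_fast ≤ τ_slow`. R² is computed on
post-bleach samples only. The polished solution is accepted only if it
does not increase the SSE of the best start, so the fitter can never lose
to a grid oracle on its own grid.

**Resolvability QC.** A converged fit contributes to cohort *fraction*
summaries only if its slow time constant is actually identified on the
acquisition window: `τ_slow ≥ 10·dt`, `τ_slow ≤` window length, and
`τ_slow ≥ 3·τ_fast`. Fits failing this (typically τ_slow pinned at a
bound, or the two components merged) have arbitrary amplitude splits and
would bias the slow fraction; they remain in the output table flagged
`resolved=False`, and in the R² summary. Cohort summaries report
`n_input / n_qc_pass / n_converged / n_resolved`.

**Generator.** Acquisition is one pre-bleach sample followed by a
0.2-s-interval, 20-s post-bleach series. Per-cell parameters are drawn
around the preset truth with a single between-cell coefficient of
variation, and a per-cell multiplicative gain (~1000 counts) is applied
so normalization is genuinely exercised. Presets:

| preset | mobile | slow (of mobile) | y0 | τ_fast | τ_slow | n | CV |
| --- | --- | --- | --- | --- | --- | --- | --- |
| unconfined | 0.7521 | 0.0421 | 0.05 | 0.2 s | 5.0 s | 45 | 0.08 |
| confined | 0.7521 | 0.0676 | 0.05 | 0.2 s | 5.0 s | 54 | 0.08 |

Choices and rationale:

- *Noise calibration.* The additive Gaussian noise SD is set analytically
  from the target fit quality: `σ² = (1 − R²_target) · Var_grid(F)`, with
  `R²_target = 0.986`, evaluated per cell on its own clean curve. This
  makes the cohort mean R² a generator invariant rather than a tuned
  quantity.
- *Time constants.* τ values are not pinned by a published statistic;
  they are chosen for identifiability on the 20-s window: τ_fast = 0.2 s
  is well above the 0.2-s sampling limit after ~3 samples resolve the
  rise, τ_slow = 5.0 s is a quarter of the window (so its plateau is
  observed) and 25 × τ_fast (so the components separate). Values in this
  range are typical of published HMGB-family FRAP recoveries.
- *Between-cell dispersion.* One CV applies to all per-cell parameters;
  it is derived from the summary statistic that pins it best, the mobile
  fraction (SEM × √n / mean ≈ 0.08).
- *Confined mobile fraction.* Only the unconfined mobile fraction has a
  published value; the confined preset reuses it, since the conditions
  are reported to differ in the slow fraction, not overall mobility.

## Nuclear accumulation (`nucleokin.accumulation`)

**Model.** Per-track intensity is expressed as fold-change over the first
sample. A track is rejected if more than four points deviate by more than
0.2 fold from its own OLS line (both knobs exposed; defaults 4 and 0.2).
Kept tracks get an OLS slope in fold h⁻¹; cohort summaries are mean ± SEM
of slopes and of last-sample fold-changes.

**Reconciling rate and endpoint.** The published baseline statistics —
0.269 fold h⁻¹ and a 1.76-fold endpoint over a 16-h series — are
mutually inconsistent under unbroken linear rise (0.269 × 16 ≈ 4.3).
The generator models what such data must look like: each cell rises
linearly at its own rate for a shared duration
`rise_h = (final_fold − 1)/rate ≈ 2.8 h`, then plateaus. Consequently the
rate is estimated on the rising window (`cohort_rates(window_h=...)`)
while the endpoint fold is read at the last sample; full-track OLS
remains the default for series without a plateau. The tubacin
(0.353 fold h⁻¹) and vehicle (0.145 fold h⁻¹) presets model 4-h
acquisitions with no plateau, so default full-track OLS applies there.

**Generator.** 0.25-h sampling; per-cell rates dispersed with CV 0.2;
additive Gaussian noise SD 0.05 fold; optional contamination injects a
5–10-point block excursion of ±(0.5 + drift) fold into a configurable
fraction of tracks, which the line filter is expected to reject.

## Morphometrics (`nucleokin.morphometrics`)

Circularity is `4πA/P²`, clamped to ≤ 1 (rasterized near-circles can
exceed 1 with any finite perimeter estimator). Region measurements come
from `skimage.measure.regionprops`, with the Crofton perimeter — the
least-biased perimeter estimator on rasterized convex shapes. Intensity
is normalized per object to a reference (DNA stain) channel; objects with
zero reference signal are excluded, not propagated as NaN. The
shape–intensity association is the Pearson correlation with its two-sided
p-value and the OLS slope/intercept.

The generator draws (circularity, normalized intensity) from a bivariate
Gaussian at the preset coupling ρ = −0.474 and n = 176 (back-derived by
inverting the Pearson t-test at the published R and P), circularity
N(0.82, 0.06) clipped to (0, 1], intensity N(1.0, 0.25). A linear
Gaussian dependence is used rather than a rank-based coupling so that
ρ = −1 produces a sample correlation of exactly −1. Optional rendering
draws each object as an ellipse whose axis ratio is solved from the
target circularity by inverting the Ramanujan perimeter approximation
(Brent root-finding), at 16-bit intensity levels around 1000 counts.

## Migration tracks (`nucleokin.tracking`)

Mean velocity is the per-cell mean of consecutive-frame Euclidean step
lengths divided by the frame interval; cohort values average per-cell
means (not pooled steps, which would weight long tracks). The generator
produces isotropic 2-D random walks with Rayleigh step lengths whose mean
equals speed × interval (σ = v·Δt/√(π/2)), per-cell speeds dispersed with
CV 0.2 around the 0.0838 µm min⁻¹ preset at 5-min frames.

## Tumour growth (`nucleokin.growth`)

Caliper volume is `V = L·W²·0.52` (mm³). Growth is modelled on ln V with
Gaussian errors. The single-exponential model is OLS on
`ln V ~ 1 + day`; the biexponential model is the continuous piecewise
log-linear curve with early/late rates and a breakpoint, profiled over a
fixed 0.1-day grid spanning the observed days (each conditional fit is
closed-form OLS). The grid is not refined continuously: 0.1 day is far
below the 3.5-day sampling interval, and a fixed grid makes the estimator
exactly reproducible and verifiable against an independent grid oracle.
The exact maximized Gaussian log-likelihood (including the σ̂ MLE term,
`−n/2 (ln 2πσ̂² + 1)`) feeds a likelihood-ratio test against χ² with
df = 2 (extra rate + breakpoint). Because the breakpoint vanishes under
the null, χ²₂ is an approximation; its type-I error is verified by
simulation (≈ 0.05–0.08 at α = 0.05) in the test suite. A
sum-of-two-exponentials variant is available for sensitivity analysis.

The study generator samples twice weekly (3.5-day interval) from day 0 at
100 mm³, 8 animals per arm, ln-scale SD 0.2 — typical xenograft designs.

## Generator limitations

- FRAP noise is i.i.d. Gaussian per sample; real confocal noise is
  Poisson-dominated and its variance scales with signal.
- Accumulation plateaus are sharp (piecewise linear); real saturation is
  smooth. The shared rise duration is a modelling device to make the
  published rate and endpoint simultaneously true.
- Morphometric shape and intensity are jointly Gaussian; real circularity
  distributions are skewed near 1 and intensity is lognormal-ish.
- Random-walk tracks have no persistence (no velocity autocorrelation),
  so they test the velocimetry arithmetic, not motility models.
- Growth noise is uncorrelated across days within an animal; real
  longitudinal measurements have serial correlation.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng` seeded from a
  `SimulationRecipe`; every generator is bit-reproducible for a fixed
  seed.
- Statistical wrappers delegate to scipy (`ttest_ind`, `f_oneway`,
  `tukey_hsd`, `mannwhitneyu` with exact small-sample nulls when both
  n ≤ 6 and there are no ties); degenerate zero-variance inputs get
  explicit conventions (equal means → p = 1; unequal constant groups are
  flagged degenerate) instead of NaN propagation.
- JSON outputs are written atomically (temp file + rename) with numpy
  scalars coerced, sorted keys and fixed indentation, so identical
  analyses produce byte-identical files.
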