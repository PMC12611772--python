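# nucleokin

Kinetic and morphometric analysis of nuclear protein dynamics under
mechanical confinement, with matched synthetic-data generators for
end-to-end validation.

When migrating cells squeeze through tight spaces, the nucleus deforms and
chromatin-associated proteins such as HMGB2 change both their abundance in
the nucleus and their exchange kinetics on chromatin. Three kinds of
measurement quantify this:

- **FRAP (fluorescence recovery after photobleaching)** probes
  protein–chromatin exchange. A nuclear spot is bleached and the recovery
  curve is fitted with a two-component exponential,
  `F(t) = y0 + A_fast (1 − e^(−t/τ_fast)) + A_slow (1 − e^(−t/τ_slow))`,
  giving a *mobile fraction* `(A_fast + A_slow)/(1 − y0)` and the split of
  the mobile pool into fast- and slow-exchanging components. A larger slow
  fraction indicates longer chromatin residence.
- **Nuclear accumulation time-lapses** follow per-cell nuclear intensity,
  expressed as fold-change over the first frame; an outlier filter rejects
  tracks that wander from a straight line, and an ordinary-least-squares
  slope per track gives an accumulation rate in fold h⁻¹.
- **Morphometrics** relates nuclear shape (circularity `4πA/P²`, a proxy
  for deformation) to normalized protein intensity across a fixed cell
  population; **migration tracks** give mean cell velocities; **tumour
  growth curves** from caliper measurements (`V = L·W²·0.52`) are compared
  between single- and biphasic-exponential models with a likelihood-ratio
  test.

Because raw imaging data for such studies are rarely deposited, every
analysis module here is paired with a generator (`nucleokin.simulate`)
whose ground-truth presets encode published summary statistics. Recovery
of those statistics by the full pipelines is the package's acceptance
standard (see *Reproducing the headline results* below).

## Worked example: a FRAP cohort

Simulate 45 unconfined-condition recovery curves on the 0.2-s/20-s
acquisition grid and push them through the full pipeline
(normalize → bleach-depth QC → two-component fit → pool fractions):

```python
from nucleokin import frap, simulate

curves, truth = simulate.simulate_frap_cohort(
    simulate.FRAP_PRESETS["unconfined"], simulate.SimulationRecipe(seed=1))

fit = frap.fit_two_component(frap.normalize_recovery(curves[0]))
print(fit.summary())
```

```
Two-component FRAP recovery fit — cell unconfined_000
  y0 (post-bleach floor)     0.0462
  A_fast                     0.7019   tau_fast   0.174 s
  A_slow                     0.0334   tau_slow   5.836 s
  R^2 (post-bleach)          0.9902   SSE 5.875e-03
  mobile fraction            0.7709
  slow / fast (of mobile)  0.0455 / 0.9545
  converged                True
```

Cohort-level analysis with QC bookkeeping:

```python
table, summary = frap.analyze_cohort(curves)
print(summary["mobile_fraction"], summary["slow_fraction"])
```

```
{'mean': 0.7654724704534553, 'sem': 0.008680167196413482}
{'mean': 0.04341957706067234, 'sem': 0.0010602034945479321}
```

The preset truth is a 75.21 % mobile fraction with a 4.21 % slow fraction;
the pipeline recovers 76.5 % and 4.34 % on this seed, with mean post-bleach
R² 0.9867 against the 0.986 calibration target.

## Worked example: accumulation rates and growth curves

```python
from nucleokin import accumulation, growth, simulate

tracks, _, preset = simulate.simulate_accumulation_preset(
    "confined", 100, simulate.SimulationRecipe(seed=2))
_, summary = accumulation.cohort_rates(tracks, window_h=preset.rise_h)
print(summary["rate_fold_per_h"]["mean"], summary["final_fold"]["mean"])
# 0.26751758501980005 1.7579681869472583   (truth: 0.269 fold/h, 1.76-fold)
```

```python
arms = [simulate.GrowthArmTruth("vehicle", rate_early=0.12),
        simulate.GrowthArmTruth("treated", rate_early=0.12,
                                rate_late=0.03, breakpoint=10.0)]
curves, _ = simulate.simulate_growth_study(arms, 8, simulate.SimulationRecipe(seed=3))
treated = [c for c in curves if c.arm == "treated"]
single = growth.fit_growth(treated, model="single")
bi = growth.fit_growth(treated, model="biexponential")
lrt = growth.growth_lrt(single, bi)
print(f"LRT: statistic {lrt.statistic:.2f}, df {lrt.df}, p = {lrt.p_value:.3g}")
# LRT: statistic 30.77, df 2, p = 2.08e-07
```

## Command-line interface

The `nucleokin` command wraps each module; every run writes its outputs
plus a `run_config.json` echo (with a config hash) into the output
directory, so results are reproducible from inputs and config alone.

```bash
nucleokin sim frap --preset unconfined --seed 1 --out results/
nucleokin frap-fit --input results/frap_unconfined.csv --out results/fit/
nucleokin sim accumulation --preset tubacin --n-cells 100 --seed 1 --out results/
nucleokin accumulate --input results/tracks_tubacin.csv --out results/acc/
nucleokin morph --labels labels.tif --channels protein=p.tif,reference=h.tif \
    --reference reference --out results/morph/
nucleokin tracks --input migration.csv --frame-interval 5 --out results/vel/
nucleokin growth --input growth_study.csv --arm treated --out results/growth/
nucleokin stats anova --input rates.csv --group-col condition --value-col rate
```

## Package layout

| Module | Contents |
| --- | --- |
| `nucleokin.frap` | normalization, bleach-depth QC, two-component VarPro fit, pool fractions, cohort analysis |
| `nucleokin.accumulation` | fold-change conversion, line filter, per-track OLS rates, condition comparisons |
| `nucleokin.morphometrics` | region measurements (Crofton perimeter), circularity, reference normalization, correlation |
| `nucleokin.tracking` | per-cell mean migration velocity |
| `nucleokin.growth` | caliper volumes, single/biexponential/sum-exponential models, likelihood-ratio test |
| `nucleokin.stats` | t-test, ANOVA + Tukey HSD, Wilcoxon + Bonferroni wrappers |
| `nucleokin.simulate` | seeded generators + ground-truth presets for all of the above |
| `nucleokin.io` / `nucleokin.cli` | CSV/TIFF/JSON/YAML interchange and the umbrella CLI |

Model/results organisation follows the statsmodels convention where a
model is fitted to data: `TwoComponentRecovery(curve).fit()` returns a
`FrapFitResults`, `GrowthModel(curves, model=...).fit()` returns a
`GrowthResults`; both carry estimates, fit diagnostics and `summary()`.

See `docs/methods.md` for model definitions, parameter choices, generator
assumptions and numerical details.

## Tests

```bash
python -m pytest -q tests/
```

The suite covers unit behaviour, property-based invariances, independent
numerical oracles (grid-search fitters, enumeration of exact test null
distributions, closed-form OLS), statistical calibration (type-I error
rates), and the acceptance criteria above. Full run ≈ 2–3 minutes on one
CPU.
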