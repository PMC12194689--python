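# mnvquant

Quantitative analysis of macular neovascularization (MNV) in neovascular
age-related macular degeneration (nAMD), for researchers relating en-face
OCT-angiography morphology and structural OCT findings to 1-year treatment
outcomes. The package covers three things:

1. **OCTA vascular morphometry** of a binary MNV lesion/flow mask pair:
   lesion **area** (mm²), **flow density** (% of lesion pixels with flow
   signal), box-counting **fractal dimension** (FD) of the skeletonized
   vessel network, and **total vessel length** sumL (mm) summed over the
   8-connected centerline (orthogonal step = 1 px, diagonal = √2 px). The
   default pixel scale is 0.012 mm (6 mm scan field, 500 A-scan positions).

2. **Percentile-bounded weighted linear regression** of outcomes (1-year
   best corrected visual acuity in logMAR, and anti-VEGF injection count)
   on OCT/OCTA predictors. For each variable, with empirical percentiles
   p₁₀ and p₉₀,

   t_low = p₁₀ − 1.5(p₉₀ − p₁₀),  t_high = p₉₀ + 1.5(p₉₀ − p₁₀),

   w(x) = exp( −½ · [max(0, t_low − x, x − t_high) / (½(t_high − t_low))]² ),

   and each observation gets the geometric mean √(w_IV·w_DV) of its two
   variables' weights, so far outliers are smoothly down-weighted while the
   bulk of the sample keeps weight 1. Slopes are reported per clinical unit
   (e.g. per 200 µm of retinal thickness) with a classical WLS 95% CI and
   two-sided t-test on n−2 degrees of freedom.

3. **Synthetic data generators**: a stochastic branching vessel-tree
   rasterizer producing mask pairs with known ground-truth centerline
   length, and an eye-level cohort simulator whose marginal distributions,
   fluid-state transitions after the three-injection loading phase, and
   (optionally) linear outcome effects are fully configurable — so the
   whole pipeline is testable without clinical data.

The core regression is a scikit-learn-style estimator
(`PercentileWeightedLinearRegression`) and composes with sklearn tooling;
`fit_weighted_univariable` / `run_regression_battery` are thin wrappers.

## Worked example

```python
import numpy as np
from mnvquant import (CohortConfig, EffectSpec, RegressionSpec,
                      VesselTreeParams, fit_weighted_univariable,
                      quantify, simulate_cohort, simulate_mnv_pair)

# grow a synthetic MNV and quantify it
pair, truth = simulate_mnv_pair(VesselTreeParams(seed=5))
ms = quantify(pair)
print(f"area = {ms.area_mm2:.3f} mm^2")
print(f"flow density = {ms.flow_density_pct:.1f} %")
print(f"fractal dimension = {ms.fractal_dimension:.3f}")
print(f"sumL = {ms.suml_mm:.3f} mm (generator ground truth {truth:.3f} mm)")

# simulate an 80-eye cohort where 1-year BCVA depends on FD with slope 1.017
effect = EffectSpec("fd", "bcva_1y_logmar", slope=1.017, intercept=0.2,
                    residual_sd=0.35, iv_dist=("normal", 1.292, 0.142))
cohort = simulate_cohort(CohortConfig(n_eyes=80, seed=5, octa_missing_frac=0.0),
                         mode="effect", effect=effect)
res = fit_weighted_univariable(cohort["fd"].to_numpy(),
                               cohort["bcva_1y_logmar"].to_numpy(),
                               RegressionSpec("fd", "bcva_1y_logmar", unit=1.0))
print(f"beta = {res.beta:.3f}  95% CI [{res.ci_low:.3f}; {res.ci_high:.3f}]  "
      f"p = {res.p_value:.4f}  (n = {res.n})")
```

prints

```
area = 0.676 mm^2
flow density = 86.1 %
fractal dimension = 1.352
sumL = 19.548 mm (generator ground truth 19.424 mm)
beta = 0.781  95% CI [0.310; 1.251]  p = 0.0014  (n = 80)
```

The morphometry block shows one simulated lesion: its skeleton length is
within ~1% of the generator's summed branch lengths, and the FD of ~1.35
sits between a line (1) and a plane-filling structure (2), as expected for
a branching network. The regression block fits one noisy 80-eye cohort:
the single-cohort slope estimate (0.781) scatters around the generating
slope 1.017 with the sampling error implied by a residual SD of 0.35
logMAR at n = 80; averaging over many cohorts recovers the slope (see the
acceptance script).

## Command line

```sh
mnvquant simulate-cohort --n-eyes 96 --seed 1 --out cohort.csv
mnvquant simulate-mnv --n-eyes 5 --seed 1 --out-dir masks/
mnvquant quantify --manifest masks/manifest.csv --out morph.csv
mnvquant regress --cohort cohort.csv --dv n_ivi_1y --out results.csv
mnvquant run-all --seed 1 --out run/      # full pipeline + markdown report
mnvquant report --results results.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time, the package's
headline simulation quantities: the mean recovered regression slope over
200 effect-mode synthetic cohorts for three anchored predictor/outcome
pairs (fractal dimension → 1-year BCVA at n = 80; PED presence after
loading → injection count at n = 94; CRT after loading, per 200 µm →
injection count at n = 94), and the baseline SRF-only percentage in a
100,000-eye marginal cohort. Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/mnvquant/weights.py` — percentile band and Gaussian tail weights
- `src/mnvquant/regression.py` — the weighted estimator and battery runner
- `src/mnvquant/morphometry.py` — area, flow density, skeleton, FD, sumL
- `src/mnvquant/synthetic.py` — vessel-tree and cohort generators, cohort I/O
- `src/mnvquant/pipeline.py`, `src/mnvquant/cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
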