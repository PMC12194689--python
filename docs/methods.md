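# Methods

## Scientific setting

In neovascular age-related macular degeneration, a macular
neovascularization (MNV) complex grows under or into the retina and is
treated with intravitreal anti-VEGF injections (IVIs), beginning with a
loading phase of three monthly injections ("upload"). Two outcomes matter
a year later: best corrected visual acuity (BCVA, logMAR — higher is
worse) and the number of injections needed. Candidate predictors are
structural OCT findings (intraretinal/subretinal fluid, pigment epithelium
detachment presence and height, central retinal thickness, and their
changes over the loading phase) and OCTA descriptors of the MNV vascular
network itself (area, flow density, fractal dimension, total vessel
length). This package implements the quantification of those descriptors
from binary en-face masks, the outlier-robust univariable regressions
relating them to outcomes, and synthetic generators that stand in for the
unavailable clinical data.

## Morphometry

Input is a pair of binary masks on one grid: the outlined lesion region
and the pixels with a flow signal. The flow mask is intersected with the
lesion on load. Pixel scale defaults to 6 mm / 500 px = **0.012 mm** and
is configurable for other devices.

- **Area** = lesion pixel count × pixel_size². The outlined lesion region
  (not the union of vessel pixels) is used, consistent with flow density
  being a proportion *of the displayed lesion area*.
- **Flow density** = 100 × |flow| / |lesion| (%).
- **Skeleton**: topology-preserving morphological thinning
  (`skimage.morphology.skeletonize`) of the flow mask, converted to an
  8-connected pixel graph. Thinning replaces an earlier gradient-field
  skeletonizer that is not reproducible from its description; the intent —
  a one-pixel-wide centerline — is identical and the substitute is
  testable against analytic shapes.
- **sumL** = Σ over skeleton edges of pixel_size (orthogonal) or
  √2·pixel_size (diagonal), each 8-adjacent pixel pair counted once.
  Whether real-device software counts diagonal steps as 1 or √2 is not
  documentable; √2 is the geometrically faithful choice.
- **FD**: box counting on the rasterized skeleton. Box sizes are powers of
  two from 2 px up to half the shorter frame side, grid anchored at the
  origin (no offset averaging), and FD is minus the least-squares slope of
  log N(ε) against log ε. A single isolated pixel has FD 0; a line ≈ 1; a
  filled frame ≈ 2. The substrate is configurable
  (`fd_substrate="binarized"` measures the flow mask instead); the
  skeleton default matches cohort-scale FD values around 1.29.

Numerical behaviour worth knowing: area and flow density are exactly
invariant under 90° mask rotation; skeleton-derived quantities are not,
because the thinning sub-iterations sweep directions in a fixed order —
measured differences are ~1–2.5% in sumL on synthetic trees, and the test
suite asserts 3%. Area scales exactly quadratically and sumL linearly
with pixel size.

## Weighted regression

For each univariable fit the two involved variables (the predictor and
the outcome — interpreted as exactly those two, since only they are
involved in a univariable model) each define a weighting band from their
own sample: t_low = p₁₀ − 1.5(p₉₀ − p₁₀), t_high = p₉₀ + 1.5(p₉₀ − p₁₀),
with the Gaussian tail weight
w(x) = exp(−½·(max(0, t_low−x, x−t_high)/s)²), s = ½(t_high − t_low).
Observation weights are the geometric mean of the two factors.

Choices where the procedure is underdetermined:

- **Quantile rule**: linear interpolation between order statistics
  ("type 7"), the default of mainstream numerical environments and
  continuous in the data.
- **Degenerate band** (p₁₀ = p₉₀): all weights 1 — no dispersion means no
  identifiable outliers, and it avoids division by zero.
- **Binary 0/1 predictors**: the formula applies unchanged; both levels
  fall inside the band, so weights are 1 without special-casing.
- **SE convention**: classical WLS with weights as precision weights —
  β̂ from the weighted normal equations, σ̂² = Σwr²/(n−2),
  SE(β̂)² = σ̂²/Σw(x−x̄_w)², 95% CI = β̂ ± t₀.₉₇₅,ₙ₋₂·SE, two-sided t-test.
  The solve is delegated to `statsmodels.WLS`; tests verify it against an
  independent closed-form normal-equations oracle to 1e-8.
- **Unit scaling**: the predictor is divided by its clinical unit (200 µm,
  20 mm, 10%, …) before fitting so slopes read per clinical unit. Weights
  are computed on raw values; by affine invariance of the band this
  commutes with scaling.
- **Relative decreases** ("decrease during upload", fitted per 10%):
  100·(baseline − follow-up)/baseline, defined only where baseline > 0. A
  percent unit implies a relative measure; a completely resolved PED
  counts as a 100% height decrease. Eyes without baseline PED contribute
  no decrease value, which reproduces the smaller per-row n for that
  predictor.
- **Missing data**: complete cases per regression, no imputation — each
  battery row reports its own n.
- Each of the three post-loading fluid states (IRF, SRF, both) is fitted
  as its own 0/1 indicator in a separate univariable model.

No multivariable modelling and no multiplicity correction are performed;
the analysis this mirrors is explicitly univariable with unadjusted
p-values.

## Synthetic data

**Vessel trees.** Branches are chains of straight segments grown from
`n_trunks` roots placed in the central third of the frame: segment length
decays by `len_decay` per generation, heading jitters by a Gaussian of SD
`angle_jitter_deg` per segment, and each segment spawns a side branch
(25–50° away) with probability `branch_prob`. Growth stops at the frame
border, so the summed Euclidean length of drawn segments is an exact
ground truth for the rasterized centerline. The flow mask is the
centerline dilated to `thickness_px`; the lesion mask is its morphological
closing. Rasterization and re-thinning bias the measured sumL by a few
percent (chain-code length of a digital line slightly exceeds the
Euclidean length; thinning erodes branch tips); the measured-vs-truth
agreement is tested at 10%.

**Cohorts.** Defaults state the published 96-eye world: age 77.9 ± 7.1 y;
MNV types 1/2/3 at 49.0/30.2/20.8%; BCVA 0.58 ± 0.33 (baseline) and
0.54 ± 0.40 logMAR (1 y); 8.26 ± 2.92 IVIs, rounded to an integer and
floored at 3 (the loading injections are always given); baseline fluid
IRF-only/SRF-only/both at 8.3/41.7/50.0%; PED prevalence 65.5%, height
177 ± 202 µm; CRT 469 ± 177 µm, decreasing 83.3 ± 26.5 µm over loading
(CRT floored at 50 µm); PED height decreasing 47.0 ± 48.0 µm (floored at
5 µm) when the PED persists; OCTA panel (area 1.56 ± 1.84 mm², flow
density 41.2 ± 5.2%, FD 1.292 ± 0.142, sumL 18.2 ± 21.7 mm) missing as a
whole block for 16/96 eyes. Fluid/PED transitions over loading are
parameterized as conditional probabilities derived from the published
cohort-level fractions (IRF disappears/persists/new/stable-absent =
40.6/17.7/2.1/39.6%; SRF 64.6/27.1%, no new SRF; PED 22.3/42.6/6.4% —
the PED figures sum to 64.9% against a 65.5% prevalence, a published
rounding inconsistency absorbed into the conditionals, implying a
post-loading PED prevalence of 0.49).

Family choices: plain normal for logMAR acuity, age and FD; normal
truncated at 0 for non-negative skewed quantities (heights, CRT, area,
sumL, injection counts before flooring); categorical for states; columns
independent in marginal mode (only univariable analyses are mirrored, so
joint structure is not needed and none is published). Truncated columns
are parameterized by the *parent* moments: several published SDs exceed
their means (PED height, area, sumL), which no truncated normal can match
exactly, so where truncation bites the realized mean sits above the
configured figure. Consequently the generator-calibration tests assert
3-Monte-Carlo-SE agreement for proportions and for unclipped means
(age, BCVA, state fractions, transitions) — a green calibration test does
*not* establish that truncated or floored columns match the printed
moments, nor that any joint dependence of real cohorts is reproduced.

**Effect mode** rewrites one designated outcome as
dv = intercept + slope·(iv/unit) + N(0, σ), with the predictor optionally
redrawn from an explicit distribution, and injection counts rounded and
floored at 3. The flooring slightly attenuates recovered slopes on the
injection outcome (~2% for the PED-presence scenario: the floor lifts the
low-predictor group's mean); this is part of the stated generative world,
and recovery is asserted within 3 Monte-Carlo SEs of the generating slope
across 200 cohorts.

## Pipeline

`run_pipeline` takes one cohort source (CSV or simulation config), an
optional mask manifest, runs the 15-predictor battery against both
outcomes, and writes the result tables, a cohort summary, a markdown
report (slopes and CIs to 3 decimals, p-values both banded at <0.05/<0.01
and exact) and a log with seed, version and config hash; outputs are
byte-identical for a fixed seed. Predictors that are absent, constant, or
have fewer than 3 complete cases are reported as skipped, not errors.
Every fit logs its weight summary (min/mean weight, down-weighted count).

## Known limitations

- Purely 2-D en-face analysis of the perfused network: no OCTA signal
  processing, projection-artifact handling, automatic lesion outlining, or
  volumetric descriptors.
- Box counting uses a single origin-anchored grid; offset averaging would
  reduce small-sample FD bias but break determinism of the simple ladder.
- Skeleton-derived measures depend on the thinning algorithm; absolute
  sumL/FD values are comparable within this package, not across devices.
- The synthetic cohort is a marginal emulation; recovered slopes under a
  correlated-covariate world would not match univariable targets.
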