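# Methods

This note documents the statistical model behind each module, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Connectome construction and thresholding

A connectome is the matrix of Pearson correlations between regional
resting-state time series. The primary mode is **absolute**: entry (i, j)
is |r_ij|, following the convention that anticorrelations contribute
magnitude; a **signed** mode keeps raw correlations for control analyses.
The diagonal is always zero.

**Proportional thresholding** retains k = round(p·E) of the E = n(n−1)/2
upper-triangle edges, where "strongest" means largest value in absolute
mode and largest magnitude in signed mode. Conventions chosen here, since
a bare proportion does not determine them:

- rounding: k = ⌊p·E + 0.5⌋ (exact .5 rounds up);
- tie-break at the cut: stable order by (strength desc, i asc, j asc), so
  results are identical across platforms;
- thresholding is **per subject** — each subject keeps their own strongest
  edges.

Mean FC over a matrix (or an edge subset) averages retained edges only:
zeroed edges leave the denominator. For an unthresholded matrix every
upper-triangle edge counts, including exact zeros. Network summaries split
edges by endpoint labels (within = same network, between = different); a
network with fewer than two ROIs has no internal edges and its per-network
mean is NaN, flagged in `undefined_networks`.

**PSMD** is the 95th minus 5th percentile of skeletonized mean-diffusivity
values. The percentile convention is linear interpolation between closest
ranks (numpy's default), exposed via the `method` argument since percentile
conventions differ across tools. The statistic is translation-invariant and
scales linearly with the input. Skeletonization itself (TBSS) and surface
reconstruction are out of scope; the statistic consumes a ready vector.

The **TMT B/A ratio** (both times in seconds, both required positive)
isolates set-shifting cost from psychomotor speed.

## Regression layer

Univariate fits report the OLS slope, the bivariate Pearson r, r², and the
two-sided p from t with n−2 df. Adjusted models (default covariates: sex,
education) are ordinary least squares with an intercept that is fitted but
not reported. The standardized coefficient is β·sd(x)/sd(y) with sample
SDs (n−1 denominator); this convention is stated because others exist.
Rows with missing values are dropped listwise and logged. Rank-deficient
designs raise an error listing the collinear terms. The family threshold
is α/m (0.05/7 ≈ 0.007 for three global measures plus four networks),
reported rounded to three decimals in output tables.

## Network-based statistic

Edge-wise statistics: for each upper-triangle edge, the t of the
predictor's slope in a per-edge linear model. The default model is simple
regression of edge FC on age, mirroring the analysis design; covariate
adjustment (partial-correlation t with n−q−1 df) is a flag, since whether
the edge model should adjust for sex/education is genuinely open — both
modes are provided and neither is asserted as canonical. Edges constant
across subjects are excluded (t = NaN, logged); perfectly fitted edges get
a ±1e6 sentinel, above any finite threshold.

Components: edges passing the primary threshold (t < −3.2 for the primary
age-decline contrast; t > +3.2 for the separate increase test) form a
graph whose connected components are scored by **edge count** (extent, not
intensity). Component extraction uses networkx for the observed map and a
hand-rolled union-find inside the permutation loop, where per-permutation
graph construction would dominate runtime.

Permutation null: the predictor is permuted across subjects
(`n_permutations` = 5,000 by default); with covariates, Freedman–Lane
residual permutation is used instead (permute reduced-model residuals,
re-residualize, correlate). Each permutation records the maximal component
size; the FWE p of an observed component is the plain proportion of null
maxima at or above its size. The (k+1)/(n+1) variant is available via
`add_one_correction` but off by default to match the plain-proportion
definition. Without covariates, permutations are evaluated in chunks of
250 through a single matrix product per chunk, which makes null-calibration
studies (hundreds of replicates) run in seconds.

Subnetwork FC for downstream mediation averages **unthresholded** edge
values over the component's edge set, so every subject shares one
denominator.

## Mediation

The standard parallel model: a-paths regress each mediator on the exposure
(plus covariates); the outcome equation contains the exposure and all
mediators jointly; the total effect comes from the outcome-on-exposure
regression. With OLS throughout, c = c′ + Σ a_j·b_j holds exactly (verified
to 1e−8 on every fit). An alternative mode adds the other mediators to each
a-path equation — the phrase "each mediator was a covariate for the others"
is ambiguous between the two — but the standard mode is the default and the
identity is only guaranteed there.

Bootstrap inference resamples subjects with replacement. Per effect:
percentile 95% CI (bias-corrected available via `ci_type="bc"`), bootstrap
SE, and a two-sided sign-based p = 2·min(P(est ≤ 0), P(est ≥ 0)). A
resample with constant exposure is redrawn and logged; fewer than 100 draws
triggers a warning. Resamples are evaluated in batches through closed-form
normal-equation solves (`einsum` + batched `solve`), so 10,000 draws at
n ≈ 1,000 take well under a second. Standardized effects are the
unstandardized ones rescaled by the resample's own sample SDs, which equals
refitting on z-scored data.

## Synthetic cohort generator

The generator's defaults are the emulated study conditions: 976 subjects,
ages uniform integers on [45, 74], 45.4% female, education uniform integers
on [8, 18] (no published distribution; flagged as arbitrary), 200-ROI
absolute-mode connectomes with baseline mean FC 0.36 and edge noise SD 0.10.

**Correlation targeting.** Each age-linked variable is linear in age plus
Gaussian noise; the noise SD is solved analytically from the slope and the
population age variance so that the population correlation equals its
target (−0.4 thickness, +0.5 PSMD, +0.32 TMTA, +0.3 TMTB). Anchors and
per-year drifts (thickness −0.012 mm/y around 2.4 mm; PSMD +3e−6 mm²/s/y
around 2.17e−4; TMT medians 36/79 s) are calibrated to the published cohort
marginals. TMT times are truncated below at 5 s to stay positive. A zero
target yields a genuinely age-independent variable at a realistic spread.

**Planted structure.** A connected random subgraph inside the default
network (fraction `planted_edge_fraction` of its edges, 10% by default —
matching the reported share of affected connections) carries the age
effect:

    edge = 0.36 + c′·(age − ā) + b·(thickness − 2.4) + u + ε,

with b = `mediation_b` (0.02 FC/mm) and c′ derived so that the **total**
expected age slope c′ + a·b equals `planted_slope` (−0.002 FC/y by
default, giving per-edge |t| ≈ 5 at n = 976). u is a per-subject latent
factor (SD 0.03, from the published mean-FC IQR ≈ 0.04) shared by all
planted edges and fed into TMTB with coefficient `outcome_b_fc`
(−50 s per FC unit), creating a real age → FC → executive-function channel
for model-two mediation. Non-planted edges are baseline + noise with zero
expected age slope. Edges are clipped to [0.01, 0.99], which is > 3 SD from
baseline and does not materially alter expected slopes. The generating
(a, b, c′) and the planted edge list are returned as ground truth.

**What is not emulated:** BOLD spectral structure, head motion, spatial
autocorrelation and smoothness, distance-dependent edge noise, site or
scanner effects, non-linear age trajectories, and the empirical (non-
uniform) age distribution of a volunteer cohort — the synthetic median age
is ≈ 59.5 rather than 63. Passing tests therefore demonstrate statistical
correctness of the machinery (calibration, error control, power, recovery)
under clean Gaussian conditions, not robustness to fMRI artifacts.

Time-series generation (for exercising the correlation step) draws
Gaussian vectors through the Cholesky factor of a target correlation
matrix; a non-positive-definite target is rejected naming the offending
eigenvalue. Default length is 125 volumes at TR 2.5 s (the 5.2-min
acquisition).

## Pipeline

Stage order: load/align inputs → cohort summary (median/IQR, linear
interpolation quantiles) → per-subject thresholding at 50% and network
means → univariate age fits (the TMT ratio is dropped downstream when its
age association fails p ≤ 0.05, mirroring the design) → adjusted
regressions with the Bonferroni gate on each network's age p-value → NBS
on the whole brain and each surviving network (unthresholded matrices) →
per-subject subnetwork FC from the largest significant component per scope
(named networks take precedence when the whole-brain component coincides
with a network's; exact duplicate columns are dropped) → mediation model
one (age → thickness, PSMD → subnetwork FC) and model two (age → subnetwork
FCs → TMTB/TMTA). The young/old split for the summary table is ≤ 63 vs
> 63 years.

One master seed derives every stage seed through `SeedSequence`; two runs
of one configuration are byte-identical (tables are written with a fixed
`%.10g` float format). The provenance block records the config, its hash,
the seed, and the package version. Configuration files are flat YAML
mappings; unknown keys are rejected.

## Problem sizes in the validation suite

The test suite scales Monte-Carlo studies to what the guarantees need:
FWE control uses 200 null cohorts (150 subjects, 60 ROIs, 500
permutations); power uses 100 cohorts with a planted 20-edge component at
per-edge |t| ≈ 6 (n = 200); bootstrap-CI coverage uses 500 cohorts of
n = 1,000 with 1,000 draws each; oracle comparisons use 200 random graphs
and 100 random designs. The acceptance script runs the full pipeline at
the emulated study scale (976 subjects, 200 ROIs, 5,000 permutations,
10,000 bootstrap draws).

## Known limitations

- FC values are treated as plain responses; no Fisher z-transform is
  applied before edge-wise modeling (matching the analysis design).
- Component scoring is extent-only; intensity weighting and threshold-free
  enhancement are out of scope.
- The mediation models are linear OLS path models: no latent variables,
  serial mediation, moderated mediation or fit indices.
- The plain-proportion FWE p can be exactly 0; use `add_one_correction`
  when a strictly positive p is required.
- Graph metrics beyond component structure and node degree (efficiency,
  modularity, segregation) are deliberately not provided.
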