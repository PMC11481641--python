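# Methods

## Scope and model

`gwquality` assesses shallow-groundwater quality in a municipal
monitoring-well network and quantifies the effect of an intervention — here
the construction of a sewerage network — on that quality. It combines four
stages: two composite indices per well sample, five-rank classification,
pre/post-period statistics, and spatial interpolation of the index surfaces.

### Weighted-arithmetic water quality index (WQI)

For parameters n = 1..N with measured value Vn, ideal value Vi and
permissible limit Vs:

    Qn  = 100 |Vn − Vi| / (Vs − Vi)          quality rating
    Wn  = k / Vs,  k = 1 / Σ(1/Vs)           unit weight (Σ Wn = 1)
    WQI = Σ Qn Wn / Σ Wn = Σ Qn Wn

Vi = 0 for all concentrations and 7 (neutrality) for pH, so every non-pH
rating reduces to 100·Vn/Vs and the index is linear in those parameters.
Weights are inversely proportional to the limit, which makes the index very
sensitive to parameters with tight limits (NH4+, NO2−, PO4 3− at 0.5 mg/L
each jointly carry ~94% of the weight under the default profile) and nearly
insensitive to EC (limit 2500 μS/cm, weight ~6e-5).

**pH convention.** The rating uses the absolute deviation |Vn − 7|, so pH
below neutral is penalised symmetrically rather than entering negatively; Vs
for pH is the upper bound 8.5 of the regulatory range 6.5–8.5. Negative
ratings are meaningless in this index family, and under this convention the
index evaluated at each campaign year's mean parameter vector reproduces the
corresponding published mean index within 1% (see the acceptance script).
This is a design choice: alternatives (signed deviation, or rating against
the lower bound below 6.5) are not implemented.

### Contamination degree (Cd)

    Cd = Σ_i Cfi,   Cfi = CAi/CNi − 1   only when CAi > CNi

Parameters at or below their upper permissible concentration CNi contribute
nothing — equality does not exceed. pH is treated two-sided: above 8.5 the
factor is CAi/8.5 − 1; below 6.5 it is the reciprocal form 6.5/CAi − 1,
which keeps every factor positive and dimensionless. Whether pH should
enter a contamination sum at all is genuinely open in this index family; the
two-sided treatment is the package's choice and can be disabled by removing
the lower bound from the standards profile.

Because Cd is piecewise-linear (a hinge at each limit), the index of a mean
parameter vector is *not* an estimate of the mean of the index; the package
documents this and never asserts it (the 2013 mean vector scores Cd = 5.50
against a published mean Cd of 6.41 — an expected discrepancy, not an
error).

### Rank scales

Both indices map onto five ranks (1 best … 5 worst). The printed
integer-style WQI bins (0–25, 26–50, 51–75, 76–100, above 100) are closed
up to contiguous half-open intervals so that any real value classifies
exactly once: [0,25], (25,50], (50,75], (75,100], (100,∞). The Cd bins are
{0}, (0,1), [1,3), [3,6], (6,∞). Bin-edge comparisons use exact
floating-point arithmetic on the input (no epsilon), so classification is
reproducible bit for bit.

## Standards profile

The default profile `hu_6_2009` carries the groundwater contamination limits
of the Hungarian joint decree 6/2009 (IV. 14.) KvVM-EüM-FVM: pH 6.5–8.5,
EC 2500 μS/cm, NH4+ 0.5, NO2− 0.5, NO3− 50, PO4 3− 0.5, COD 4.5, Na+
200 mg/L. Profiles are plain YAML; per-parameter CNi may differ from Vs.

## Synthetic monitoring campaigns

The raw well measurements of the motivating campaign are not public, so the
package ships a generator whose defaults reproduce the campaign's design:
40 wells placed uniformly on a 2 km × 2 km extent, sampled in 2013
(pre-sewerage) and 2017, 2018, 2019, 2021, 2022 (post-sewerage; no 2020
campaign), with 3 wells dry in 2021 and 6 in 2022 — 231 samples in total.
Dropout wells persist (the same wells stay dry), chosen deterministically
from the seed.

**Marginals.** Concentrations are lognormal — right-skewed, positive, and
consistent with the published mean > median pattern; pH is normal, truncated
to (0, 14) as a safety clamp (the truncation is ~12σ away from the data and
never binds in practice). Each year × parameter marginal is calibrated to
the published summary row by

    σ = ln(q75/q25) / (2 z₀.₇₅),   μ = ln(mean) − σ²/2     (lognormal)
    σ = (q75 − q25) / (2 z₀.₇₅),   μ = mean                (normal)

with z₀.₇₅ = 0.6744898. The calibration is overdetermined (three numbers,
two parameters): the analytic mean is matched exactly and the quartile
*ratio* exactly; the individual quartiles are matched only approximately
(for EC 2013 they deviate ~12%, because the printed mean/quartile geometry
is not exactly lognormal). The intervention is encoded in the per-year
targets themselves; an explicit per-parameter multiplicative effect factor
for post-boundary years exists as a mechanism (default 1.0 in the shipped
config) for controlled experiments.

**Spatial structure.** One zero-mean unit-variance Gaussian latent field
with exponential covariance exp(−d/range), range 500 m, realised by Cholesky
factorisation (coincident points are deduplicated first so they share the
exact field value). Each parameter's standard-normal driver is
√s·F + √(1−s)·ε with sill fraction s = 0.5, mixed on the log scale for
concentrations and additively for pH — marginals keep their calibrated
(μ, σ) exactly. The field is drawn **once per campaign and reused in every
year**: contamination plume geometry around leaking sources is persistent on
a decade scale, successive years' maps should be mutually coherent, and the
well-level persistence is precisely what gives the paired pre/post test its
power. With sill fraction 0 the field stage is skipped entirely (pure-noise
marginals; used for large-n calibration checks).

**What the generator does not emulate.** Temporal dynamics within the
post period beyond the per-year calibration (no autoregressive evolution of
the noise component), measurement error as a separate variance component,
censoring at detection limits, rainfall covariates, and any
hydrogeological process (flow, transport). Passing tests therefore show the
pipeline recovers effects of the calibrated size and shape from data with
this covariance structure — not that it would do so on any real network.

## Statistics

- **Summaries** use linear interpolation between order statistics for
  quartiles (the inclusive convention shared by spreadsheets and most
  statistics packages; the original processing software's convention is
  unknown).
- **Spearman** rank correlation with average ranks for ties; p from the
  t-approximation, or exact permutation (full n! enumeration) for n ≤ 8.
- **Wilcoxon signed-rank**, pairing each well's mean pre-period index with
  its mean post-period index (wells seen in only one period are dropped;
  with a single pre year this is the well's 2013 value against its post
  mean). Zero differences are dropped (classic convention; Pratt's method is
  a flag), |d| ranked with average ties, W = min(W+, W−). For effective
  n ≤ 15 the two-tailed p is exact, from the full 2^n sign-assignment
  distribution of the observed ranks (computed by convolution); beyond that
  the tie-corrected normal approximation is used. Z is reported signed,
  negative when the post period is lower.
- **Fisher two-group discriminant**: direction w solves Sw·w = m₁ − m₂ with
  the pooled within-group scatter; classification by nearest projected group
  mean with the midpoint cut (equal priors; boundary ties go to the first
  group deterministically). Wilks' Λ = 1/(1 + λ) with λ the
  between/within scatter ratio along w; significance via Bartlett's
  chi-square. Leave-one-out refits the discriminant n times. A singular
  scatter matrix is ridged by 1e-8·trace (with a warning). Features default
  to the eight chemical parameters; `discriminant_features="indices"`
  switches to the two index values — both modes exist because either is a
  defensible reading of the original analysis description.
- **No multiple-testing correction** is applied anywhere: the stage reports
  the same small set of single tests the workflow defines.

## Interpolation

Global ordinary kriging (no search neighbourhood — defensible and exact for
networks of a few dozen wells): the (n+1)×(n+1) semivariance system with
the unit-sum constraint is LU-factorised once and solved for all grid nodes;
weights sum to 1 at every node (asserted to 1e-8), prediction at a data
point with zero nugget returns the datum exactly, and the kriging variance
is reported per node (clipped at 0 against roundoff). Duplicate well
locations are averaged before the solve. The default variogram is spherical
with zero nugget, fitted to the binned empirical semivariogram by weighted
least squares with pair-count weights; fewer than 3 usable lags or optimiser
failure falls back to a flagged default model (nugget 0, sill at the mean
empirical semivariance, range at half the maximum lag). IDW (power 2) is the
model-free fallback.

Grids default to the well bounding box padded 10% with 50 m cells; row 0 is
the northernmost row and cell centres are the prediction locations. Rasters
are written as ESRI ASCII grids with a `.prj` sidecar carrying the CRS
identifier — a plain-text format every GIS ingests; values use shortest
round-trip float formatting so write→read is bit-exact.

## Numerical and degenerate-input choices

- Weight normalisation Σ Wn = 1 is asserted to 1e-9 at construction.
- Missing parameter values: the WQI raises by default (its weights are
  global over the configured set) with an opt-in renormalise-over-present
  mode that flags the result partial; Cd silently skips missing parameters
  (a value that was not measured cannot exceed its limit).
- Degenerate calibration (q25 = q75) yields a flagged point mass at the
  mean, not an error.
- All generator randomness flows through one `numpy` Generator seeded from
  the config; identical config + seed ⇒ byte-identical output, which the
  pipeline's run manifest records together with a config hash.

## Problem sizes

Default analyses operate at the campaign's own scale (40 wells × 6 years,
231 samples; 40-point kriging systems; ~45×45 grids at 50 m cells).
Replicated checks in the test-suite and acceptance script use 200 seeded
campaigns for the intervention-recovery rates and 10,000 wells for
marginal-calibration convergence — sizes at which the binomial/Monte-Carlo
error of the checked rates is well below the asserted margins.

## Known limitations

- The two-sided pH contamination factor and the absolute-deviation pH
  rating are conventions chosen here; sites using different conventions
  should edit the standards profile accordingly.
- The generator matches first moments and quartile ratios per year but not
  printed minima/maxima; extreme-value behaviour of the synthetic indices is
  therefore milder than in the real campaign.
- Kriging assumes isotropy and a global stationary variogram; no
  cross-validation-based model selection is performed.
- The discriminant stage assumes exactly two groups and equal priors.
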