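# Methods note

This note documents the statistical model, the synthetic data generator, the
numerical choices, and the known limitations of the `pwastox` package.

## 1. Exposure assessment model

**Geometry.** Each participant address is surrounded by a disc buffer of
radius 500 m (configurable). For each field parcel, the exposure weight is
the fraction of the parcel's area inside the buffer. The pipeline computes
this with exact polygon arithmetic on shapely geometries, approximating the
disc by a regular 64-gon (`quad_segs=16`). The 64-gon under-covers the true
disc by a relative area of about `1 - (n/2π)·sin(2π/n) ≈ 1.6e-3` for n = 64;
a 1 m raster oracle in the test suite bounds the end-to-end error of the
fraction at < 0.01. The synthetic generator computes participant ground truth
through an independent closed-form circle–rectangle overlap routine
(corner-integral decomposition of the disc over the rectangle edges), so the
polygonal pipeline is validated against an analytically exact second route.

**Annual values.** Each application record contributes
`(pounds / acres_treated) × buffer_fraction` to that parcel-year's pesticide
value, in lbs/acre units; contributions are summed per calendar year. Records
with non-positive treated acres are rejected with an error naming the record.
When a participant occupies several addresses of one location type in the
same year, the yearly value is the duration-weighted mean over spells
(month-weighted when `start_month`/`end_month` columns exist, equal weights
otherwise).

**Window averaging.** The exposure window is 1974 through ten years before
the participant's index year. The windowed summary is the mean of annual
values over window years covered by at least one address spell of that
location type; participants with zero covered years get a *missing* (not
zero) summary for that location type. Residential and workplace histories are
assessed as separate layers.

**Transformation.** Raw summaries are `log(x+1)`-transformed, centered, and
scaled to unit SD within each wave × location-type stratum, pooled over cases
and controls, so association estimates are odds ratios per SD of transformed
exposure. Zero-variance pesticide-strata raise an error (strict mode) or
yield missing values with a log entry (pipeline mode).

## 2. Association screen

Per pesticide, an unconditional maximum-likelihood logistic regression of
case status on the standardized exposure is fitted within each wave ×
location-type stratum (statsmodels). A stratum contributes only when the
pesticide has at least one exposed case and one exposed control there;
non-convergent or separated fits are flagged and skipped. Stratum log odds
ratios are pooled by inverse-variance fixed-effects meta-analysis
(weights 1/SE², pooled SE `(Σw)^(-1/2)`, two-sided normal p-value).
Benjamini–Hochberg q-values are computed across pesticides; discovery tiers
are FDR ≤ 0.01, (0.01, 0.05], and (0.05, 0.10). "Implicated" means
q < 0.10; the overrepresentation input set ("associated") is q ≤ 0.05.
Pesticides with fewer than 25 exposed participants (raw value > 0 at either
location type) are excluded from testing.

The fixed-effects choice reflects the design: strata are waves of one study
population under a common protocol, so a common-effect model is the natural
pooling rule and keeps the screen well-defined with as few as one usable
stratum. An exposure-by-modifier interaction test (product-term Wald test per
stratum, meta-combined) is provided for follow-up of single pesticides.

## 3. Overrepresentation analysis

For each annotation group, the 2×2 table of group membership versus
association over the tested universe is analyzed in the Fisher exact
framework: the two-sided Fisher exact p-value (summation convention), the
*conditional maximum-likelihood* odds ratio (the ψ maximizing the noncentral
hypergeometric likelihood of the observed top-left cell given all margins,
found by root-finding on E[A|ψ] = a), and the exact 95% CI obtained by
inverting the noncentral hypergeometric tails at 2.5% per side
(`P(X ≥ a | ψ_lo) = 0.025`, `P(X ≤ a | ψ_hi) = 0.025`). The conditional MLE
is used instead of the sample cross-product ratio deliberately; on the
reference table `[[19, 34], [31, 202]]` they give 3.62 vs 3.64. Boundary
tables return 0 or ∞ with the corresponding CI bound. BH adjustment is
applied across groups.

## 4. Co-exposure structure

Pairwise Pearson correlations of standardized residential exposures among
implicated pesticides are computed pairwise-complete; zero-variance
pesticides become missing rows. The two-layer network connects a neurotoxic
pesticide to a non-toxic implicated one when R > 0.45 (within-layer edges are
not represented); node closeness centrality is computed on the edge-bearing
subgraph. Hierarchical clustering runs on distance 1 − R with *complete*
linkage, cut at height 0.55: complete linkage makes the cut height a
guarantee — every within-cluster pair is correlated at R ≥ 0.45 — which is
exactly coherent with the network threshold. Cluster labels are
deterministic (decreasing size, ties by lexically smallest member). Crop
shares are the per-pesticide proportion of application records on a crop.

## 5. Screen statistics

Object-level detections are gated strictly: 40 < area < 400, roundness > 0.7,
intensity > 500. The reporter-positive cutoff is mean + 3 SD of gated object
intensities in control (DMSO) wells; per-well counts of gated objects above
the cutoff are the assay readout. A condition is called toxic when its mean
count falls strictly below mean(DMSO) − 3·SD(DMSO). Assay quality is
`Z' = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|` over the control arms. Dose
summaries report per-dose mean counts and percent decrease versus DMSO, with
an LD50 interpolated log-linearly between the doses bracketing the 50% level
(missing when not bracketed).

The all-combinations co-exposure analysis takes one well group per subset of
the compound panel (2^k conditions including DMSO). Each multi-compound
subset is compared with each constituent singleton and with DMSO by Student's
t-test (equal variances by default, matching the small per-condition
replicate counts), BH-adjusted over all comparisons; a pair is flagged
*enhanced toxicity* when it is significantly lower (q < 0.05) than both of
its constituents.

Mito-stress parameters from OCR traces use vendor-standard cycle selections:
non-mitochondrial respiration = minimum after rotenone/antimycin A; basal =
last pre-oligomycin cycle − non-mitochondrial; ATP-linked = last
pre-oligomycin − post-oligomycin minimum; maximal = post-FCCP maximum −
non-mitochondrial; spare = maximal − basal (and as percent,
100·maximal/basal). Parameters are invariant to a constant baseline shift
except `non_mito`, which absorbs it.

## 6. Synthetic data generator

**Landscape.** Rectangular parcels on a jittered grid (margins 3–18% of the
cell), so parcels never overlap and areas are exact; crops are drawn from a
configurable mixture. **Applications.** Per cluster, one shared
parcel-year Bernoulli indicator; each member copies it with probability equal
to the cluster correlation (0.8 by default) or draws independently, which
plants a tunable co-application structure. Crop-restricted pesticides (the
simulated cotton defoliants and one cotton herbicide) appear only on their
crop. Pounds are lognormal; treated acres are a uniform fraction of the
parcel.

**Cohorts.** Two routes share one causal model — a logistic outcome whose
linear predictor is Σ β_p · z_p over configured causal pesticides (z on the
same log1p-standardized scale the analysis estimates on) plus centered
covariate terms:

* the *geospatial route* draws address spells inside the landscape, computes
  true exposures with the closed-form overlap routine, and rejection-samples
  case status to per-wave quotas;
* the *statistical route* draws raw exposures from a cluster-correlated
  lognormal hurdle model (latent factor `U = √ρ·F + √(1−ρ)·ε`, exposed when
  U exceeds the prevalence quantile, lognormal intensity given exposure),
  emulating the right-skewed, zero-inflated, cluster-correlated joint
  distribution of the geospatial route at a fraction of the cost — this is
  what makes 200-replicate calibration studies feasible.

**Plates.** Well counts are Poisson with mean = Hill response × lognormal
well noise (σ = 0.08). Object tables mix a dominant dim background
population (the cutoff lands between the populations because the dim
population dominates control wells), a sparse bright reporter-positive
population whose per-well size is the ground-truth count, and junk objects
that each fail exactly one gate. Combination plates follow multiplicative-
independence survival times configured pairwise interaction multipliers.
**OCR.** Piecewise-constant traces at the configured truth levels plus
optional Gaussian noise (zero by default, making inversion exact).

**Realism and limits.** The generator reproduces the qualitative features
the analysis is sensitive to — skewed hurdle exposures, co-application
correlation, stratified waves, Hill dose-response, two-population intensity
mixtures — but not secular trends in application records, spatial
autocorrelation of crops, address moves correlated with exposure,
measurement error in geocoding, or plate-position effects.

## 7. Numerical choices

* All randomness flows from one master seed through named per-artifact
  streams (`default_rng([seed mod 2^31, stream])`), so regenerating one
  artifact never perturbs another and derived seeds stay below 2^31.
* Root-finding for the conditional MLE and exact CI uses Brent's method on
  log-odds in [−50, 50] with xtol 1e-12; support boundaries short-circuit to
  0/∞.
* Logistic fits flag non-convergence and SE ≥ 50 (a practical separation
  guard) rather than failing the whole screen.
* CSV output uses `%.10g` floats; identical configuration and seed produce
  byte-identical runs.
* BH adjustment delegates to statsmodels; correlation, linkage and
  centrality delegate to pandas/scipy/networkx.

## 8. Limitations

* Wald confidence intervals from moderate stratum sizes carry the usual
  slight under-coverage of ML asymptotics (~94–95% empirically at n = 2000).
* The fixed-effects pooling assumes a common stratum effect; heterogeneity
  is not tested in the screening pass.
* The 3-SD toxicity call depends on the control-arm SD estimate; with few
  control wells the false-flag rate across hundreds of null tests is
  non-negligible (see the sizing analysis in the acceptance suite, which
  uses 24 control wells and 4 replicates).
* The exposure model treats the parcel-area fraction as the within-parcel
  application weight; actual within-field spray placement is unknown.
* Synthetic calibration covers the implemented model; it cannot validate
  assumptions about real cohort recruitment or recall.
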