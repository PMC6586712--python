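# Methods

## Site-level metrics

A site's vegetation is observed in `n_plots` (default 5) fixed-area plots.
For each taxon, site cover = (sum of its plot covers) / `n_plots` and
frequency = (plots present) / `n_plots` × 100; the divisor is always the
configured plot count, so a plot with no record of the taxon contributes a
true zero. Sites with fewer recorded plots than configured are accepted
(validation flags out-of-range plot ids only); whether a field protocol
would instead shrink the denominator is a protocol decision we expose via
`n_plots`.

The three indicator metrics follow directly: nonnative richness (count of
distinct nonnative taxa), and relative frequency / relative cover as the
nonnative share of the summed frequencies / site covers over *all* taxa.
Taxa of undetermined native status stay in the denominators, which can
only dilute the nonnative share — the conservative direction for a
stressor indicator. Relative (not absolute) abundance is used so that
structurally rich systems (forested wetlands with many canopy layers, high
total cover) are comparable with sparse ones.

The wetland index (WI) is the cover-weighted mean of numeric wetland
indicator statuses (OBL=1, FACW=2, FAC=3, FACU=4, UPL=5) over taxa with a
defined status: 1 = entirely obligate wetland vegetation, 5 = entirely
upland. It is undefined (NaN) when no scored taxon occurs. Growth-habit
covers sum site covers within forb / graminoid / vine / shrub / tree
groups; for nonnatives, trees and shrubs are merged into one group because
woody nonnatives commonly span both habits. Importance value =
(% frequency + % cover)/2.

Percent values are carried at full precision internally; outputs round to
at most 6 decimals.

## Stressor-level decision matrix

Each metric maps to an ordered level through three ascending cutpoints
with *inclusive upper bounds* (value ≤ c1 → low, ≤ c2 → moderate, ≤ c3 →
high, > c3 → very high); exactly-at-threshold values therefore take the
lower level. The overall NNPI is the maximum over the three per-metric
levels — one strongly exceeding metric is enough to raise the site, which
encodes the judgment that cover, richness, and frequency are distinct
stress pathways. Cutpoints are configurable; the defaults
(cover 1/15/40, richness 5/10/15, frequency 10/30/60) reflect expert
assessment practice rather than a fitted boundary, and users with
different risk tolerances may supply their own. A site with no vegetation
at all classifies low and is flagged `unvegetated` rather than dropped.
The LM/HVH rollup groups low+moderate vs high+very high and is
order-preserving.

## Design-based estimation

Probability sites carry areal weights w_i (hectares represented). The
extent of a category is the Horvitz–Thompson total Σ w_i·1[site i in
category]; the population mean of a metric is Σ w_i y_i / Σ w_i. Within
any domain the four category extents sum exactly to the domain's total
weight, and scaling all weights by k scales areas and SEs by k while
leaving percentages and means unchanged.

Two variance estimators are provided for a total T = Σ z_i
(z_i = w_i y_i):

- **srs** — the with-replacement approximation
  v(T) = n/(n−1) · Σ (z_i − z̄)², the always-available fallback; for means
  it is applied to the linearized residuals e_i = w_i (y_i − ŷ).
- **local** (default) — a local-neighborhood estimator: each site's
  neighborhood is its `nbh_size` = 4 nearest sites (Euclidean, self
  included, equal weights), and
  v(T) = Σ_i Σ_{j∈D_i} (z_j − z̄_{D_i})² / (nbh_size − 1).
  The 1/(nbh−1) scaling is a finite-neighborhood bias correction: with
  equal neighborhood weights the uncorrected form is biased low by exactly
  (nbh−1)/nbh for spatially unstructured data. With the correction the
  estimator agrees with the with-replacement form on spatially random
  data and drops below it when contributions trend smoothly in space,
  which is the gain a spatially balanced design buys. The neighborhood
  size and the equal-weight kernel are deliberate simplifications of the
  published local-mean estimator family and are exposed as configuration.

CIs are estimate ± 1.96·SE (normal two-sided 95%), truncated at 0 for
areas. Domains with a single site return the point estimate with SE
flagged undefined; domains smaller than the neighborhood size fall back to
the srs form with a logged warning. A `ci_nonoverlap` helper flags pairs
of nonoverlapping CIs — a screening device, not a multiplicity-adjusted
test.

Population estimates use visit-1 probability sites only. Multi-visit
sites are classified per visit; no reconciliation across visits is
attempted.

## Signal:noise

S:N for a metric = (sample variance of visit-1 values across all sites) /
(mean over revisit pairs of (visit1 − visit2)²/2). The noise term is the
standard paired estimate of within-site, within-season variance. Zero
noise with positive signal is reported as an infinite ratio (flagged);
zero signal and zero noise raises. At least 2 sites and 2 revisit pairs
are required. Note the signal term includes the noise component, so for a
generative model with between-site variance σ_b² and within-site σ_w² the
estimand is (σ_b² + σ_w²)/σ_w².

## Composite disturbance index

Each of eight raw sub-indices is standardized to 0–10 by min-max over the
sites being analyzed (fixed reference ranges can be supplied for
cross-dataset comparability; scores are then clipped to [0, 10]); the
overall index is (Σ scores) × 10/8, range 0–100. A constant sub-index
standardizes to 0 everywhere with a logged warning — it carries no
between-site signal. A site missing any sub-index gets a missing overall
index: the formula presumes eight values and we do not impute.

## Balanced random forest

The two-class response (LM vs HVH) is typically imbalanced, so each of
the 1000 CART trees is trained on a downsampled balanced bootstrap: the
minority-class size is drawn with replacement from *each* class. mtry =
⌊√p⌋ features are examined per split (p counted after encoding). Survey
weights are not used — this is a site-scale, not population-scale,
analysis. Categorical predictors (ecoregion, wetland type) are one-hot
encoded; the encoding is recorded in the report.

Out-of-bag machinery: each site's class is predicted by majority vote of
the trees for which it was out of bag (ties → HVH, the
stress-conservative call, since a tied vote under balanced training is
genuine ambiguity); percent correctly classified is reported overall and
per class. Permutation importance is the per-tree decrease in OOB
accuracy after permuting one predictor within the tree's OOB rows,
averaged over trees; all one-hot columns of a categorical are permuted
jointly (rows keep coherent category draws), so importance is reported
per original predictor. A predictor a tree never splits on contributes an
exact 0 for that tree. Partial dependence for predictor x evaluates the
forest's HVH vote fraction with x set to each of 25 grid points (1st to
99th percentile) for every site, averaging over sites — the empirical
marginalization of the other predictors.

With the default generator the forest's OOB accuracy on 200 sites is
modest (low 70s% overall) — the synthetic labels are driven by a few
latent variables plus sampling noise, not a sharp rule — while the
behavioral guarantees (near-perfect accuracy on separable rules, chance
on permuted labels, correct importance ranking) are exercised on purpose-
built simulations in the test suite.

## Synthetic data generator

The generator emulates the survey's *structure*, not its floristics. Per
dataset: a species pool (default 400 taxa, 12% nonnative, 3%
undetermined) with growth-habit and wetland-indicator mixes matching the
observed nonnative flora's skew toward forbs/graminoids and drier
indicator statuses; per site: an ecoregion and wetland type drawn with
the survey's probability-site proportions, uniform coordinates on the
unit square, a gamma-distributed areal weight (mean 26,000 ha — the
sampled-population area per probability site), Poisson richness (mean
28), and a latent disturbance score in [0, 1] shared by the eight raw
sub-indices (each on its own scale, so standardization has real work).

Species are selected by propensity weights that combine a lognormal
commonness factor, a hydrologic-affinity kernel pulling the site toward
its stratum's target wetland index (estuarine herbaceous wettest, inland
woody driest), and — for nonnatives — a prevalence multiplier
(ecoregion × wetland type, western/herbaceous strata higher) times
exp(disturbance_effect · (d − 0.5)). Covers are lognormal (truncated to
(0, 100]); plot occupancy is per-species Bernoulli with a uniform
site-level occupancy probability, forcing at least one plot. Revisit
sites (default 10%) get visit-2 data with multiplicative lognormal cover
noise (SD `revisit_noise_sd` exactly, on the log scale) plus a small
detection-turnover probability (default 0.05) of missing any observation
or picking a species up in an extra plot, so frequency- and
richness-based metrics also show revisit noise. With few revisit pairs a
metric can still show zero observed noise (infinite S:N) — small
turnover on few, multi-plot nonnatives — which the S:N code flags rather
than hides.

What passing tests on this generator do **not** show: realism of species
identities or co-occurrence, spatial autocorrelation of communities
(coordinates are uniform and independent of composition, except through
strata), any particular national marginal distribution, or behavior under
the access-denial nonresponse that real surveys face.

## Problem sizes and numerical choices

Test and demo runs use 20–400 synthetic sites, 1000-replicate coverage
simulations, and 1000-tree forests on 500-site simulations — sizes chosen
so the whole suite runs in a couple of minutes on one core while leaving
Monte-Carlo error well inside the asserted bands. Floating-point
comparisons in tests use absolute tolerance 1e-9 for exact accounting
identities (area conservation, metric oracles) and stated relative bands
for stochastic recoveries. Seeds fix all randomness end to end; the
pipeline manifest and outputs are bit-identical across runs at a fixed
seed.

## Known limitations

- No taxonomy standardization or native-status adjudication: trait tables
  are taken as given.
- The local variance estimator is a simplified member of the
  local-neighborhood family (fixed k-nearest, equal kernel), not the full
  published weighting scheme.
- Extent/mean estimation assumes weights are final (no nonresponse or
  post-stratification adjustment).
- The forest is exploratory: no hyperparameter search, no spatial
  cross-validation, and importance is descriptive, not causal.
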