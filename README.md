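# nnpi

Analysis toolkit for characterizing **nonnative (invasive) plants in
wetlands** from probability-design vegetation surveys, built around the
categorical **nonnative plant indicator (NNPI)** used in national wetland
condition assessments.

Wetland monitoring programs record percent absolute cover of every vascular
plant taxon in five 100-m² vegetation plots per site, together with taxon
traits (native status, growth habit, wetland indicator status), site survey
weights from a spatially balanced area-resource design, and on-the-ground
disturbance checklists. This package turns those tables into site-scale
indicator values and population-scale (area-weighted) estimates, for
wetland ecologists and monitoring programs that need a tested, scriptable
version of that workflow.

## What it computes

**Three NNPI component metrics** per site (all from the five plots):

- nonnative relative cover = (Σ absolute cover of nonnative species / Σ
  absolute cover of all species) × 100
- nonnative richness = number of unique nonnative species
- nonnative relative frequency = (Σ plot frequency of nonnative species /
  Σ plot frequency of all species) × 100, where a species' frequency is
  the percent of plots in which it occurs

Nonnative = alien (introduced + adventive) + cryptogenic taxa; taxa of
undetermined status count in denominators only.

**Stressor-level classification.** Each metric is bracketed against
exceedance cutpoints (defaults: cover 1/15/40, richness 5/10/15, frequency
10/30/60; boundaries belong to the lower category) into low / moderate /
high / very high, and the site's overall NNPI is the *highest* level
reached by any metric (max-filter rule). A two-class rollup (LM = low or
moderate, HVH = high or very high) supports site-scale modeling.

**Design-based population estimation.** Horvitz–Thompson area extent per
NNPI category (hectares of wetland in each stressor level) and
population-weighted metric means, nationally or by ecoregion / wetland
type, with two-sided 95% CIs from either a local-neighborhood variance
estimator (suited to spatially balanced designs) or the with-replacement
approximation.

**Repeatability.** Signal:noise (S:N) per metric: among-site variance over
within-season revisit variance; values above 2 are conventionally deemed
useful.

**Composite disturbance index.** Eight site-level disturbance sub-indices,
each min-max standardized to 0–10 across sites, summed and scaled by 10/8
to a 0–100 overall index.

**Exploratory random forest.** A class-balanced forest (1000 trees,
mtry = ⌊√p⌋, each tree trained on an equal-size bootstrap of both combined
classes at the minority-class size) predicting LM vs HVH from vegetation,
environment, and disturbance predictors, with out-of-bag percent correct
classification, permutation importance (mean decrease in accuracy), and
partial dependence curves.

A seeded synthetic-data generator emulates the survey's structure (plots,
species pools, trait mixes, unequal weights, revisit pairs,
disturbance-linked invasion) so the full pipeline is testable end to end
without access to survey data.

## Worked example

```bash
nnpi run-all --seed 7 --out demo
```

runs simulate → metrics → classification → extent/means/S:N → disturbance
→ forest on 200 synthetic sites and prints

```json
{
  "seed": 7,
  "n_sites": 200,
  "rf": {"pcc_all": 71.0, "pcc_lm": 76.4, "pcc_hvh": 48.7}
}
```

`demo/extent.csv` then starts

```
domain,category,area_ha,se,ci95_lo,ci95_hi,pct_of_domain,n_sites
national,LOW,1372193.0157,233478.6229,914574.9148,1829811.1166,25.7646,61
national,MODERATE,3022278.7571,335273.7625,2365142.1826,3679415.3316,56.747,100
national,HIGH,879882.9115,193178.8568,501252.3522,1258513.4708,16.5209,37
national,VERY_HIGH,51530.7175,26530.0282,0.0,103529.5728,0.9676,2
```

read as: of the ~5.3 million synthetic hectares represented by the
probability sites, 25.8% falls in the low NNPI category, 56.7% moderate,
and 17.5% high or very high, each with its standard error and 95% CI (CIs
truncate at zero area). `demo/popmean.csv` reports, e.g., a national
population-weighted mean nonnative relative cover of 7.04% (CI 5.76–8.32),
and `demo/sn.csv` the repeatability of each metric from the 20 revisit
pairs (a noise variance of exactly 0 — no revisit disagreement — is
flagged as an infinite ratio). `demo/rf_report.json` holds the forest's
OOB performance shown above plus per-predictor importance; with this
generator the wetland index ranks first, echoing the dominance of
moisture-related predictors in real assessments.

Every stage is also available separately (`nnpi simulate`, `metrics`,
`species-table`, `nnpi`, `extent`, `popmean`, `sn`, `disturbance`, `rf`) —
see `nnpi --help` — or as library functions (`nnpi.site_metrics`,
`nnpi.classify_table`, `nnpi.category_extent`, ...).

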