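# andrias

Spatial conservation prioritization for data-limited species, built around
the Chinese giant salamander (*Andrias davidianus*) — a critically
endangered amphibian for which only a handful of single-site habitat
records, coarse historical gazetteer records and community interview
surveys exist. The package turns that limited-data analysis into a tested,
reusable pipeline that runs end-to-end on synthetic landscapes and surveys
with known ground truth, so every stage can be validated before it ever
touches real data.

It is aimed at conservation ecologists and biostatisticians who need to
(1) map potentially suitable habitat from presence-only records,
(2) validate the map against independent occurrence data, and
(3) analyse interview-survey ground-truthing with proper hierarchical
statistics.

## What it computes

**Threshold-envelope habitat model.** A cell is suitable iff every
environmental variable lies in the range attained at known occurrence
sites:

    S(x) = 1  iff  190 ≤ elev(x) ≤ 1330 m
              and 12.7 ≤ T̄(x) ≤ 16.8 °C
              and P(x) ≥ 732.6 mm yr⁻¹
              and landcover(x) ∈ forest classes

with mean annual temperature from 12 monthly layers and annual
precipitation as the sum of 12 monthly totals (all bounds inclusive).
Zonal statistics then give each county's percent suitable habitat over its
assessed (non-nodata) cells.

**Randomization inference.** Whether counties with historical occurrence
records hold more suitable habitat than chance: the observed F from the
linear model `percent ~ presence` (equal to the two-group ANOVA F) is
compared to a null distribution built by permuting the presence labels
(10,000 iterations by default, exact enumeration when feasible);
p is the fraction of null F at or above the observed F.

**Interview-survey battery.** Sighting reports in four raw date formats are
normalised to years-before-interview; counties are summarised (proportion
reporting, most recent and mean sighting lag); the design-level 2×2 table
gets a Yates-corrected chi-squared test; and county summaries are fitted
with hierarchical models estimated by direct marginal maximum likelihood
with adaptive Gauss–Hermite quadrature:

- binomial GLMM, `logit P(report) = β₀ + β₁·arm + u_province (+ e_county)`,
  with an observation-level random effect (OLRE) added when the Pearson
  dispersion ratio exceeds 2;
- Poisson / negative-binomial (NB2, Var = μ + μ²/θ) GLMMs for the
  most-recent-sighting lag;
- a Tweedie compound Poisson–gamma GLMM (1 < p < 2, exact series density,
  power profiled) for the zero-inflated mean sighting lag;
- likelihood-ratio tests between nested fits.

**Power analysis.** The probability of detecting a true difference in
reporting probability between the two county-selection arms, by simulating
the full survey (95 counties in 15 provinces with the recorded per-province
county counts, ~30 respondents per county, baseline 0.45, province and
county logit SDs 0.5) and fitting the GLMM battery per replicate.

## Worked example

```python
import andrias as ad

cfg = ad.LandscapeConfig(seed=7)     # 120x120 cells, 95 counties, 15 provinces
land = ad.generate_landscape(cfg)

temp = ad.aggregate_climate(land.monthly_temperature, mode="mean")
prec = ad.annual_precipitation(land.monthly_precipitation)   # annual total
forest = ad.regroup_landcover(land.landcover, cfg.forest_class_ids)
suit = ad.apply_envelope(
    {"elevation": land.elevation, "temperature": temp,
     "precipitation": prec, "forest": forest},
    ad.giant_salamander_envelope(),
)
print(f"suitable cells: {100 * suit.values.mean():.1f}%")

counties = ad.percent_suitable_by_zone(suit, land.county_labels,
                                       land.county_province_map)
counties, truth = ad.generate_historical_records(counties, -2.2, 0.05, seed=1)
res = ad.permutation_f_test(counties["percent_suitable"].to_numpy(),
                            counties["presence"].to_numpy(),
                            n_iterations=10_000, seed=2)
print(f"presence counties: {int(counties['presence'].sum())} of {len(counties)}")
print(f"observed F = {res.f_observed:.2f}, permutation p = {res.p_value:.4f}")
```

prints

```
suitable cells: 12.0%
presence counties: 18 of 95
observed F = 30.42, permutation p = 0.0000
```

On this landscape 12% of cells satisfy all four envelope conditions; the 18
counties carrying simulated historical records hold significantly more
predicted habitat than the rest (no permuted labelling out of 10,000
reached the observed F, so p < 10⁻⁴) — the generator planted exactly this
association (logit-linear in percent suitable, slope 0.05 per point) and
the randomization test recovers it.

The same analysis runs as one command, writing rasters (ESRI ASCII grid),
county tables (CSV), a results JSON and a human-readable report:

```bash
andrias --seed 2 --outdir out all
```

```
Interviews: 2850 respondents in 95 counties; 47.8% reported a sighting, 41.6% dated it
Binomial GLMM: overdispersion ratio 1.84; OLRE LRT chi2 = 29.56 (p = 5.42e-08); method effect p = 0.694
Power (50 replicates, alpha 0.05): 0.00: 0.08, 0.10: 0.84
```

Here the survey generator injected no arm difference, and none is found
(method-effect p = 0.69), while the county-level extra-binomial noise it
did inject is flagged and absorbed by the OLRE refit.

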