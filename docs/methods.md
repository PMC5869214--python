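# Methods

This note documents the models, conventions and numerical choices behind
`andrias`, in the order the pipeline runs them.

## Raster substrate

All spatial computation happens on `RasterGrid`: a single-band regular
grid, cell-centre registered, row 0 = north, half-open pixel footprints,
with a nodata sentinel and an opaque CRS tag. Persistence uses the ESRI
ASCII grid format — a plain-text single-band raster that round-trips
shape, georeference and nodata, keeps every artifact human-inspectable,
and needs no binary I/O stack. Alignment resamples onto a target grid
(nearest-neighbour for categorical layers, bilinear for continuous ones,
nodata poisoning any interpolation it touches); grids with different CRS
tags are refused rather than silently reprojected.

## Envelope model

The habitat model is a presence-only threshold envelope: suitable iff
elevation ∈ [190, 1330] m, mean annual temperature ∈ [12.7, 16.8] °C,
annual precipitation ≥ 732.6 mm and land cover in the forest group (tree
cover, shrub cover, tree/natural-vegetation mosaic collapsed to one
class). Choices worth stating:

- **All comparisons inclusive.** The published ranges are values attained
  at occupied sites, so the endpoints are themselves suitable.
- **Annual precipitation is the SUM of the 12 monthly totals** (default
  `precip_mode="sum"`). The 732.6 mm threshold is an annual total, so
  averaging monthly values onto a monthly scale would make the threshold
  unreachable; `mean_x12` and `mean` modes are kept for explicitness and
  for users whose thresholds live on other scales.
- **Nodata propagates.** A cell missing any input is nodata in the
  output, never 0: absence of evidence is not unsuitability.
- Output is exactly {0, 1, nodata}; intersection makes the model
  monotone (tightening any interval can only remove suitable cells) and
  order-independent in the condition list. Both are property-tested.

## Zonal statistics

County percentages use cell-centre containment (a cell belongs to the
polygon containing its centre; ties on shared boundaries go to the
first-listed polygon, and interior overlaps are an error). Percent
suitable is computed over assessed cells only — suitability-nodata cells
leave both numerator and denominator — so a county's figure reflects the
area the model actually evaluated; fully unassessed counties carry a
missing flag. The implementation is exercised against a brute-force
per-cell oracle on random grids.

## Randomization test

The link between historical presence and percent suitable habitat is
tested by permutation. The statistic is the overall F of the linear model
`percent ~ presence` on the raw proportions (equal to the two-group
one-way ANOVA F); proportions are not logit-transformed because they
contain many zeroes. The null is built by permuting the presence labels
*without replacement*, preserving the number of presence counties (the
design margin); a `bootstrap_labels` option resamples with replacement as
a sensitivity analysis. When the number of distinct arrangements is at
most the iteration budget the null is enumerated exhaustively.

p is the fraction of null statistics **at or above** the observed F
(`greater_equal`, no +1 smoothing); the strictly-greater rule is available
and differs only through ties. The F statistic is inherently one-sided —
large values indicate association in either direction — so the test is
implemented one-sided on F; a response with zero variance returns F = 0
with a degenerate flag. Type-I calibration at α = 0.05 is verified over
1,000 exchangeable-null datasets.

## Interview processing

Raw last-sighting reports arrive as a calendar year, "N years ago", a
decade, or the respondent's age at the sighting, and are normalised to
whole years before the interview. Decades map to their midpoint (e.g.
"1980s" → 1985), unbiased if sightings are uniform within the decade; a
decade-start rule is available. Reports dated after the interview are
excluded with a count (batch mode) or raised (single-record mode);
unparseable reports become missing with a logged warning. Timing is
resolved to whole years.

County summaries carry the proportion reporting, and the minimum and mean
lag among dated reports. Counties with no dated report get a missing
most-recent lag (excluded from the count models), while the mean-lag
response is zero-filled by default — the Tweedie model is chosen
precisely because its compound Poisson–gamma form puts positive mass at
zero; `zero_mean_for_undated=False` keeps such counties out instead.

The design-level comparison (counties with ≥1 report vs none, by
selection arm) uses Pearson's chi-squared with Yates continuity
correction by default; the uncorrected statistic is cross-checked against
the textbook closed form.

## Hierarchical models

All four families are fitted by direct maximization of the marginal
likelihood. Each province intercept u_p ~ N(0, σ_p²) is integrated out by
**adaptive Gauss–Hermite quadrature** (default 15 nodes): the integrand's
mode and curvature are found by damped Newton steps (the county
log-densities are log-concave in the linear predictor for every family,
so the mode is unique) and the Hermite rule is centred and scaled there.
With the binomial OLRE a second, nested adaptive quadrature integrates
each county's effect, exploiting conditional independence of counties
given their province. Adaptive quadrature was chosen over a plain Laplace
approximation because provinces here can hold very few counties — exactly
where Laplace is least accurate; estimates are checked to be stable
(Δ < 10⁻³) between 15 and 25 nodes.

Details:

- Variance components are optimized on the log-SD scale (L-BFGS-B, three
  deterministic starts by default — the data-driven start plus pushes of
  the variance component toward and away from zero — to dodge boundary
  local optima). SD estimates below 10⁻⁴ are reported as 0. A
  `fixed_sigma_province` option pins the province SD, which gives the
  fixed-effects GLM limit through the same engine; the zero-variance
  limits of all families are tested against statsmodels GLM fits.
- The negative binomial uses the NB2 parameterization
  (Var = μ + μ²/θ). Its log-likelihood is written with the η-independent
  part cached and the η-dependent part on the log1p scale, so the Poisson
  limit (θ → ∞) stays numerically smooth for finite-difference gradients.
- The Tweedie density (1 < p < 2) is evaluated exactly by series: the
  μ-free factor a(y, φ, p) is summed with adaptive truncation (terms
  extended until the boundary term falls 10 orders below the peak) and
  cached per (φ, p); at y = 0 the point mass exp(−μ^{2−p}/(φ(2−p))) is
  closed-form. Normalization to 1 over a (μ, φ, p) grid and agreement
  with compound Poisson–gamma simulation are both tested. The power p is
  profiled on a grid in (1.05, 1.95) and refined by bounded scalar
  search.
- Overdispersion is the sum of squared Pearson residuals, conditional on
  the posterior modes of the estimated random effects, divided by
  n − n_fixed − n_variance_components. ≈1 means the variance function
  holds; the analysis protocol refits with an OLRE when the ratio
  exceeds 2.
- Likelihood-ratio tests use the naive chi-squared reference, matching
  common practice; because that reference is anti-conservative when the
  tested parameter is a variance component on its boundary, the 50:50
  mixture p-value is reported alongside (`p_boundary`). A nested fit
  whose log-likelihood exceeds its superset's by numerical noise is
  clamped to χ² = 0 with a warning.

## Synthetic data

The generator produces every input the analysis needs, with ground truth
retained:

- **Landscapes.** Continuous fields are moving-average-smoothed white
  noise (window = `autocorrelation_length` cells), the simplest mechanism
  that yields contiguous suitable/unsuitable patches. Elevation is
  rescaled exactly onto its configured range; monthly temperature adds a
  seasonal cosine peaking in July and a 6.5 °C/km elevation lapse;
  monthly precipitation gets a wet-season weighting and is floored at 0;
  land cover slices a smooth field at weight quantiles, giving contiguous
  class patches. Counties are Voronoi regions of random seed cells
  (contiguity guaranteed by nearest-seed assignment), grouped into
  provinces by seed proximity. Defaults (120×120 cells, 95 counties, 15
  provinces, temperature mean 12 °C with SD 2, elevation 0–2500 m,
  ~90 mm/month precipitation) were chosen so roughly a tenth of the
  landscape is suitable, county percentages span 0 to ~65% with many
  zeroes, and a handful of counties exceed 50% — the qualitative shape of
  the real county distribution.
- **Historical records.** County presence ~
  Bernoulli(logit⁻¹(a + b·percent)); the pipeline default (a = −2.2,
  b = 0.05 per percentage point) makes presence strongly habitat-linked
  while keeping presence counties a minority.
- **Surveys.** Reporting follows
  logit P = β₀ + β₁·arm + u_province + e_county with u ~ N(0, σ_p²) and
  e ~ N(0, σ_o²); the arm effect is specified on the probability scale
  and converted to the logit scale at the baseline. Defaults: 30
  respondents per county, baseline 0.45, σ_p = σ_o = 0.5. Reporters draw
  a true sighting lag (geometric, mean 20 years, capped at age − 5) and
  render it in one of four raw date formats; respondents assigned the
  decade format have the lag snapped to the decade midpoint so every raw
  report normalises back to the stored truth exactly. About one reporter
  in eight declines to date the sighting, mirroring the gap between
  reported and dated counts in real campaigns.

What the generator does **not** emulate: real geography (rivers,
reachability, spatial correlation between neighbouring counties'
surveys), interviewer effects beyond a province intercept, recall decay
or memory heaping on round years, and detection/identification error.
Passing tests therefore demonstrate that the statistical machinery
recovers known structure under the stated model, not that the model
captures every feature of real survey data.

## Power analysis

`estimate_power` simulates complete surveys on a given county/province
layout, fits the binomial GLMM battery per replicate and tests the arm
effect by LRT. The bundled layout is the recorded survey design: 95
counties across 15 provinces with the documented per-province county
counts and a 48/47 arm split; only the within-province arm assignment is
randomised, since it is not documented. Rejection uses the LRT (not
Wald), with the OLRE added when the province-only fit's dispersion ratio
exceeds 2 (`olre="auto"`).

One property of that pretest deserves note: when the true county-level
noise sits near the trigger (as it does at σ_o = 0.5 with 30 respondents,
dispersion ≈ 2–3), a third of replicates stay on the plain model, whose
LRT is anti-conservative under the residual overdispersion — the null
rejection rate lands near 0.10 rather than 0.05. With `olre="always"`
(generating and fitted models agree) the null rate is calibrated
(measured 0.02 at 150 replicates, inside the binomial interval around
0.05). The calibration test therefore forces the OLRE, while the power
figures follow the protocol's adaptive rule. At the defaults, the power
to detect a 10-point difference is ~85% across 200-replicate runs.
Replicate counts (200 for headline figures, 50–100 for secondary curves)
balance Monte-Carlo error (~2.5 points at power 0.85) against runtime;
per-replicate fits use a single optimizer start from a data-driven
initial point, which in spot checks always reached the multi-start
optimum on these well-behaved simulated likelihoods.

## Known limitations

- The envelope model ignores interactions and gradients — by design, it
  is the method under study, not a recommended SDM.
- Zonal membership is cell-centre based; counties much smaller than a
  cell would be missed (not an issue at the tested resolutions).
- The Tweedie power profile is unimodal in all simulated cases but is
  not guaranteed so; the grid-then-refine search would track a secondary
  mode only if it beat every grid point.
- `rasterize_zones` requires valid, non-overlapping polygons and refuses
  anything else; there is no repair step.
- No reprojection: all layers must share a CRS tag.
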