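# Methods

This note documents the models, conventions and design choices behind
`coastclim`, in the order the pipeline runs them.

## Sensitivity index

The community sensitivity index multiplies three factors computed from
ranked household occupation lists: engagement `X/(X+NX)`, linkage
`N/(X+NX)` and ranking directionality `((r_x/2)+1)/(r_x+r_nx+1)`. Choices
the index definition leaves open, and how this package resolves them:

- **"Relying on" a sector** means listing at least one occupation mapped to
  it; there is no minimum-rank requirement. A household may count in both
  `X` and `NX`, which is why `X + NX ≥ N` (and each factor stays in [0, 1])
  whenever every household lists at least one occupation.
- **Ranking counts are household-level.** `r_x`/`r_nx` are computed only
  over households engaged on both sides; the best (lowest) rank on each
  side is compared and the winner gets one increment per household. Ranks
  are distinct within a household, so ties cannot occur. A pair-level
  alternative (every focal × counterpart occupation pair counted) is
  available via `rank_rule="pairs"`; it inflates `r_x + r_nx` for
  occupation-rich households, which is why the household rule is the
  default.
- **The joint index's counterpart is the off-sector.** For S_AF both
  engagement ("any non-joint occupation") and directionality use salaried /
  informal / tourism / other, which for the joint focal are the same set.
- Households with zero listed occupations are dropped with a logged
  warning rather than failing the whole community.

## Material style of life

The wealth score is the first principal axis of the centred (not
standardised) 16-item binary matrix — the covariance form standard for
asset indices, computed with scikit-learn's PCA. The axis sign is fixed so
that owning more items gives a higher score; the sign of a principal axis
is otherwise arbitrary and silently flips between solvers. Community means
are min–max rescaled to [0, 1] across the community set; rescaling is
affine and therefore order-preserving. Temporal trajectories fit one PCA on
households pooled across survey waves and project wave centroids into that
common two-axis space, so displacement between waves is comparable.

## Exposure extraction

- **Cell selection.** Fisheries: the 20 ocean-masked cells nearest the site
  by haversine distance (Earth radius 6371 km); distance ties at the cut
  break lexicographically by (lat, lon) so selection is deterministic.
  Agriculture: land cells inside an 11×11 block centred on the site's cell,
  where the site's cell is the one with the nearest centre (robust when a
  site sits on a cell boundary). A cell-count sensitivity helper reruns the
  ocean extraction at counts 1–100.
- **Relative change** per run is `100·(future mean − historical mean) /
  historical mean`, means taken over selected cells and inclusive window
  years (historical 1983–2013, future 2046–2056); monthly inputs are
  annualised by unweighted month means first. Change is computed per run
  first and aggregated across runs second; the per-cell-first alternative
  gives the same ensemble mean for equal-weight cells but different
  quartiles, and the per-run-first order matches how ensemble spread is
  usually reported.
- **Missing runs.** A run with a non-positive historical baseline at a site
  is flagged missing, excluded, and the agreement denominator reduced to
  the runs available at that site.
- **Agreement** is the fraction of available runs whose sign matches the
  ensemble mean's sign; zero-change runs agree with either direction (they
  contradict neither); an exactly zero mean is defined as full agreement.
  Percentiles use linear interpolation (numpy's default).
- **Composites.** E_A averages rice, maize and cassava changes unweighted
  by default; optional production-share weights are renormalised over the
  crops a run simulated (cassava exists only in one model family).
  E_AF = (E_A + E_F)/2 exactly.

## Potential impact

Sensitivity and exposure live on different scales (a [0, 1] index vs a
percent change), so both are min–max scaled across the community set before
the Euclidean distance. Exposure is first mapped to *loss* (gains floored
at zero), making the distance monotone in harm on both axes and bounded by
√2. Because the published analysis does not pin down this joint scaling, a
`signed` variant (min–max of the signed change, distance measured from the
most favourable corner) is provided; the loss scaling is the default and is
the one used by the pipeline. Scaling is within scenario, so scores compare
communities under one scenario, not across scenarios. A single community
cannot be scaled without explicit bounds and is rejected.

## Statistics

- **Mixed means.** Reported averages are the fixed intercept of a
  random-intercept-by-country model (statsmodels `MixedLM`, REML). Singular
  fits fall back to the mean of country means with a warning. Denominator
  df use a Satterthwaite-style two-component approximation: the intercept
  variance is split as `tau²/k + sigma²/N` with k−1 and N−k df, combined by
  the Welch–Satterthwaite formula; when between-country variance dominates
  the df approaches k−1 (fractional df near the number of countries, as
  expected for 5 countries). Estimates and SEs agree with R lme4 to ~1e-4
  in the test suite; the df approximation is deliberately simple and can
  run a little above lmerTest's exact Satterthwaite value.
- **Paired sector comparison** models per-community differences (E_F − E_A)
  with the same machinery, keeping the pairing while absorbing country
  scatter.
- **Wealth–impact regression** is a random-intercept model of potential
  impact on scaled MSL. Slope SEs come from a nonparametric bootstrap
  (default 1000 replicates) resampling communities *within* country —
  stratification keeps every country present; degenerate resamples are
  redrawn. p-values use a normal approximation on the bootstrap SE.
  Marginal and conditional R² follow the standard variance-decomposition
  definitions (fixed-effect variance over total, and fixed-plus-random over
  total).
- **Cohen's D** uses df-weighted pooled variance.
- **Coastal sampler**: eligibility is coastal (land with an ocean
  8-neighbour) *and* density strictly greater than 25 people/km²; the
  sample is ⌊0.1 · eligible⌋ cells without replacement from a seeded
  generator.

## Synthetic study system

The generators emulate the statistical structure the analysis assumes, not
the physics of any earth-system model.

- **Surveys.** Households draw a sector-engagement category per community
  from (agriculture-only, fisheries-only, both, neither) probabilities;
  default tuples give roughly 25/28/35/15% with small country differences,
  and community wealth tilts the odds of resource engagement
  (log-odds −0.5 per latent-wealth unit, so poorer communities depend more
  on the two sectors — the coupling the wealth–impact regression is meant
  to detect). Dual-sector households rank fisheries above agriculture with
  probability 0.6. Household counts are uniform on 13–150 per community, 72
  communities in 5 contiguous coastal blocks. The 16 binary items follow a
  logistic item-response model on latent wealth (slopes 0.8–1.55,
  intercepts −1.5…1.5), giving a realistic mix of common and rare assets.
- **Grids.** A deterministic sinusoidal coastline divides land from ocean
  identically at 1° and 0.5°, so both extraction geometries are exercised
  and the masks are mutually consistent. Historical fields are a positive
  deterministic texture (so cells differ); future fields multiply the
  historical by `1 + change/100` with change = scenario mean + regional
  anomaly + run offset + i.i.d. cell noise. The *regional anomaly* is a
  smooth field (coarse 6° white noise, bilinearly interpolated) shared by
  all runs of a sector and — crucially — shared across scenarios as a unit
  pattern scaled by each scenario's SD: scenario severity amplifies a
  common spatial response pattern, as in forcing-scaled projections. This
  is what makes sites genuinely differ in true exposure (i.i.d. cell noise
  alone averages out over 20–121 cells) and what makes the double-burden
  comparison between scenarios meaningful site by site.
- **Defaults** (the study conditions for all seed-replicated checks):
  harsh scenario fisheries −15%, crops (rice +9.6, maize −3, cassava −3 →
  E_A +1.2%); mild scenario fisheries −5%, crops (+3.6, −0.5, −0.5);
  run SD 5%, cell noise SD 10%, regional SD 10% (fisheries) / 8% (crops).
  Fisheries runs: 7 models × 2 forcings + 2 × 1 = 16; crops: 4 models × 5
  forcings = 20, cassava only from the single LPJmL family (5 runs).
- **Stream order.** Generators draw from child streams of the master seed
  spawned in a fixed order (survey, fisheries grids, crop grids,
  population, sites); within the grid streams the unit spatial patterns are
  drawn before any scenario-level noise. Adding a generator or a scenario
  therefore never shifts the draws of the others.
- **What the synthetic world does not have:** spatially autocorrelated
  *cell* noise, interannual variability (historical years are identical, so
  window means are exact), model-family correlation structure beyond the
  shared regional pattern, demographic structure in the population raster,
  seasonality or gender structure in surveys, and any exposure–wealth
  coupling (sites are assigned to communities independently of wealth).
  Passing recovery tests therefore demonstrates correctness of the
  estimators under these idealised conditions, not skill on real ensemble
  output.

## Problem sizes

The seed-replicated studies use the full default world (72 sites, 16/20
runs, 30×30 and 60×60 grids) over 50 seeds; survey-marginal checks use one
5000-household community; oracle equivalence uses 1000 random communities.
These sizes give Monte-Carlo SEs well below the effects being checked
(e.g. exposure-bias SE ≈ 0.2 points against a −15% signal).

## Known limitations

- The Satterthwaite-style df is an approximation; exact Kenward–Roger or
  Satterthwaite df would require the full REML information matrix.
- The bootstrap resamples communities, not households; household-level
  resampling would propagate survey noise into sensitivity scores too.
- Exposure extraction assumes regular lat/lon grids and does no regridding
  or bias correction; inputs at other resolutions must be regridded
  upstream.
- With a single scaling per scenario, potential-impact scores are not
  comparable across scenarios; cross-scenario comparisons should use the
  underlying exposures.
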