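# coastclim

Coastal communities in the tropics often depend on fisheries *and*
agriculture at the same time, so climate change can hit the same households
through both food systems at once. `coastclim` implements a community-scale
potential-impact analysis for exactly this setting: it turns household
livelihood surveys into sector-dependence (sensitivity) indices, extracts
mid-century sector exposure from gridded multi-model projection ensembles,
combines the two into a potential-impact score per community, and runs the
comparative mixed-effects statistics. A first-class synthetic-data module
generates surveys, gridded ensembles, population rasters and site
coordinates with known generating values, so the entire chain is testable
without any external downloads.

It is intended for researchers in climate vulnerability assessment and
socio-ecological systems who want a reproducible, testable implementation of
this exposure–sensitivity analysis, either to run on their own survey and
ensemble data or to study the method's behaviour on simulated worlds.

## The method

**Sensitivity.** Each surveyed household lists its ranked livelihood
occupations (rank 1 = most important). Occupations map to a *fisheries*
sector (fishing, mariculture, gleaning, fish trading), an *agriculture*
sector (farming, cash cropping), or the *off-sector* (salaried, informal,
tourism, other). A community's sensitivity to a focal sector is

```
S = X/(X+NX) · N/(X+NX) · ((r_x/2) + 1)/(r_x + r_nx + 1)
```

where `X` households rely on the focal sector, `NX` on any occupation
outside it, `N` is the community size, and `r_x` / `r_nx` count households
ranking the focal sector above / below its counterpart. The three factors
measure engagement, cross-sector linkage, and ranking directionality; each
lies in [0, 1] when every household has at least one occupation, and S = 0
exactly when nobody engages in the sector. The index is computed for
agriculture (S_A), fisheries (S_F), and both sectors jointly (S_AF, with the
off-sector as counterpart).

**Exposure.** For each site, fisheries exposure E_F is the ensemble percent
change in ocean total consumer biomass between a historical window
(1983–2013) and mid-century (2046–2056) over the twenty nearest ocean grid
cells by haversine distance (16 model runs on a 1° grid). Agriculture
exposure E_A averages rain-fed rice, maize and cassava yield changes over
land cells in an 11×11 window centred on the site (4 crop models × 5
forcings on a 0.5° grid; cassava from a single model family). Change per run
is `100·(future − historical)/historical`; runs aggregate to a mean,
25th/75th percentiles, and a direction-agreement fraction. The composite is
`E_AF = (E_A + E_F)/2`.

**Potential impact.** Sensitivity and exposure loss (gains floored at zero)
are min–max scaled to [0, 1] across communities; the relative potential
impact is the Euclidean distance `√(s² + e²)` from the origin. A community
faces a *double burden* when both sector exposures are negative.

**Statistics.** Every reported average is the fixed intercept of a linear
mixed model with a country random intercept. Sector comparisons keep the
pairing by modelling per-community differences. The wealth–impact
relationship regresses potential impact on the community material style of
life (first principal axis of 16 binary household items, scaled 0–1) with
bootstrap standard errors (communities resampled within country) and
marginal/conditional R². A representativeness check compares study sites
with a random 10% sample of coastal cells above 25 people/km² via Cohen's D.

## Worked example

The numbered scripts under `analysis/` run the full chain on the default
synthetic world (72 communities in 5 countries, seed 1):

```
python analysis/01_simulate.py
python analysis/02_sensitivity.py
python analysis/03_exposure.py
python analysis/04_impact.py
python analysis/05_analyze.py
```

The analyze step prints:

```
Harsh scenario: fisheries loss 13.5% (SE 2.0), agriculture change +3.3% (SE 1.6)
Sector gap (F - A): -16.7 points (t=-5.52, df=4.11, p=0.00487)
Wealth-impact slope: -0.104 (boot SE 0.110), R2 marginal 0.01 / conditional 0.42
```

Read: in this simulated world, mid-century fisheries productivity falls by
13.5% on average (country-random-effect estimate) while agriculture changes
little, so the fisheries-minus-agriculture gap of −16.7 points is
significantly below zero — fisheries-dependent livelihoods face the larger
loss. The wealth–impact slope is negative (poorer communities score higher
potential impact), though this single world does not separate it from zero.

The generating truths behind this world are a −15% fisheries change and a
+1.2% agriculture change under the harsh scenario; `analysis/06_recovery_study.py`
replicates the world 50 times and reports

```
mean_E_F: -14.66 (truth -15.0, MC SE 0.46)
mean_E_A: +0.80 (truth +1.2, MC SE 0.36)
sector gap: -15.4 points, negative in 100% of worlds
double burden: 36% (mild) vs 45% (harsh) of sites, expectation over worlds
```

i.e. the extraction is unbiased, the sector gap keeps its sign in every
replicate, and the milder emissions scenario consistently produces fewer
double-burden communities.

The same stages are available as a CLI (`coastclim simulate|sensitivity|
exposure|impact|analyze|all`) for running on external survey tables and
NetCDF ensembles with the same schemas.

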