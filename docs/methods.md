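# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limitations of `mobexpo`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## The estimation problem

A sparse trace is a sequence of records `(user, day, t, x, y, event_type)`
generated only at communication or network events; the time between records is
bursty and heavy-tailed, so most wall-clock hours of most users carry no
observation, while pollutant surfaces vary hour by hour. Cumulative exposure
`Σ_t AP_{i(t),t}` therefore depends on filling the unobserved hours well. The
package's premise is that filling them with a model trained on *many users
with similar movement patterns* beats per-user interpolation.

## Stage 1 — trajectory reconstruction

**Preprocessing.** Cell-tower oscillation (the trace ping-ponging A→B→A while
the phone is stationary) is suppressed by deleting the middle records of every
maximal A→B→A pattern whose transitions both occur within `window_s`
(default 300 s) and whose displacement is at most `max_jump_m` (default
2000 m), applied to a fixpoint so the operation is idempotent. The cited
literature does not fix the algorithm's constants; both are config keys.

**Anchor detection.** Per user, distinct locations are ranked by record count
(ties: earliest first visit, then lexicographic coordinates — the ranking must
be total for reproducibility); the top unconsumed location absorbs all
unconsumed locations within `alpha_m` (default 500 m) into one candidate, and
candidates holding at least `beta` (default 0.2) of the user's records become
anchors. The defaults are the standard choices for urban cell-tower spacing
(several hundred metres) and for the share of records at home/work.

**Clustering.** Anchors project to zones (supplied polygons, or 1-km grid
cells as fallback); users are compared by the Jaccard index of their zone sets
and grouped by average-linkage agglomerative clustering on distance
1 − similarity, cut at a configured cluster count. Users without anchors (too
sparse) are placed in singleton fallback clusters instead of aborting.

**Reconstruction model.** Within each cluster, trajectories are subsampled at
several intervals (default 1 h, 2 h, 3 h); each interior point of a resampled
sequence yields one training example `[x⁻, y⁻, t⁻, t, x⁺, y⁺, t⁺, ROG, Ent] →
(x, y)`. Two gradient-boosted regression-tree ensembles (one per coordinate;
defaults 200 trees, depth 3, learning rate 0.1, full subsample, fixed seed)
are fitted per cluster; clusters with too few examples fall back to a globally
pooled model. At prediction time a missing hour's context is its nearest
*observed* records before and after — never previously reconstructed points,
to avoid compounding errors. Hours within the snap tolerance (default 900 s)
of a record pass through as observed; hours before the first or after the
last record take the nearest record's location.

**Baselines.** Nearest interpolation (temporally closest record, ties to the
earlier one) and linear interpolation (affine between bracketing records,
clamped at the ends). Held-out evaluation keeps the communication-driven
records (calls/texts: about a third of events under the default event model)
and hides the network-generated ones; everything downstream of the split —
features, clustering, model training — uses kept records only. Errors are
Euclidean distances at the hidden records' times; per-point error lists are
retained so MAE and its standard deviation are recomputable.

## Stage 2 — hourly pollution surfaces

**Ordinary kriging.** Each meteorological variable (horizontal visibility m,
wind speed m/s, air temperature °C) is interpolated per hour to the 1-km cell
centres. The semivariogram is exponential with zero nugget, fitted by weighted
least squares (weights √pair-count) to the empirical semivariogram restricted
to lags ≤ 25% of the maximum pairwise distance — interpolation accuracy is
governed by short-lag behaviour, and long lags are trend-dominated. The
fitted range is capped at 1.5× the network diameter and the kriging system
carries a 1e-6-of-sill diagonal guard; station predictions are therefore
exact to that relative order. A Gaussian variogram option exists; it
reproduces smooth short-wavelength structure more faithfully pointwise but
its near-singular systems propagate structured artifacts into the downstream
regressions, so the exponential model is the default.

**Covariate attachment.** Kriged cell values whose centres lie within 1 km of
a pollution monitor are averaged onto it (monitors with no cell in radius take
the nearest cell, flagged). The alternative reading — averaging raw station
observations — is not implemented as a default because the kriged field is the
quantity used for prediction everywhere else.

**GWR.** One model per hour regresses monitor PM2.5 on the three attached
covariates with an adaptive bisquare kernel: at target s the bandwidth is the
distance to the k-th nearest monitor and weights are `(1 − (d/h)²)²`.
`bandwidth="select"` minimises the corrected AIC
`n ln σ̂² + n ln 2π + n(n + tr S)/(n − 2 − tr S)` by integer golden-section
over k; bandwidths whose local designs are singular are excluded from the
search, while an explicitly requested singular bandwidth raises an error
naming the hour. With bandwidth → ∞ the estimator reduces exactly to OLS
(tested at 1e-6 relative tolerance). Surfaces are predicted by refitting the
local regression at every cell centre and applying the cell's kriged
covariates; negative concentrations are floored at zero and counted.

## Stage 3 — exposure

Hourly positions map to grid cells half-open (`[x₀+c·1000, x₀+(c+1)·1000)`),
with out-of-grid points clamped to the nearest edge cell and flagged.
Cumulative exposure sums the occupied cell's concentration per hour
(µg/m³·h); with a microenvironment table, each hour contributes
`Σ_n AP·ME_n·TP_n` and the TP fractions must sum to 1 (a single
microenvironment with ME = TP = 1 reduces exactly to the outdoor sum). The
three estimators: TR uses the reconstructed hourly trajectory; REC carries the
last observed hour forward (leading hours back-filled — a config-documented
choice; nothing in the record stream says where the user was before the first
record); SL pins every hour at the home location, the modal nighttime
(22:00–06:00) location with ties broken by the latest within-night record then
lexicographically, falling back (flagged) to the overall modal location for
users with no nighttime records.

Health categories partition [0, ∞) left-closed: Excellent [0,35), Good
[35,70), LightlyPolluted [70,115), ModeratelyPolluted [115,150),
SeverelyPolluted [150,∞) µg/m³ — the printed category tables in the ambient
air-quality standard overlap at the boundaries, and the left-closed convention
resolves every boundary deterministically. Distribution comparisons use the
two-sample Kolmogorov–Smirnov statistic (asymptotic p); per-(user, day)
paired differences are summarised by linear-interpolation quartiles grouped by
a config calendar of workdays/weekends. The top ⌈0.2·n⌉ users by cumulative
exposure aggregate by home zone: per zone, category-time percentages, the
share of hours spent away from the home cell, and the share of exposure
accrued in those hours, plus the OLS slope and Pearson r of the
(time-away %, exposure-away %) relation across zones.

## The synthetic world

The generator is the package's ground-truth instrument, not a fixture. Its
defaults define the study conditions:

- **Geometry:** 40×40 km grid of 1-km cells; zones are 10×10 km blocks.
- **Agents:** 200 agents in 4 movement-pattern clusters over 2 simulated
  days. Each cluster owns a home and a work base (drawn apart by at least a
  quarter of the region); agents jitter around the bases (Gaussian, 800 m).
  The daily template: home 20:00–08:00, work 09:00–17:00, linear transit
  between (08:00 at the midpoint; 18:00–19:00 returning). Occupancy is
  piecewise-constant at hourly resolution.
- **Sampling:** a renewal process with inter-event gaps from a
  Pareto(α=1.5, x_m=60 s)/exponential(mean 5400 s) mixture (weight 0.4 on the
  heavy component), truncated to [60 s, 12 h] — about 26 records per agent-day
  with the bursty, heavy-tailed spacing characteristic of event-driven traces.
  Each event is a communication record with probability 0.34, otherwise
  network-generated; records take the true position at the event time.
- **Fields:** PM2.5 per cell-hour is `β₀ + β₁·VIS + β₂·WS + β₃·TEM + N(0,σ)`
  with σ = 5 µg/m³ by default. β₀ = 160 µg/m³ (a polluted-episode background
  chosen so the linear model stays positive region-wide — a physical floor at
  zero would otherwise kink the model); β₁ falls linearly west–east from
  −0.003 to −0.009 µg/m³ per m (a 3× contrast, detectable at the default
  noise); β₂ = −2.5 per m/s; β₃ = 0.6 per °C. Each covariate field combines a
  broad gradient, a diurnal cycle, and a smooth wave at a distinct wavelength
  and orientation (haze patches 12 km, wind channels 15 km, heat-island
  pockets 15 km): the waves are what keep the covariates locally
  non-collinear, hence the local coefficients identifiable.
- **Stations:** the world is cell-resolved, so stations sit at cell centres.
  60 pollution monitors occupy seeded random cells and report their cell's
  noisy truth; weather stations form a regular ≈3-km lattice (169 sites) — a
  planned network dense enough to resolve the covariate waves.

Everything regenerates bit-identically from (seed, parameters). The exact
exposure of every agent (true trajectory × true field) is the universal oracle
for the estimator comparisons.

**What the generator does not emulate:** positioning error (records sit on the
true position, not a tower location), transport networks and mode choice,
inter-individual schedule heterogeneity beyond jitter, day-to-day behavioural
variation, station outages, pollutant chemistry, and temporal correlation of
the field noise. Passing tests therefore demonstrate internal consistency and
method ranking under idealised-but-sparse observation, not performance on any
real city's data.

## Validation experiments and their sizes

- **Coefficient recovery:** one simulated day, 60 monitors, noise ladder
  σ ∈ {20, 10, 5, 0} µg/m³. The 24 hourly GWR fits use a *fixed* adaptive
  bandwidth of 25 neighbours — a ladder experiment varies one factor only —
  and each monitor's fitted β₁ is averaged over the day (β₁ is
  time-invariant, so the day mean is its natural estimator). Note the fitted
  β₁ is systematically amplified relative to truth: the covariate's broad
  gradient is collinear with β₁'s own gradient, a known identifiability
  limitation of locally constant coefficient models on smooth covariates; the
  recovery criterion is therefore correlation with (and error monotonicity
  against) the true field, not unbiasedness.
- **Method rankings:** ten replicate default worlds (seeds 1–10 in the test
  suite). Reconstruction: held-out MAE of the cluster-pooled boosted trees vs
  both interpolation baselines. Exposure: median |estimate − true| per world
  for TR/REC/SL, with the TR-vs-SL gap required to exceed the TR-vs-REC gap.
  Problem sizes (200 agents × 2 days, ≈7000 held-out points per world) keep
  one replicate under ~30 s on a single CPU.
- **Oracle equivalences and exactness properties** run on small constructed
  instances (≤ 60 stations, ≤ 101 users) and brute-force recomputations.

## Numerical choices and degenerate inputs

- Kriging refuses < 3 distinct stations and conflicting duplicate
  coordinates; constant fields short-circuit to the constant.
- GWR needs ≥ p + 2 stations; the AICc search floor is max(p+3, 8) neighbours.
- Oscillation suppression, anchor ranking and home-inference tie-breaks are
  all total orders, so every pipeline output is a pure function of
  (inputs, config, seed).
- Hour snapping uses absolute time, so a 23:59 record can serve the next
  day's 00:00 mark; ties snap to the earlier record.
- Exposure of a trajectory leaving the grid clamps to edge cells and counts
  the clamps rather than failing.

## Limitations

The reconstruction model predicts each missing hour independently from its
observed bracket; it does not enforce path continuity between consecutive
reconstructed hours. The K-S comparison treats users as independent samples.
Microenvironment ratios default to the outdoor-only simplification; supplying
measured ME/TP tables is supported but no defaults are shipped, since credible
values are population-specific. The away-from-home exposure share is a share
of summed concentrations, which equals a time share only under a spatially
uniform field.
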