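# mobexpo

Dynamic individual air-pollution exposure estimation from sparse mobility
traces.

Epidemiological exposure assessment needs to know *where people actually are*
hour by hour, but the cheapest population-scale mobility source — mobile-phone
records — only logs a location when an event happens (a call, a text, a
network handover), leaving most hours unobserved. `mobexpo` closes that gap
end to end:

1. **Trajectory reconstruction.** Users are grouped by the similarity of their
   *anchor points* (locations holding ≥ β of a user's records, merged within a
   distance α; Jaccard index over the zones they project to, then hierarchical
   clustering). Within each movement-pattern group, a gradient-boosted tree
   model learns to place a missing point from its two temporal neighbours,

   `[x_{n−1}, y_{n−1}, t_{n−1}, t_n, x_{n+1}, y_{n+1}, t_{n+1}, ROG, Ent] → (x_n, y_n)`,

   where ROG is the radius of gyration `√((1/n) Σ‖p_j − p̄‖²)` and Ent the
   Shannon entropy `−Σ p(j) log₂ p(j)` of the user's visit frequencies. Every
   trace is densified to one point per wall-clock hour.

2. **Hourly 1-km pollution surfaces.** Meteorological station observations are
   interpolated to a 1-km grid by ordinary kriging, averaged onto each PM2.5
   monitor, and a geographically weighted regression (GWR)

   `PM_{i,t} = β₀(i,t) + β₁(i,t)·VIS + β₂(i,t)·WS + β₃(i,t)·TEM + ε`

   is fitted per hour (adaptive bisquare kernel, bandwidth by corrected-AIC
   golden-section search). The local coefficients, re-evaluated at every cell
   centre, yield an hourly concentration surface.

3. **Exposure integration.** Each user's hourly cell sequence is integrated
   against the surfaces: `Exp′_j = Σ_t AP_{i(t),t}` (µg/m³·h), optionally
   refined by microenvironment ratios ME and time fractions TP
   (`Exp_j = Σ_t Σ_n AP·ME·TP`). Three estimators are compared — TR
   (reconstructed trajectory), REC (raw records carried forward), SL (static
   home location, inferred from nighttime records) — via two-sample
   Kolmogorov–Smirnov tests and paired-difference summaries; hourly
   concentrations map to five health categories and high-exposure residents
   aggregate by home zone.

Because real phone traces are proprietary, the package ships a first-class
synthetic-world generator (`mobexpo.synthetic`): commuting agents with
anchor-structured schedules, event-driven sampling with a heavy-tailed
inter-event distribution, and a PM2.5 field generated from the very
linear-in-meteorology model with known spatially varying coefficients that the
estimation stage tries to recover — so every stage is testable against exact
ground truth.

## Worked example

```python
import numpy as np
from mobexpo.synthetic import generate_world, world_zones
from mobexpo.pipeline import run_pipeline

world = generate_world(seed=7, n_agents=60, n_clusters=3, days=2)
zones = world_zones(world.grid)
res = run_pipeline(world.trajectories, world.pm_obs, world.met_obs,
                   world.grid, seed=7, n_clusters=3, zones=zones)

print("clusters:", sorted(set(res.clustering.labels.values())))
print("mean GWR R^2: %.3f   mean RMSE: %.2f ug/m3"
      % (res.diagnostics.iloc[-1].r2, res.diagnostics.iloc[-1].rmse))
for pair, (stat, p) in res.ks.items():
    print("K-S %s: statistic=%.3f p=%.3g" % (pair, stat, p))
errs = {m: [] for m in ("tr", "rec", "sl")}
for agent in world.agents:
    truth = world.true_exposure(agent.user_id)
    for m in errs:
        errs[m].append(abs(res.exposures[agent.user_id][m].cumulative - truth))
for m, v in errs.items():
    print("median |%s - truth|: %.1f ug/m3 h" % (m.upper(), float(np.median(v))))
```

prints

```
clusters: [0, 1, 2]
mean GWR R^2: 0.950   mean RMSE: 4.83 ug/m3
K-S tr_vs_rec: statistic=0.233 p=0.0641
K-S tr_vs_sl: statistic=0.617 p=1.63e-11
median |TR - truth|: 65.9 ug/m3 h
median |REC - truth|: 85.2 ug/m3 h
median |SL - truth|: 273.3 ug/m3 h
```

Read: the three schedule groups are recovered exactly; the hourly surface fits
explain 95% of station variance; exposure from the reconstructed trajectories
(TR) tracks each agent's true cumulative exposure markedly better than raw
records (REC) and far better than assuming everyone stays home (SL) — the SL
distribution differs from TR strongly (K-S 0.617), the REC distribution only
mildly. That ordering is the package's central claim.

## Command line

```bash
mobexpo synth --seed 1 --out world/          # write synthetic input CSVs + zones
mobexpo all  --seed 1 --out run/ \
    --traces world/traces.csv --pollution world/pollution.csv \
    --meteorology world/meteorology.csv --zones world/zones.geojson
```

Subcommands `reconstruct`, `field`, `expose`, `compare`, `zones` run the
individual stages; every run writes a resolved config and a JSON manifest
(input hashes, seed, timings). Exit codes: 0 success, 1 stage failure, 2
configuration error.

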