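# hauloutnet

Harbour seals (*Phoca vitulina*) in regions such as the Skagerrak–Kattegat
are managed through area-based frameworks — Norwegian county quotas, national
protection in Sweden and Denmark — whose boundaries are administrative rather
than ecological. GPS phone tags with wet/dry sensors record when and where
seals haul out on land, and those haul-out sequences reveal whether animals
actually stay inside the unit in which they are counted and regulated.
`hauloutnet` turns raw wet/dry telemetry into that evidence: per-seal haul-out
events, management-unit assignment, time-to-boundary-crossing survival models,
and a spatial network of haul-out site connectivity.

The package is aimed at movement ecologists and managers working with
pinniped biologging data, and at anyone needing a tested implementation of
the recurrent-event survival and network metrics involved.

## What it computes

**Haul-out events.** A haul-out is a period in which the wet/dry sensor stays
dry for ≥ 10 min and ends when a wet run of ≥ 40 s begins (shorter wet blips
are absorbed). Consecutive events separated by < 10 min are merged; seals
with < 10 days of data are dropped.

**Cross-boundary survival.** Events are assigned to management units by
polygon containment, and each maximal same-unit run of haul-outs becomes a
risk interval on a gap-time clock: it opens at the first haul-out in the
unit, ends with an event at the start of the next cross-boundary haul-out
(which resets the clock), and the final spell is censored at the end of
tracking. On these intervals the package fits

* Kaplan–Meier curves per departure jurisdiction, S(t) = Π(1 − dᵢ/nᵢ),
  with Greenwood variance and median time-to-crossing, and
* Cox proportional-hazards models h(t) = h₀(t)·exp(β₁·X₁ + β₂·X₂ + b),
  where X₁ is the departure jurisdiction, X₂ body weight, and b an optional
  per-seal Gaussian random intercept (log-normal frailty, b ~ N(0, σ²_b)).
  The partial likelihood (Efron ties) is maximized by Newton–Raphson; the
  frailty variance maximizes a Laplace-approximate marginal likelihood.
  Hazard ratios exp(β) are reported relative to a reference jurisdiction
  (default: the one with the highest empirical crossing rate).

**Spatial network.** Haul-out locations pooled over seals are grouped into
nodes by transitive chain-rule clustering at 10 km; consecutive haul-outs at
different nodes add trips to undirected edges carrying density (trips),
occupancy (distinct seals), weight (trips per seal = density/occupancy),
great-circle distance, and distance-corrected weight (weight/distance).
Node metrics are degree and Brandes betweenness centrality on the
distance-corrected weights, normalized to [0, 1]; both the edge-cost and the
normalization convention are explicit, logged parameters.

**Synthetic cohorts.** A semi-Markov generator produces multi-seal haul-out
sequences (and optional wet/dry sensor streams) with known per-unit crossing
hazards, per-seal frailty and site geometry, so every pipeline stage can be
tested against ground truth.

## Worked example

```python
import hauloutnet as hn

# simulate a 26-seal cohort and run the survival analysis
cfg = hn.SimulationConfig(n_seals=26, seed=1)
events, seals, truth = hn.simulate_cohort(cfg)
unit_map = hn.ManagementUnitMap.from_geojson(hn.unit_polygons(cfg.sites))
labelled = hn.flag_cross_boundary(hn.assign_units(events, unit_map))
tracks = hn.tracks_from_frames(labelled, seals)
intervals = hn.cohort_risk_intervals(tracks)
fit = hn.cox_frailty(intervals, reference="Sweden")
print(fit.summary().round(2))

# rebuild the published 13-node network from its printed edge table
nw = hn.network_from_edge_table(hn.load_printed_edges())
cost, norm, scores, err = hn.select_convention(nw, {"H": 0.62, "B": 0.64})
```

Output:

```
                  coef  exp_coef    se     z     p  significant
unit[Aust-Agder] -0.15      0.86  0.49 -0.32  0.75        False
unit[Buskerud]   -0.45      0.64  0.53 -0.85  0.40        False
unit[Ostfold]    -0.53      0.59  0.47 -1.12  0.26        False
unit[Telemark]   -3.71      0.02  0.93 -3.99  0.00         True
unit[Vest-Agder]  0.28      1.33  0.47  0.60  0.55        False
unit[Vestfold]   -1.61      0.20  0.57 -2.84  0.00         True
weight_kg         0.03      1.03  0.02  1.56  0.12        False
```

Coefficients are log hazard ratios of leaving each jurisdiction relative to
Sweden: seals in this simulated cohort were significantly less likely to
cross out of Telemark (HR 0.02) and Vestfold (HR 0.20) than out of Sweden,
while body weight had no significant effect — the kind of jurisdiction
contrast the real study design is meant to detect. The network call
reconstructs 13 nodes and 17 edges, finds degree 6 for hub node H, and the
convention selection reports `cost=inverse_dc_weight, normalization=pairs`
with H = 0.62 and B = 0.64.

A CLI mirrors the stages: `hauloutnet simulate`, `events`, `assign`,
`survival`, `network`, `all` (see `hauloutnet --help`).

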