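# Methods

This note documents the models, rules and numerical choices behind
`hauloutnet`, in the spirit of a statistical-software methods appendix.

## Event construction

A haul-out event is a maximal sensor-dry period of at least `min_dry`
(default 10 min) that ends at the first instant a wet run of at least
`end_wet` (default 40 s) begins. Because the terminating rule is "wet for
≥ 40 s", wet interruptions shorter than 40 s are absorbed into the dry
period — both the absorbed wet time and the flanking dry runs count toward
the event's duration, and the qualifying ≥ 10 min test is applied to the
absorbed (merged) dry period as a whole. A record's state is assumed to hold
until the next record; a trailing dry run at the end of a stream is closed
by the last timestamp. Duplicate timestamps within a seal keep the first
record (tags can emit retries); the drops are logged.

Consecutive events of one seal whose inter-event gap is `< gap` (default
10 min, strict) are merged, keeping the first start, the last end, and the
location of the longest constituent — the dominant dry period best
represents the site; the rule is idempotent, order-independent on sorted
input, and never decreases total dry time. "Ten days of movement data" for
track filtering is elapsed time between the first and last record of any
kind, boundary inclusive. All times are UTC; intervals are half-open
[start, end) for gap arithmetic. Cohort summary tables report across-seal
means with a normal-approximation 95% CI (mean ± 1.96·SE).

## Jurisdiction assignment and risk intervals

Events are assigned to management units by polygon containment (`covers`,
so boundary points count), resolved to the first feature in file order when
polygons share an edge; events outside every polygon are labelled
`unassigned` and excluded from the cross-boundary analysis with a logged
warning. A haul-out is cross-boundary when its unit differs from the
immediately preceding haul-out's unit; the first event of a seal is
undefined.

Survival data use a gap-time (renewal) formulation: the clock restarts at
zero at every crossing. Spell 1 opens at the seal's first haul-out start
(in whatever unit that event fell — not necessarily the tagging unit); a
spell ends with `event = 1` at the start time of the next cross-boundary
haul-out, which is taken as the moment the crossing is observed (events,
not at-sea positions, define the analysis); the last spell is censored at
the end of the tracking period. The jurisdiction covariate is the spell's
departure unit, constant within a spell by construction; body weight is
mass at tagging, constant per seal. Sex is not used as a covariate (it is
collinear with weight in cohorts like the motivating one).

## Survival models

Kaplan–Meier curves are product-limit estimates per departure jurisdiction
with Greenwood variance; the median is the smallest t with S(t) ≤ 0.5 and
is undefined when S never reaches 0.5.

The Cox models maximize the Efron-tie partial likelihood by Newton–Raphson
with step-halving on likelihood decrease, convergence |Δℓ| < 1e−8, at most
50 iterations. Ties are possible after day-resolution rounding of
user-supplied data, hence Efron rather than Breslow; internally time is
continuous days with no rounding. The observed information at the optimum
supplies Wald standard errors, z and p values (two-sided, α = 0.05).
Covariates with zero variance raise a degeneracy error. Coefficients
exceeding 15 in absolute value abort with a convergence error carrying the
iteration trace — a log hazard ratio that large on this data scale is a
monotone-likelihood signature, not an estimate. Jurisdictions in which no
crossing was ever observed are excluded from the Cox fit (with a warning):
their log hazard ratio diverges to −∞, and removing their intervals is the
exact profile limit of the full fit since their risk-set contribution
carries the vanishing factor exp(β).

The frailty model adds a Gaussian random intercept per seal on the
log hazard. For fixed σ²_b the penalized partial likelihood
ℓ_p(β, b) − bᵀb/(2σ²_b) is maximized jointly over (β, b); σ²_b itself
maximizes the Laplace approximation to the integrated likelihood,
ℓ_m(σ²) = ℓ_pen(β̂, b̂) − (q/2)·log σ² − ½·log det K, where K is the
b-block of the penalized observed information, searched by bounded Brent
on log σ² over [10⁻⁶, 10²] (a maximum-likelihood, not REML-like,
flavour). When the profile optimum collapses toward the lower bound the
model returns the fixed-effects fit with σ²_b = 0 and a note. Fixed-effect
standard errors come from the β-block of the inverse penalized
information. Boundary behaviour worth knowing: on data generated with
σ²_b = 0 the estimator piles up near — not exactly at — zero, and on
frailty-generated data the Laplace profile estimate is mildly biased
downward at modest event counts per seal; parameter-recovery tests bound
both effects. Survival curves are not predicted from the frailty model;
curve display uses the fixed-effects model and the KM estimates.

The default reference level is the jurisdiction with the highest empirical
crossing rate (events per day at risk), so all hazard ratios are ≤ 1-ish
and read as "how much less likely to leave than the most mobile
jurisdiction"; it is user-settable.

## Spatial network

Node grouping is transitive chain-rule clustering (single-linkage
connected components of the "within 10 km" graph) on great-circle
distances (haversine, Earth radius 6371.0088 km); endpoints of a chain may
be farther apart than the threshold. Nodes are lettered A, B, … west to
east by centroid longitude. Trips are counted only between consecutive
haul-outs at different nodes — passing near a node without hauling out is
not a visit. Edge metrics: density (trips), occupancy (distinct seals),
weight = density/occupancy (reported to 1 dp), distance (centroid-to-
centroid haversine, or authoritative printed distances when reproducing a
published edge table), and distance-corrected weight = weight/distance.

Betweenness centrality is Brandes shortest-path betweenness with two
explicit conventions, because published analyses often leave them implicit:
edge cost ∈ {1/dc_weight (default; strong connections act as short),
dc_weight} and normalization ∈ {divide by (n−1)(n−2)/2 pair count
(default), divide by maximum raw score}. `select_convention` runs the 2×2
grid against anchor values and reports the matching cell; on the packaged
printed 17-edge network the default cell reproduces the published hub
scores (H = 0.62, B = 0.64) to two decimals, with maximum anchor deviation
0.004.

## Synthetic cohort generator

Each seal is a semi-Markov renewal process: exponential at-sea gaps (mean
28 h) alternate with lognormal haul-out durations (μ = 1.578, σ = 0.6;
mean ≈ 5.8 h), giving roughly 0.7 haul-outs per day. Tracking lengths are
uniform on 30–178 days; weights are normal (75 ± 20 kg, truncated at
30 kg); locations get 500 m Gaussian jitter around discrete sites. These
scales are chosen to emulate a Skagerrak-like post-moult deployment —
deployments of tens to ~180 days, tens of events per seal, ~6 h events.
While a seal occupies unit u, the waiting time to its next crossing is
exponential with rate λ_u·exp(b_i + β_w·(w_i − w̄)) on the spell clock
(defaults: β_w = 0, frailty SD 0.7); the drawn time is thinned to the next
haul-out boundary, which is relocated to a site in another unit chosen
with an exp(−d/20 km) distance-decay kernel — keeping most movement local
with occasional long jumps. The default unit hazards span 0.006–0.08
crossings/day so some units retain seals for months while others turn them
over within two weeks. The thinning means an observed gap time slightly
exceeds the drawn exponential time (by the forward-recurrence time of the
renewal process, ≈ 1 day on average); at crossing timescales of 12+ days
this shifts log hazard ratios by only a few hundredths, which the
parameter-recovery tolerances absorb.

The generator emits ground truth (frailties, spells, crossing times,
site-pair trip counts, event counts) for exact bookkeeping tests, and an
inverse sensor stream (dry during events, wet between, records at exact
transitions plus regular samples) with optional sub-threshold noise blips
(20 s wet inside events, 5 min dry inside gaps, placed with margins that
keep them strictly below the detection rules) so that
`emit_sensor_stream → detect_haulouts` is the identity.

What the generator does *not* emulate: at-sea trajectories, tidal or diel
haul-out rhythms, seasonal behaviour shifts, spatially realistic
coastlines, or location error structure beyond isotropic jitter. Passing
tests therefore demonstrate correctness of the event rules, spell
construction, estimators and network metrics under the stated model — not
behavioural realism of real deployments.

## Problem sizes used in tests

Parameter-recovery tests use 200 simulated 50-seal cohorts (100 with
σ²_b = 0 fitted with the fixed-effects model, 100 with σ²_b = 0.5 fitted
with the frailty model, each with a true 2:1 hazard ratio) and 5 cohorts of
100 seals for frailty-variance recovery; exhaustive oracles cover every
censoring pattern at n ≤ 8 for Kaplan–Meier, 100 random instances of up to
200 points for clustering, and random graphs of up to 9 nodes for
betweenness. These sizes give stable verdicts for the stated tolerances
(CI coverage ≥ 90%, variance within a factor of two).

## Known limitations

* The frailty fit is Laplace-ML; no REML-style correction, no nested or
  crossed random effects, no time-varying covariates or stratified
  baselines.
* Polygon assignment is pure containment: offshore events (skerries outside
  the supplied polygons) become `unassigned` rather than snapped to the
  nearest unit.
* The network is static and undirected; no temporal dynamics, direction of
  travel, or community detection.
* Betweenness convention selection needs anchor values; absent anchors the
  defaults are used and logged.
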