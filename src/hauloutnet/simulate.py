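"""Synthetic multi-seal haul-out cohorts with known ground truth.

The generator emulates the kind of data a GPS phone-tag deployment on
coastal harbour seals produces: each seal alternates at-sea gaps and
haul-out events at discrete sites (a semi-Markov renewal process -- only
haul-outs matter to the analysis, so no at-sea trajectory is simulated).
Management-unit crossings follow the proportional-hazards structure the
survival models assume: while a seal occupies a unit ``u`` the waiting time
to its next crossing is exponential with rate
``lambda_u * exp(b_i + weight_log_hazard * (w_i - mean_w))`` on the
spell clock, with ``b_i ~ N(0, frailty_sd^2)`` a per-seal log-hazard
intercept.  The drawn crossing time is thinned to the next haul-out
boundary: the first haul-out starting after it is relocated to a site in a
different unit (chosen with an exponential distance-decay kernel), which is
exactly the event the downstream analysis codes as cross-boundary.

Default scales mirror a Skagerrak-like deployment: tracking lengths of
30-178 days, lognormal haul-out durations with mean ~5.8 h, mean at-sea
gaps of ~28 h (about 0.7 haul-outs per day), and per-unit leave hazards
spanning roughly 0.006-0.08 crossings per day so that some units retain
their seals for months while others turn them over within two weeks.

Every cohort is reproducible from a single integer seed; each seal draws
from its own counter-based substream, so enlarging ``n_seals`` leaves the
earlier seals' trajectories unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .events import EVENT_COLUMNS

DEFAULT_UNIT_HAZARDS = {
    # leave-hazard per day while occupying the unit; ordering echoes a
    # coastline where some counties retain seals far longer than others
    "Sweden": 0.080,
    "Vest-Agder": 0.077,
    "Ostfold": 0.047,
    "Buskerud": 0.040,
    "Aust-Agder": 0.037,
    "Vestfold": 0.024,
    "Telemark": 0.006,
}


def default_sites(units: list[str] | None = None, sites_per_unit: int = 2,
                  lon0: float = 7.0, lat: float = 58.5) -> pd.DataFrame:
    """Synthetic coastline: one longitude band per unit, ``sites_per_unit``
    sites per band spaced ~17 km apart (far enough to form distinct nodes
    at a 10 km clustering threshold)."""
    if units is None:
        units = list(DEFAULT_UNIT_HAZARDS)
    rows = []
    for i, unit in enumerate(units):
        for s in range(sites_per_unit):
            rows.append({"site_id": f"{unit}_{s}",
                         "lon": lon0 + i * 1.0 + 0.2 + s * 0.3,
                         "lat": lat + (s % 2) * 0.02,
                         "unit": unit})
    return pd.DataFrame(rows)


def unit_polygons(sites: pd.DataFrame, margin: float = 0.45) -> dict:
    """GeoJSON FeatureCollection of rectangular unit boundaries around the
    sites of each unit (synthetic stand-in for administrative polygons)."""
    feats = []
    for unit, grp in sites.groupby("unit", sort=False):
        lo_x, hi_x = grp["lon"].min() - margin, grp["lon"].max() + margin
        lo_y, hi_y = grp["lat"].min() - margin, grp["lat"].max() + margin
        feats.append({
            "type": "Feature", "properties": {"unit": unit},
            "geometry": {"type": "Polygon", "coordinates": [[
                [lo_x, lo_y], [hi_x, lo_y], [hi_x, hi_y], [lo_x, hi_y], [lo_x, lo_y]]]},
        })
    return {"type": "FeatureCollection", "features": feats}


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator.

    Durations are hours unless stated; hazards are per day.
    """

    sites: pd.DataFrame = field(default_factory=default_sites)
    n_seals: int = 26
    unit_hazards: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNIT_HAZARDS))
    site_switch_prob: float = 0.3
    duration_lognorm_mu: float = 1.578   # mean exp(mu + sigma^2/2) ~ 5.8 h
    duration_lognorm_sigma: float = 0.6
    gap_mean_h: float = 28.0
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 20.0
    weight_log_hazard: float = 0.0       # per kg deviation from the mean
    frailty_sd: float = 0.7
    tracking_days_range: tuple[float, float] = (30.0, 178.0)
    distance_decay_km: float = 20.0
    jitter_sd_m: float = 500.0
    start_date: str = "2020-09-01"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.site_switch_prob <= 1:
            raise ValueError("site_switch_prob must be in [0, 1]")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be non-negative")
        if any(lam < 0 for lam in self.unit_hazards.values()):
            raise ValueError("unit hazards must be non-negative")
        units = set(self.sites["unit"])
        missing = units - set(self.unit_hazards)
        if missing:
            raise ValueError(f"no leave hazard given for unit(s) {sorted(missing)}")
        if len(units) < 2 and any(self.unit_hazards.get(u, 0) > 0 for u in units):
            raise ValueError("a single-unit configuration with positive leave "
                             "hazard has no crossing destination")


@dataclass
class GroundTruth:
    """Generator-side bookkeeping the pipeline should recover."""

    frailty: dict[str, float]
    weights: dict[str, float]
    tagging_unit: dict[str, str]
    tagging_site: dict[str, str]
    spells: pd.DataFrame        # seal_id, spell, unit, gap_days, event
    n_events: dict[str, int]
    site_trips: dict[tuple[str, str], int]   # unordered site-pair trip counts
    crossing_times: dict[str, list[float]]   # elapsed days at each crossing

    def to_json(self, path) -> None:
        d = asdict(self)
        d["spells"] = self.spells.to_dict(orient="records")
        d["site_trips"] = {f"{u}|{v}": c for (u, v), c in self.site_trips.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)


def _seal_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def simulate_cohort(config: SimulationConfig):
    """Generate a cohort of seal tracks.

    Returns ``(events, seals, truth)``: an events table (EVENT_COLUMNS),
    per-seal metadata (tagging unit/site/location, weight, sex, first/last
    record), and the :class:`GroundTruth`.
    """
    cfg = config
    sites = cfg.sites.reset_index(drop=True)
    site_xy = sites[["lon", "lat"]].to_numpy(float)
    units = sites["unit"].to_numpy()
    t0 = pd.Timestamp(cfg.start_date, tz="UTC")
    deg_per_m_lat = 1.0 / 111_195.0

    from .network import haversine

    ev_rows, seal_rows, spells = [], [], []
    truth = GroundTruth({}, {}, {}, {}, pd.DataFrame(), {}, {}, {})
    for i in range(cfg.n_seals):
        rng = _seal_rng(cfg.seed, i)
        sid = f"seal_{i:03d}"
        b = rng.normal(0.0, cfg.frailty_sd)
        w = float(np.clip(rng.normal(cfg.weight_mean_kg, cfg.weight_sd_kg), 30.0, None))
        sex = "M" if rng.random() < 0.5 else "F"
        site = int(rng.integers(len(sites)))
        track_days = float(rng.uniform(*cfg.tracking_days_range))
        track_h = track_days * 24.0
        hz_scale = float(np.exp(b + cfg.weight_log_hazard * (w - cfg.weight_mean_kg)))

        truth.frailty[sid] = float(b)
        truth.weights[sid] = w
        truth.tagging_unit[sid] = str(units[site])
        truth.tagging_site[sid] = str(sites["site_id"].iloc[site])
        seal_rows.append({
            "seal_id": sid, "tagging_unit": units[site],
            "tagging_lon": site_xy[site, 0], "tagging_lat": site_xy[site, 1],
            "weight_kg": w, "sex": sex,
            "first_record": t0, "last_record": t0 + pd.Timedelta(hours=track_h),
        })

        def draw_cross(unit):
            lam = cfg.unit_hazards[str(unit)] * hz_scale
            return np.inf if lam <= 0 else rng.exponential(1.0 / lam) * 24.0  # hours

        t = 0.0
        spell_unit = None
        spell_origin = 0.0
        cross_at = np.inf       # spell clock, hours
        spell_no = 0
        n_ev = 0
        prev_site = None
        crossings = []
        while True:
            t += rng.exponential(cfg.gap_mean_h)
            if t >= track_h:
                break
            dur = float(rng.lognormal(cfg.duration_lognorm_mu, cfg.duration_lognorm_sigma))
            if spell_unit is None:
                # first haul-out opens spell 1 and starts its clock
                spell_unit, spell_origin = units[site], t
                spell_no = 1
                cross_at = draw_cross(spell_unit)
            elif t - spell_origin >= cross_at:
                # thinned crossing: this haul-out lands in a different unit
                other = np.flatnonzero(units != spell_unit)
                d = haversine(site_xy[site, 0], site_xy[site, 1],
                              site_xy[other, 0], site_xy[other, 1])
                p = np.exp(-np.atleast_1d(d) / cfg.distance_decay_km)
                site = int(rng.choice(other, p=p / p.sum()))
                spells.append({"seal_id": sid, "spell": spell_no, "unit": spell_unit,
                               "gap_days": (t - spell_origin) / 24.0, "event": 1})
                crossings.append(t / 24.0)
                spell_no += 1
                spell_unit, spell_origin = units[site], t
                cross_at = draw_cross(spell_unit)
            elif rng.random() < cfg.site_switch_prob:
                same = np.flatnonzero((units == spell_unit) &
                                      (np.arange(len(sites)) != site))
                if same.size:
                    d = haversine(site_xy[site, 0], site_xy[site, 1],
                                  site_xy[same, 0], site_xy[same, 1])
                    p = np.exp(-np.atleast_1d(d) / cfg.distance_decay_km)
                    site = int(rng.choice(same, p=p / p.sum()))
            end = min(t + dur, track_h)
            jit = rng.normal(0.0, cfg.jitter_sd_m * deg_per_m_lat, size=2)
            jit[0] /= np.cos(np.radians(site_xy[site, 1]))
            ev_rows.append({
                "seal_id": sid,
                "start": t0 + pd.Timedelta(hours=t),
                "end": t0 + pd.Timedelta(hours=end),
                "lon": site_xy[site, 0] + jit[0], "lat": site_xy[site, 1] + jit[1],
            })
            n_ev += 1
            if prev_site is not None and prev_site != site:
                key = tuple(sorted((str(sites["site_id"].iloc[prev_site]),
                                    str(sites["site_id"].iloc[site]))))
                truth.site_trips[key] = truth.site_trips.get(key, 0) + 1
            prev_site = site
            t = end
        if spell_no:
            spells.append({"seal_id": sid, "spell": spell_no, "unit": spell_unit,
                           "gap_days": track_h / 24.0 - spell_origin / 24.0, "event": 0})
        truth.n_events[sid] = n_ev
        truth.crossing_times[sid] = crossings

    events = pd.DataFrame(ev_rows, columns=["seal_id", "start", "end", "lon", "lat"])
    if len(events):
        events["duration_h"] = (events["end"] - events["start"]) / pd.Timedelta(hours=1)
    else:
        events["duration_h"] = pd.Series(dtype=float)
    events = events[EVENT_COLUMNS]
    seals = pd.DataFrame(seal_rows)
    truth.spells = pd.DataFrame(
        spells, columns=["seal_id", "spell", "unit", "gap_days", "event"])
    return events, seals, truth


def emit_sensor_stream(events: pd.DataFrame, sampling_s: float = 30.0,
                       noise_prob: float = 0.0,
                       rng: np.random.Generator | None = None,
                       lead_h: float = 1.0) -> pd.DataFrame:
    """Wet/dry sensor records consistent with an events table.

    The stream is dry during events and wet in between, sampled every
    ``sampling_s`` seconds with extra records at the exact state
    transitions (so detection recovers boundaries exactly).  With
    probability ``noise_prob`` a wet blip (20 s) is injected inside an
    event and a dry blip (5 min) into a gap -- both below the detection
    thresholds, so a correct detector absorbs them.
    """
    import warnings

    if sampling_s > 40.0:
        warnings.warn("sampling interval coarser than 40 s: the wet-termination "
                      "rule cannot be resolved reliably")
    if noise_prob and rng is None:
        rng = np.random.default_rng(0)
    sec = pd.Timedelta(seconds=1)
    rows = []
    for sid, grp in events.sort_values("start").groupby("seal_id", sort=False):
        g = grp.reset_index(drop=True)
        t_first = g["start"].iloc[0] - pd.Timedelta(hours=lead_h)
        t_last = g["end"].iloc[-1] + pd.Timedelta(hours=lead_h)
        marks = [(t_first, "wet", np.nan, np.nan)]
        for k, r in g.iterrows():
            marks.append((r["start"], "dry", r["lon"], r["lat"]))
            if noise_prob and rng.random() < noise_prob and \
                    (r["end"] - r["start"]) > pd.Timedelta(minutes=4):
                mid = r["start"] + (r["end"] - r["start"]) / 2
                marks.append((mid, "wet", np.nan, np.nan))
                marks.append((mid + 20 * sec, "dry", r["lon"], r["lat"]))
            marks.append((r["end"], "wet", np.nan, np.nan))
            nxt = g["start"].iloc[k + 1] if k + 1 < len(g) else t_last
            gap = nxt - r["end"]
            if noise_prob and rng.random() < noise_prob and gap > pd.Timedelta(minutes=22):
                mid = r["end"] + gap / 2
                marks.append((mid, "dry", np.nan, np.nan))
                marks.append((mid + pd.Timedelta(minutes=5), "wet", np.nan, np.nan))
        marks.sort(key=lambda m: m[0])
        # regular sampling between marks, repeating the current state
        for (tm, st, lo, la), nxt in zip(marks, [m[0] for m in marks[1:]] + [t_last]):
            rows.append({"seal_id": sid, "timestamp": tm, "state": st,
                         "lon": lo, "lat": la})
            k = 1
            while tm + k * sampling_s * sec < nxt:
                rows.append({"seal_id": sid, "timestamp": tm + k * sampling_s * sec,
                             "state": st, "lon": lo, "lat": la})
                k += 1
        rows.append({"seal_id": sid, "timestamp": t_last, "state": "wet",
                     "lon": np.nan, "lat": np.nan})
    out = pd.DataFrame(rows, columns=["seal_id", "timestamp", "state", "lon", "lat"])
    return out.drop_duplicates(subset=["seal_id", "timestamp"], keep="first",
                               ignore_index=True)
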