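"""Haul-out event construction from wet/dry sensor streams.

A haul-out is detected as a period in which the tag's wet/dry sensor stays
dry, allowing for brief submersions: the period must last at least
``min_dry`` (default 10 minutes) and it ends at the first instant a wet run
of at least ``end_wet`` (default 40 seconds) begins.  Wet interruptions
shorter than ``end_wet`` do not split a haul-out.  Consecutive haul-outs of
one seal separated by less than ``gap`` (default 10 minutes) are merged and
treated as a single event, and seals with fewer than ``min_days`` of data
are dropped before analysis.

Events are carried as a :class:`pandas.DataFrame` with columns
``seal_id, start, end, lon, lat, duration_h`` (UTC timestamps, WGS84
decimal degrees, hours).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._validation import OrderingError, ParseError, as_timedelta, check_coordinates, require_columns

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["seal_id", "start", "end", "lon", "lat", "duration_h"]

WET, DRY = "wet", "dry"


@dataclass
class SealTrack:
    """Per-seal metadata plus its ordered haul-out events."""

    seal_id: str
    tagging_unit: str | None = None
    tagging_lon: float = np.nan
    tagging_lat: float = np.nan
    weight_kg: float = np.nan
    sex: str | None = None
    first_record: pd.Timestamp | None = None
    last_record: pd.Timestamp | None = None
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    @property
    def span_days(self) -> float:
        """Elapsed days between first and last record of any kind."""
        first, last = self.first_record, self.last_record
        if first is None or last is None:
            if len(self.events) == 0:
                return 0.0
            first = self.events["start"].min()
            last = self.events["end"].max()
        return (last - first) / pd.Timedelta(days=1)


def _finalize_events(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["duration_h"] = (df["end"] - df["start"]) / pd.Timedelta(hours=1)
    if (df["duration_h"] <= 0).any():
        raise ValueError("event with non-positive duration")
    return df.reset_index(drop=True)[[c for c in EVENT_COLUMNS if c in df.columns] +
                                     [c for c in df.columns if c not in EVENT_COLUMNS]]


class HaulOutDetector:
    """Sensor-rule haul-out detector (stateless transformer).

    Parameters
    ----------
    min_dry : str | Timedelta, default "10min"
        Minimum dry duration for a period to qualify as a haul-out.
    end_wet : str | Timedelta, default "40s"
        A wet run of at least this length terminates a haul-out; shorter
        wet blips are absorbed.
    """

    def __init__(self, min_dry="10min", end_wet="40s"):
        self.min_dry = min_dry
        self.end_wet = end_wet

    def get_params(self, deep: bool = True) -> dict:
        return {"min_dry": self.min_dry, "end_wet": self.end_wet}

    def set_params(self, **params) -> "HaulOutDetector":
        for k, v in params.items():
            if k not in ("min_dry", "end_wet"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        """Detect haul-out events in a wet/dry record stream.

        ``records`` needs columns ``seal_id, timestamp, state`` with state in
        {"wet", "dry"}; optional ``lon``/``lat`` columns attach a location to
        each event (first in-event fix).  A record's state is taken to hold
        until the next record; the stream's last timestamp closes the final
        run.
        """
        require_columns(records, ["seal_id", "timestamp", "state"], "sensor records")
        min_dry = as_timedelta(self.min_dry, "min_dry")
        end_wet = as_timedelta(self.end_wet, "end_wet")
        bad = set(records["state"].unique()) - {WET, DRY}
        if bad:
            raise ParseError(f"unknown wet/dry state values {sorted(bad)}")
        out = []
        for seal_id, grp in records.groupby("seal_id", sort=False):
            out.append(self._one_seal(str(seal_id), grp, min_dry, end_wet))
        if not out:
            return pd.DataFrame(columns=EVENT_COLUMNS)
        return _finalize_events(pd.concat(out, ignore_index=True))

    def _one_seal(self, seal_id, grp, min_dry, end_wet) -> pd.DataFrame:
        ts = pd.to_datetime(grp["timestamp"], utc=True)
        if ts.duplicated().any():
            n = int(ts.duplicated().sum())
            logger.warning("seal %s: dropping %d duplicate-timestamp records", seal_id, n)
            keep = ~ts.duplicated()
            grp, ts = grp[keep], ts[keep]
        if not ts.is_monotonic_increasing:
            raise OrderingError(f"seal {seal_id}: timestamps not sorted")
        t = ts.to_numpy()
        state = grp["state"].to_numpy()
        has_loc = "lon" in grp.columns and "lat" in grp.columns
        lon = grp["lon"].to_numpy() if has_loc else None
        lat = grp["lat"].to_numpy() if has_loc else None

        # run-length encode; run i spans [t[s_i], t[s_{i+1}]) and the final
        # run is closed by the last timestamp
        change = np.flatnonzero(state[1:] != state[:-1]) + 1
        starts = np.concatenate([[0], change])
        run_state = state[starts]
        run_t0 = t[starts]
        run_t1 = np.concatenate([t[change], [t[-1]]])

        # absorb wet runs shorter than end_wet between dry runs
        events = []  # (start, end, first_dry_index)
        i = 0
        n = len(run_state)
        while i < n:
            if run_state[i] != DRY:
                i += 1
                continue
            j = i
            end = run_t1[i]
            while j + 2 < n and run_state[j + 1] == WET and \
                    (run_t1[j + 1] - run_t0[j + 1]) < end_wet:
                j += 2
                end = run_t1[j]
            if end - run_t0[i] >= min_dry:
                events.append((run_t0[i], end, starts[i]))
            i = j + 1

        rows = []
        for t0, t1, idx in events:
            row = {"seal_id": seal_id, "start": pd.Timestamp(t0), "end": pd.Timestamp(t1)}
            if has_loc:
                # first finite fix inside the event
                inside = np.flatnonzero((t >= t0) & (t < t1) & np.isfinite(lon) & np.isfinite(lat))
                row["lon"] = lon[inside[0]] if inside.size else np.nan
                row["lat"] = lat[inside[0]] if inside.size else np.nan
            else:
                row["lon"] = np.nan
                row["lat"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows, columns=["seal_id", "start", "end", "lon", "lat"])


def detect_haulouts(records: pd.DataFrame, min_dry="10min", end_wet="40s") -> pd.DataFrame:
    """Functional wrapper around :class:`HaulOutDetector`."""
    return HaulOutDetector(min_dry=min_dry, end_wet=end_wet).transform(records)


def merge_events(events: pd.DataFrame, gap="10min") -> pd.DataFrame:
    """Merge consecutive haul-outs of a seal separated by less than ``gap``.

    The merged event keeps the first start, the last end, and the location of
    the longest constituent event.  Idempotent.  Raises on overlapping input
    events.
    """
    require_columns(events, ["seal_id", "start", "end"], "events")
    gap = as_timedelta(gap, "gap")
    if len(events) == 0:
        return _finalize_events(events.copy()) if len(events) else events.copy()
    out = []
    for seal_id, grp in events.groupby("seal_id", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        if (grp["start"].iloc[1:].to_numpy() < grp["end"].iloc[:-1].to_numpy()).any():
            raise ValueError(f"seal {seal_id}: overlapping events cannot be merged")
        cur = grp.iloc[0].to_dict()
        best_dur = cur["end"] - cur["start"]
        for _, row in grp.iloc[1:].iterrows():
            if row["start"] - cur["end"] < gap:
                dur = row["end"] - row["start"]
                if dur > best_dur:
                    best_dur = dur
                    cur["lon"], cur["lat"] = row["lon"], row["lat"]
                cur["end"] = row["end"]
            else:
                out.append(cur)
                cur = row.to_dict()
                best_dur = cur["end"] - cur["start"]
        out.append(cur)
    merged = pd.DataFrame(out)
    n_merged = len(events) - len(merged)
    if n_merged:
        logger.info("merged %d haul-out events across %d seals",
                    n_merged, events["seal_id"].nunique())
    return _finalize_events(merged[["seal_id", "start", "end", "lon", "lat"]])


def filter_tracks(tracks: list[SealTrack], min_days: float = 10.0) -> list[SealTrack]:
    """Drop seals whose records span fewer than ``min_days`` (boundary inclusive)."""
    kept = [tr for tr in tracks if tr.span_days >= min_days]
    removed = len(tracks) - len(kept)
    if removed:
        logger.info("removed %d individual(s) with < %g days of movement data",
                    removed, min_days)
    return kept


def tracks_from_frames(events: pd.DataFrame, seals: pd.DataFrame | None = None) -> list[SealTrack]:
    """Bundle an events table (and optional per-seal metadata) into SealTracks.

    ``seals`` may carry columns ``seal_id, tagging_unit, tagging_lon,
    tagging_lat, weight_kg, sex, first_record, last_record``.
    """
    require_columns(events, ["seal_id", "start", "end"], "events")
    meta = {} if seals is None else {str(r["seal_id"]): r for _, r in seals.iterrows()}
    tracks = []
    ids = list(dict.fromkeys(events["seal_id"])) if seals is None else list(meta)
    for sid in ids:
        ev = events[events["seal_id"] == sid].sort_values("start").reset_index(drop=True)
        m = meta.get(str(sid), {})
        get = (lambda k, d=np.nan: m[k] if k in m and pd.notna(m[k]) else d)
        tracks.append(SealTrack(
            seal_id=str(sid),
            tagging_unit=get("tagging_unit", None),
            tagging_lon=get("tagging_lon"),
            tagging_lat=get("tagging_lat"),
            weight_kg=get("weight_kg"),
            sex=get("sex", None),
            first_record=get("first_record", None),
            last_record=get("last_record", None),
            events=ev,
        ))
    return tracks


def _mean_ci(x: np.ndarray) -> tuple[float, float, float]:
    """Across-seal mean with normal-approximation 95% CI (mean +/- 1.96 SE)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan, np.nan, np.nan
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return m, m - 1.96 * se, m + 1.96 * se


def summarize_tracks(tracks: list[SealTrack]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-seal deployment/haul-out summary plus across-seal mean (95% CI).

    Returns ``(per_seal, cohort)``.  ``per_seal`` has one row per seal with
    deployment days, event count, haul-out duration statistics and maximum
    great-circle displacement from the tagging location; when events carry a
    ``unit`` column, the number of management units visited and the
    percentage of haul-outs outside the tagging unit are added.  ``cohort``
    aggregates each numeric column as mean, lo95, hi95, min, max.
    """
    from .network import haversine

    if not tracks:
        raise ValueError("no tracks to summarize")
    rows = []
    for tr in tracks:
        ev = tr.events
        if len(ev) == 0:
            warnings.warn(f"seal {tr.seal_id} has no haul-out events; skipped in summary")
            continue
        row = {
            "seal_id": tr.seal_id,
            "deployment_days": tr.span_days,
            "n_haulouts": len(ev),
            "mean_duration_h": float(ev["duration_h"].mean()),
            "min_duration_h": float(ev["duration_h"].min()),
            "max_duration_h": float(ev["duration_h"].max()),
        }
        if np.isfinite(tr.tagging_lon) and np.isfinite(tr.tagging_lat) and ev["lon"].notna().any():
            d = haversine(tr.tagging_lon, tr.tagging_lat,
                          ev["lon"].to_numpy(float), ev["lat"].to_numpy(float))
            row["max_displacement_km"] = float(np.nanmax(d))
        else:
            row["max_displacement_km"] = np.nan
        if "unit" in ev.columns:
            assigned = ev[ev["unit"].notna() & (ev["unit"] != "unassigned")]
            row["n_units_visited"] = int(assigned["unit"].nunique())
            if tr.tagging_unit is not None and len(assigned):
                row["pct_outside_tagging_unit"] = float(
                    100.0 * (assigned["unit"] != tr.tagging_unit).mean())
        rows.append(row)
    per_seal = pd.DataFrame(rows)
    agg = []
    for col in per_seal.columns:
        if col == "seal_id":
            continue
        x = per_seal[col].to_numpy(float)
        m, lo, hi = _mean_ci(x)
        finite = x[np.isfinite(x)]
        agg.append({"statistic": col, "mean": m, "lo95": lo, "hi95": hi,
                    "min": float(np.min(finite)) if finite.size else np.nan,
                    "max": float(np.max(finite)) if finite.size else np.nan})
    return per_seal, pd.DataFrame(agg)


def read_events_csv(path) -> pd.DataFrame:
    """Read a telemetry events CSV (seal_id, start, end, lon, lat)."""
    df = pd.read_csv(path)
    require_columns(df, ["seal_id", "start", "end", "lon", "lat"], "events CSV")
    df["seal_id"] = df["seal_id"].astype(str)
    from ._validation import as_utc

    df["start"] = as_utc(df["start"])
    df["end"] = as_utc(df["end"])
    check_coordinates(df["lon"].dropna(), df["lat"].dropna())
    if (df["end"] <= df["start"]).any():
        raise ParseError("events with end <= start present")
    return _finalize_events(df[["seal_id", "start", "end", "lon", "lat"]])


def read_sensor_csv(path) -> pd.DataFrame:
    """Read a wet/dry sensor CSV (seal_id, timestamp, state[, lon, lat])."""
    df = pd.read_csv(path)
    require_columns(df, ["seal_id", "timestamp", "state"], "sensor CSV")
    df["seal_id"] = df["seal_id"].astype(str)
    from ._validation import as_utc

    df["timestamp"] = as_utc(df["timestamp"])
    return df
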