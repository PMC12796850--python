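"""Management-unit assignment and cross-boundary spell construction.

Haul-out events are assigned to administrative management units (Norwegian
counties, plus Sweden and Denmark as single national units) by polygon
containment, each event is flagged as cross-boundary when its unit differs
from the immediately preceding haul-out's unit, and maximal same-unit runs
of haul-outs ("spells") are converted to counting-process risk intervals on
a gap-time clock: the clock restarts at zero at every crossing, a spell ends
with event=1 at the start of the next cross-boundary haul-out, and the final
spell of each seal is censored at the end of its tracking period.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.validation import explain_validity

from ._validation import require_columns
from .events import SealTrack

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

RISK_COLUMNS = ["seal_id", "spell", "unit", "t_start", "t_stop", "event", "weight_kg"]


class GeometryError(ValueError):
    """A boundary polygon is invalid."""


@dataclass
class ManagementUnitMap:
    """Labelled boundary polygons defining jurisdictions.

    ``features`` is an ordered list of ``(unit_label, shapely geometry)`` in
    WGS84.  File order matters: a point on a shared edge is resolved to the
    first feature that covers it.
    """

    features: list[tuple[str, object]]

    def __post_init__(self):
        labels = [lab for lab, _ in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError("unit labels must be unique")
        for lab, geom in self.features:
            if not geom.is_valid:
                raise GeometryError(f"invalid geometry for unit {lab!r}: "
                                    f"{explain_validity(geom)}")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.features]

    @classmethod
    def from_geojson(cls, source) -> "ManagementUnitMap":
        """Load from a GeoJSON FeatureCollection (path, file object or dict).

        Each feature must carry a ``unit`` property.
        """
        if isinstance(source, dict):
            gj = source
        elif hasattr(source, "read"):
            gj = json.load(source)
        else:
            with open(source) as fh:
                gj = json.load(fh)
        feats = []
        for f in gj["features"]:
            props = f.get("properties") or {}
            if "unit" not in props:
                raise ValueError("GeoJSON feature missing 'unit' property")
            feats.append((str(props["unit"]), shape(f["geometry"])))
        return cls(feats)

    def to_geojson(self) -> dict:
        from shapely.geometry import mapping

        return {"type": "FeatureCollection",
                "features": [{"type": "Feature", "properties": {"unit": lab},
                              "geometry": mapping(geom)} for lab, geom in self.features]}

    def assign(self, lon: float, lat: float) -> str:
        """Unit containing the point (boundary points go to the first feature
        in file order); ``"unassigned"`` if no polygon covers it."""
        pt = Point(float(lon), float(lat))
        for lab, geom in self.features:
            if geom.covers(pt):
                return lab
        return UNASSIGNED


def assign_unit(lon: float, lat: float, unit_map: ManagementUnitMap) -> str:
    return unit_map.assign(lon, lat)


def assign_units(events: pd.DataFrame, unit_map: ManagementUnitMap) -> pd.DataFrame:
    """Add a ``unit`` column to an events table by polygon containment."""
    require_columns(events, ["lon", "lat"], "events")
    out = events.copy()
    out["unit"] = [unit_map.assign(lo, la) if np.isfinite(lo) and np.isfinite(la)
                   else UNASSIGNED
                   for lo, la in zip(out["lon"], out["lat"])]
    n_un = int((out["unit"] == UNASSIGNED).sum())
    if n_un:
        logger.warning("%d haul-out event(s) fell outside every management unit", n_un)
    return out


def flag_cross_boundary(events: pd.DataFrame) -> pd.DataFrame:
    """Flag each haul-out as cross-boundary (1) when its unit differs from the
    preceding haul-out's unit, per seal.  The first event of each seal gets
    NaN (undefined).  Events must already carry assigned units; unassigned
    events should be excluded beforehand.
    """
    require_columns(events, ["seal_id", "start", "unit"], "labelled events")
    out = events.sort_values(["seal_id", "start"], kind="stable").copy()
    prev = out.groupby("seal_id", sort=False)["unit"].shift(1)
    out["cross_boundary"] = np.where(prev.isna(), np.nan,
                                     (out["unit"] != prev).astype(float))
    return out


def drop_unassigned(events: pd.DataFrame) -> pd.DataFrame:
    n = int((events["unit"] == UNASSIGNED).sum())
    if n:
        logger.warning("dropping %d unassigned event(s) from cross-boundary analysis", n)
    return events[events["unit"] != UNASSIGNED].reset_index(drop=True)


def build_risk_intervals(events: pd.DataFrame, censor_time: pd.Timestamp,
                         weight_kg: float = np.nan,
                         seal_id: str | None = None) -> pd.DataFrame:
    """Counting-process risk intervals (gap-time clock) for one seal.

    ``events`` are this seal's labelled haul-outs (unassigned excluded),
    time-sorted.  Spell 1 opens at the first haul-out's start; a spell closes
    with ``event=1`` at the start of the next cross-boundary haul-out, which
    simultaneously opens the next spell with the clock reset to zero; the
    final spell is censored (``event=0``) at ``censor_time``.
    """
    if len(events) == 0:
        raise ValueError("cannot build risk intervals from zero assigned events")
    ev = events.sort_values("start").reset_index(drop=True)
    sid = seal_id if seal_id is not None else str(ev["seal_id"].iloc[0])
    censor_time = pd.Timestamp(censor_time)
    if censor_time < ev["end"].iloc[-1]:
        raise ValueError(f"seal {sid}: censor time precedes last haul-out end")
    day = pd.Timedelta(days=1)
    rows = []
    origin = ev["start"].iloc[0]
    unit = ev["unit"].iloc[0]
    spell = 1
    for i in range(1, len(ev)):
        if ev["unit"].iloc[i] != unit:
            t_cross = ev["start"].iloc[i]
            rows.append({"seal_id": sid, "spell": spell, "unit": unit,
                         "t_start": 0.0, "t_stop": (t_cross - origin) / day,
                         "event": 1, "weight_kg": weight_kg})
            origin, unit = t_cross, ev["unit"].iloc[i]
            spell += 1
    rows.append({"seal_id": sid, "spell": spell, "unit": unit,
                 "t_start": 0.0, "t_stop": (censor_time - origin) / day,
                 "event": 0, "weight_kg": weight_kg})
    out = pd.DataFrame(rows, columns=RISK_COLUMNS)
    if (out["t_stop"] <= out["t_start"]).any():
        raise ValueError(f"seal {sid}: degenerate (zero-length) risk interval")
    return out


def cohort_risk_intervals(tracks: list[SealTrack]) -> pd.DataFrame:
    """Risk intervals for every seal with at least one assigned haul-out."""
    frames = []
    for tr in tracks:
        ev = tr.events
        if "unit" in ev.columns:
            ev = drop_unassigned(ev)
        if len(ev) == 0:
            logger.warning("seal %s has no assigned haul-outs; excluded from survival data",
                           tr.seal_id)
            continue
        censor = tr.last_record if tr.last_record is not None else ev["end"].max()
        frames.append(build_risk_intervals(ev, censor, tr.weight_kg, tr.seal_id))
    if not frames:
        raise ValueError("no seal contributed risk intervals")
    return pd.concat(frames, ignore_index=True)


def displacement_fraction(events: pd.DataFrame, tagging_unit: str) -> float:
    """Percentage of a seal's assigned haul-outs outside its tagging unit."""
    ev = events[events["unit"] != UNASSIGNED]
    if len(ev) == 0:
        raise ValueError("no assigned events")
    return float(100.0 * (ev["unit"] != tagging_unit).mean())


def status_at_date(tracks: list[SealTrack], date, window_days: float = 7.0):
    """Proportion of active seals with a cross-unit haul-out near a date.

    Among seals recording around ``date`` (their record span overlaps
    ``date +/- window_days``), the fraction with at least one haul-out inside
    the window in a unit different from their tagging unit.  Returns
    ``(numerator, denominator, proportion)``.
    """
    date = pd.Timestamp(date)
    if date.tzinfo is None:
        date = date.tz_localize("UTC")
    w = pd.Timedelta(days=window_days)
    lo, hi = date - w, date + w
    num = den = 0
    for tr in tracks:
        first = tr.first_record if tr.first_record is not None else tr.events["start"].min()
        last = tr.last_record if tr.last_record is not None else tr.events["end"].max()
        if pd.isna(first) or first > hi or last < lo:
            continue
        den += 1
        ev = tr.events
        if "unit" not in ev.columns or tr.tagging_unit is None:
            continue
        inside = ev[(ev["start"] <= hi) & (ev["end"] >= lo) &
                    (ev["unit"] != UNASSIGNED) & (ev["unit"] != tr.tagging_unit)]
        if len(inside):
            num += 1
    if den == 0:
        raise ValueError(f"no seal was recording within {window_days} days of {date.date()}")
    return num, den, num / den
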