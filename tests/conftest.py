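import numpy as np
import pandas as pd
import pytest

import hauloutnet as hn

T0 = pd.Timestamp("2021-01-01 00:00:00", tz="UTC")


def make_events(seal_id, intervals, lon=10.0, lat=59.0):
    """Events from (start_offset, end_offset) pairs (pandas offsets strings
    or Timedeltas) relative to T0."""
    rows = []
    for k, (s, e) in enumerate(intervals):
        rows.append({
            "seal_id": seal_id,
            "start": T0 + pd.Timedelta(s),
            "end": T0 + pd.Timedelta(e),
            "lon": lon if np.isscalar(lon) else lon[k],
            "lat": lat if np.isscalar(lat) else lat[k],
        })
    df = pd.DataFrame(rows, columns=["seal_id", "start", "end", "lon", "lat"])
    df["duration_h"] = (df["end"] - df["start"]) / pd.Timedelta(hours=1)
    return df


def make_sensor(seal_id, segments, t0=T0):
    """Sensor records from (state, duration) run-length segments, one record
    per second boundary at segment starts plus 10 s sampling."""
    rows = []
    t = t0
    for state, dur in segments:
        dur = pd.Timedelta(dur)
        end = t + dur
        cur = t
        while cur < end:
            rows.append({"seal_id": seal_id, "timestamp": cur, "state": state})
            cur += pd.Timedelta(seconds=10)
        t = end
    rows.append({"seal_id": seal_id, "timestamp": t, "state": "wet"})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def printed_network():
    return hn.network_from_edge_table(hn.load_printed_edges())


@pytest.fixture(scope="session")
def square_map():
    """Two unit squares sharing the edge lon=1."""
    gj = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"unit": "West"},
         "geometry": {"type": "Polygon",
                      "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]]}},
        {"type": "Feature", "properties": {"unit": "East"},
         "geometry": {"type": "Polygon",
                      "coordinates": [[[1, 0], [2, 0], [2, 1], [1, 1], [1, 0]]]}},
    ]}
    return hn.ManagementUnitMap.from_geojson(gj)


@pytest.fixture(scope="session")
def two_unit_config():
    units = ["UnitA", "UnitB"]
    sites = hn.default_sites(units=units)
    return hn.SimulationConfig(sites=sites,
                               unit_hazards={"UnitA": 0.08, "UnitB": 0.04},
                               n_seals=30, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = hn.SimulationConfig(n_seals=10, seed=5)
    return hn.simulate_cohort(cfg)


def intervals_from_truth(truth):
    iv = truth.spells.rename(columns={"gap_days": "t_stop"}).assign(t_start=0.0)
    iv["weight_kg"] = iv["seal_id"].map(truth.weights)
    return iv
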