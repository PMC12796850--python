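"""End-to-end orchestration: events -> jurisdictions -> survival -> network.

``run_pipeline`` executes the full analysis from a :class:`RunConfig` and
writes a report bundle: a per-seal haul-out summary, Kaplan-Meier curve
data, fixed-effects and frailty Cox coefficient tables, the node/edge
tables of the spatial network (plus GraphML), and a structured run log with
per-stage record counts, the seed and the convention choices, so every
number in the report traces back to a stage output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev_mod
from . import jurisdictions as jur
from . import network as net
from . import survival as surv
from ._validation import ParseError

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name and offending context."""

    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Paths, thresholds and conventions for one pipeline run.

    Threshold defaults are the sensor/processing rules of the analysis:
    10 min minimum dry, 40 s wet termination, 10 min merge gap, 10 days
    minimum track span, 10 km node clustering.
    """

    telemetry: str | None = None          # events CSV or sensor CSV
    boundaries: str | None = None         # GeoJSON FeatureCollection
    seal_metadata: str | None = None      # optional per-seal CSV
    edge_table: str | None = None         # optional printed edge list
    output_dir: str = "hauloutnet_run"
    min_dry: str = "10min"
    end_wet: str = "40s"
    merge_gap: str = "10min"
    min_track_days: float = 10.0
    cluster_km: float = 10.0
    reference_level: str | None = None
    betweenness_cost: str = "inverse_dc_weight"
    betweenness_normalization: str = "pairs"
    fit_frailty: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def validate_inputs(config: RunConfig) -> list[str]:
    """Schema and sanity diagnostics for the configured inputs.

    Returns a list of non-fatal issue strings; raises ``ParseError`` /
    ``ConfigurationError`` on fatal problems (missing files, wrong columns,
    out-of-range coordinates with row numbers, unsorted timestamps).
    """
    issues = []
    if config.telemetry is not None:
        path = Path(config.telemetry)
        if not path.exists():
            raise ConfigurationError(f"telemetry file not found: {path}")
        df = pd.read_csv(path)
        if {"seal_id", "start", "end", "lon", "lat"} <= set(df.columns):
            bad = df.index[(df["lat"].abs() > 90) | (df["lon"].abs() > 180)]
            if len(bad):
                raise ParseError(
                    f"coordinates out of range (lon/lat swapped?) at rows {list(bad[:10])}")
            for sid, grp in df.groupby("seal_id"):
                starts = pd.to_datetime(grp["start"])
                if not starts.is_monotonic_increasing:
                    issues.append(f"seal {sid}: event start times not sorted (will be sorted)")
                dup = int(starts.duplicated().sum())
                if dup:
                    issues.append(f"seal {sid}: {dup} duplicate start timestamp(s)")
        elif {"seal_id", "timestamp", "state"} <= set(df.columns):
            bad_states = set(df["state"].unique()) - {"wet", "dry"}
            if bad_states:
                raise ParseError(f"unknown sensor states {sorted(bad_states)}")
            for sid, grp in df.groupby("seal_id"):
                ts = pd.to_datetime(grp["timestamp"])
                dup = int(ts.duplicated().sum())
                if dup:
                    issues.append(f"seal {sid}: {dup} duplicate sensor timestamp(s)")
        else:
            raise ParseError(
                "telemetry CSV must have columns (seal_id, start, end, lon, lat) "
                f"or (seal_id, timestamp, state); found {list(df.columns)}")
    if config.boundaries is not None:
        path = Path(config.boundaries)
        if not path.exists():
            raise ConfigurationError(f"boundary file not found: {path}")
        jur.ManagementUnitMap.from_geojson(path)
    if config.edge_table is not None:
        path = Path(config.edge_table)
        if not path.exists():
            raise ConfigurationError(f"edge table not found: {path}")
        tab = pd.read_csv(path)
        need = {"node_u", "node_v", "distance_km", "occupancy", "density"}
        if not need <= set(tab.columns):
            raise ParseError(f"edge table needs columns {sorted(need)}")
    return issues


def _write_cox(model, path: Path, reference: str) -> None:
    out = {
        "reference_level": reference,
        "coefficients": model.summary().reset_index(names="term").to_dict(orient="records"),
        "log_partial_likelihood": model.loglik_,
        "n_events": model.n_events_,
        "n_iterations": model.n_iter_,
    }
    if hasattr(model, "frailty_variance_"):
        out["frailty_variance"] = model.frailty_variance_
        out["random_effects"] = {str(k): float(v)
                                 for k, v in model.random_effects_.items()}
        out["marginal_loglik"] = model.marginal_loglik_
        out["notes"] = getattr(model, "notes_", [])
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, default=float)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns a dict of the in-memory stage products (events, tracks, risk
    intervals, fitted models, network) keyed by stage name.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "config": {k: str(v) for k, v in asdict(config).items()},
                 "stages": {}}
    products: dict = {}

    issues = validate_inputs(config)
    log["validation_issues"] = issues

    # ---- events stage ------------------------------------------------
    events = None
    if config.telemetry is not None:
        try:
            df = pd.read_csv(config.telemetry)
            if "state" in df.columns:
                records = ev_mod.read_sensor_csv(config.telemetry)
                events = ev_mod.detect_haulouts(records, config.min_dry, config.end_wet)
            else:
                events = ev_mod.read_events_csv(config.telemetry)
            n_raw = len(events)
            events = ev_mod.merge_events(events, config.merge_gap)
            log["stages"]["events"] = {"raw_events": n_raw, "merged_events": len(events),
                                       "n_merged_away": n_raw - len(events)}
            events.to_csv(out_dir / "events.csv", index=False)
        except Exception as exc:
            raise StageError("events", exc) from exc
        products["events"] = events

    seals = None
    if config.seal_metadata is not None:
        seals = pd.read_csv(config.seal_metadata)
        seals["seal_id"] = seals["seal_id"].astype(str)
        for col in ("first_record", "last_record"):
            if col in seals.columns:
                seals[col] = pd.to_datetime(seals[col], utc=True)

    # ---- jurisdictions + survival ------------------------------------
    if events is not None and config.boundaries is not None:
        try:
            unit_map = jur.ManagementUnitMap.from_geojson(config.boundaries)
            labelled = jur.assign_units(events, unit_map)
            labelled = jur.flag_cross_boundary(labelled)
            labelled.to_csv(out_dir / "labelled_events.csv", index=False)
            tracks = ev_mod.tracks_from_frames(labelled, seals)
            n_before = len(tracks)
            tracks = ev_mod.filter_tracks(tracks, config.min_track_days)
            log["stages"]["jurisdictions"] = {
                "tracks_in": n_before, "tracks_kept": len(tracks),
                "unassigned_events": int((labelled["unit"] == jur.UNASSIGNED).sum()),
            }
            per_seal, cohort = ev_mod.summarize_tracks(tracks)
            per_seal.to_csv(out_dir / "track_summary.csv", index=False)
            cohort.to_csv(out_dir / "cohort_summary.csv", index=False)
            products["tracks"] = tracks

            intervals = jur.cohort_risk_intervals(tracks)
            intervals.to_csv(out_dir / "risk_intervals.csv", index=False)
            products["risk_intervals"] = intervals
        except StageError:
            raise
        except Exception as exc:
            raise StageError("jurisdictions", exc) from exc

        try:
            reference = config.reference_level or surv.pick_reference(intervals)
            curves = surv.km_fit(intervals, "unit")
            pd.concat([c.as_frame() for c in curves.values()],
                      ignore_index=True).to_csv(out_dir / "km_curves.csv", index=False)
            products["km_curves"] = curves
            log["stages"]["survival"] = {
                "n_intervals": len(intervals), "n_crossings": int(intervals["event"].sum()),
                "reference_level": reference,
                "median_survival_days": {k: surv.median_survival(c)
                                         for k, c in curves.items()},
            }
            try:
                fixed = surv.cox_fixed(intervals, reference)
                _write_cox(fixed, out_dir / "cox_fixed.json", reference)
                products["cox_fixed"] = fixed
            except (surv.DegeneracyError, ValueError) as exc:
                logger.warning("fixed-effects Cox fit skipped: %s", exc)
                log["stages"]["survival"]["cox_fixed_skipped"] = str(exc)
            if config.fit_frailty and "cox_fixed" in products:
                frail = surv.cox_frailty(intervals, reference)
                _write_cox(frail, out_dir / "cox_frailty.json", reference)
                products["cox_frailty"] = frail
                log["stages"]["survival"]["frailty_variance"] = frail.frailty_variance_
        except StageError:
            raise
        except Exception as exc:
            raise StageError("survival", exc) from exc

    # ---- network stage -----------------------------------------------
    try:
        network = None
        if config.edge_table is not None:
            edges = pd.read_csv(config.edge_table)
            network = net.network_from_edge_table(
                edges, cost=config.betweenness_cost,
                normalization=config.betweenness_normalization)
        elif events is not None:
            network = net.build_network(
                events, threshold_km=config.cluster_km,
                cost=config.betweenness_cost,
                normalization=config.betweenness_normalization)
        if network is not None:
            network.edges.to_csv(out_dir / "network_edges.csv", index=False)
            network.nodes.to_csv(out_dir / "network_nodes.csv", index=False)
            network.to_graphml(out_dir / "network.graphml")
            log["stages"]["network"] = {
                "n_nodes": int(network.graph.number_of_nodes()),
                "n_edges": int(network.graph.number_of_edges()),
                **{k: str(v) for k, v in network.metadata.items()},
            }
            products["network"] = network
    except Exception as exc:
        raise StageError("network", exc) from exc

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    products["log"] = log
    return products
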