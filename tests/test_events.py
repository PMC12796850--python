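"""Sensor-rule haul-out detection, merging and track summaries."""

import numpy as np
import pandas as pd
import pytest

import hauloutnet as hn
from hauloutnet._validation import OrderingError, ParseError

from conftest import T0, make_events, make_sensor


class TestDetection:
    @pytest.mark.parametrize("segments, expected", [
        # dry run of 9 min bounded by wet: below threshold, no event
        ([("wet", "5min"), ("dry", "9min"), ("wet", "5min")], []),
        # exactly 10 min dry then 40 s wet: one event of exactly 10 min
        ([("wet", "5min"), ("dry", "10min"), ("wet", "40s"), ("wet", "5min")],
         [("5min", "15min")]),
        # 20 s wet blip absorbed; 60 s wet terminates: single 30 min 20 s event
        ([("wet", "5min"), ("dry", "15min"), ("wet", "20s"), ("dry", "15min"),
          ("wet", "60s"), ("wet", "5min")],
         [("5min", "35min20s")]),
        # two separate events split by a 2 min wet run
        ([("wet", "1min"), ("dry", "12min"), ("wet", "2min"), ("dry", "11min"),
          ("wet", "2min")],
         [("1min", "13min"), ("15min", "26min")]),
    ])
    def test_threshold_rules(self, segments, expected):
        out = hn.detect_haulouts(make_sensor("s1", segments))
        assert len(out) == len(expected)
        for (_, row), (s, e) in zip(out.iterrows(), expected):
            assert row["start"] == T0 + pd.Timedelta(s)
            assert row["end"] == T0 + pd.Timedelta(e)

    def test_short_dry_blip_before_event_absorbed_only_if_qualifying(self):
        # 5 min dry, 60 s wet, 10 min dry: only the second run is an event
        segs = [("wet", "1min"), ("dry", "5min"), ("wet", "60s"), ("dry", "10min"),
                ("wet", "2min")]
        out = hn.detect_haulouts(make_sensor("s1", segs))
        assert len(out) == 1
        assert out["start"].iloc[0] == T0 + pd.Timedelta("7min")

    def test_unsorted_records_raise(self):
        rec = make_sensor("s1", [("dry", "20min"), ("wet", "2min")])
        rec = rec.iloc[::-1].reset_index(drop=True)
        with pytest.raises(OrderingError):
            hn.detect_haulouts(rec)

    def test_unknown_state_raises(self):
        rec = make_sensor("s1", [("dry", "20min")])
        rec.loc[0, "state"] = "damp"
        with pytest.raises(ParseError):
            hn.detect_haulouts(rec)

    def test_duplicate_timestamps_kept_first(self, caplog):
        rec = make_sensor("s1", [("wet", "1min"), ("dry", "15min"), ("wet", "2min")])
        dup = rec.iloc[[3]]
        rec = pd.concat([rec, dup]).sort_values("timestamp", kind="stable")
        out = hn.detect_haulouts(rec)
        assert len(out) == 1


class TestMerging:
    def test_gap_below_threshold_merges(self):
        ev = make_events("s1", [("0h", "1h"), ("1h9min", "2h")])
        out = hn.merge_events(ev)
        assert len(out) == 1
        assert out["start"].iloc[0] == T0
        assert out["end"].iloc[0] == T0 + pd.Timedelta("2h")

    def test_gap_at_threshold_not_merged(self):
        ev = make_events("s1", [("0h", "1h"), ("1h10min", "2h")])
        assert len(hn.merge_events(ev)) == 2

    def test_transitive_merge(self):
        ev = make_events("s1", [("0h", "1h"), ("1h5min", "2h"), ("2h5min", "3h")])
        out = hn.merge_events(ev)
        assert len(out) == 1
        assert out["end"].iloc[0] == T0 + pd.Timedelta("3h")

    def test_idempotent_and_duration_conserved(self):
        rng = np.random.default_rng(0)
        t = 0.0
        iv = []
        for _ in range(30):
            t += rng.exponential(0.4)
            d = rng.exponential(1.5)
            iv.append((pd.Timedelta(hours=t), pd.Timedelta(hours=t + d)))
            t += d
        ev = make_events("s1", iv)
        once = hn.merge_events(ev)
        twice = hn.merge_events(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once["duration_h"].sum() >= ev["duration_h"].sum() - 1e-9

    def test_merge_properties_hold_for_arbitrary_gap_structures(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, derandomize=True, deadline=None)
        @given(st.lists(st.tuples(st.floats(0.01, 5.0), st.floats(0.02, 4.0)),
                        min_size=1, max_size=25))
        def check(gaps_durs):
            t = 0.0
            iv = []
            for gap, dur in gaps_durs:
                t += gap
                iv.append((pd.Timedelta(hours=t), pd.Timedelta(hours=t + dur)))
                t += dur
            ev = make_events("s1", iv)
            out = hn.merge_events(ev)
            # no remaining gap below the threshold
            gaps = (out["start"].iloc[1:].to_numpy()
                    - out["end"].iloc[:-1].to_numpy()) / np.timedelta64(1, "m")
            assert (gaps >= 10.0).all()
            # total dry time never decreases; span preserved
            assert out["duration_h"].sum() >= ev["duration_h"].sum() - 1e-9
            assert out["start"].iloc[0] == ev["start"].iloc[0]
            assert out["end"].iloc[-1] == ev["end"].iloc[-1]
            pd.testing.assert_frame_equal(out, hn.merge_events(out))

        check()

    def test_merged_location_from_longest_constituent(self):
        ev = make_events("s1", [("0h", "30min"), ("35min", "3h")],
                         lon=[10.0, 11.0], lat=[59.0, 58.0])
        out = hn.merge_events(ev)
        assert out["lon"].iloc[0] == 11.0 and out["lat"].iloc[0] == 58.0

    def test_overlap_raises(self):
        ev = make_events("s1", [("0h", "2h"), ("1h", "3h")])
        with pytest.raises(ValueError, match="overlap"):
            hn.merge_events(ev)


class TestTrackFilter:
    def _track(self, sid, days):
        tr = hn.SealTrack(seal_id=sid, first_record=T0,
                          last_record=T0 + pd.Timedelta(days=days))
        return tr

    def test_threshold_boundary_inclusive(self):
        tracks = [self._track("a", 3), self._track("b", 9.9),
                  self._track("c", 10.0), self._track("d", 10.1)]
        kept = hn.filter_tracks(tracks)
        assert [t.seal_id for t in kept] == ["c", "d"]

    def test_cohort_removal_count(self):
        tracks = [self._track(f"s{i}", 12) for i in range(26)]
        tracks += [self._track("x1", 4), self._track("x2", 8)]
        assert len(hn.filter_tracks(tracks)) == 26


class TestSummaries:
    def test_zero_displacement_and_mean_duration(self):
        ev = make_events("s1", [("0h", "2h"), ("12h", "16h")], lon=10.0, lat=59.0)
        tr = hn.SealTrack("s1", tagging_lon=10.0, tagging_lat=59.0,
                          first_record=T0, last_record=T0 + pd.Timedelta(days=20),
                          events=ev)
        per_seal, cohort = hn.summarize_tracks([tr])
        row = per_seal.iloc[0]
        assert row["max_displacement_km"] == pytest.approx(0.0)
        assert row["mean_duration_h"] == pytest.approx(3.0)
        assert row["n_haulouts"] == 2
        assert row["deployment_days"] == pytest.approx(20.0)

    def test_matches_generator_bookkeeping(self, small_cohort):
        events, seals, truth = small_cohort
        tracks = hn.tracks_from_frames(events, seals)
        per_seal, _ = hn.summarize_tracks(tracks)
        counts = dict(zip(per_seal["seal_id"], per_seal["n_haulouts"]))
        active = {k: v for k, v in truth.n_events.items() if v > 0}
        assert counts == active

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hn.summarize_tracks([])


class TestRoundTrip:
    def test_sensor_emission_inverts_detection(self, small_cohort):
        events, _, _ = small_cohort
        one = events[events["seal_id"] == "seal_001"].reset_index(drop=True)
        rec = hn.emit_sensor_stream(one)
        back = hn.detect_haulouts(rec)
        assert len(back) == len(one)
        assert (back["start"].to_numpy() == one["start"].to_numpy()).all()
        assert (back["end"].to_numpy() == one["end"].to_numpy()).all()
        assert np.allclose(back["lon"], one["lon"])

    def test_round_trip_with_noise_blips(self, small_cohort):
        events, _, _ = small_cohort
        one = events[events["seal_id"] == "seal_002"].reset_index(drop=True)
        rng = np.random.default_rng(1)
        rec = hn.emit_sensor_stream(one, noise_prob=0.8, rng=rng)
        back = hn.detect_haulouts(rec)
        assert len(back) == len(one)
        assert (back["start"].to_numpy() == one["start"].to_numpy()).all()
        assert (back["end"].to_numpy() == one["end"].to_numpy()).all()
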