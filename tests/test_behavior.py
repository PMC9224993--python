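"""Behavior classifiers: published thresholds, recovery, and bout algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defensetrack import (
    ClassifierParams,
    bout_robustness,
    compute_kinematics,
    detect_freezing,
    detect_runs,
    detect_sap,
    percent_time_freezing,
    postprocess_bouts,
)
from defensetrack.behavior import BOUT_COLUMNS
from defensetrack.pose import KinematicsSeries

from conftest import make_track


def kin_from_speeds(head_speed, tail_speed=None, nt_dist=None, body_len=7.0, fps=30.0,
                    signed_v=None):
    n = len(head_speed)
    return KinematicsSeries(
        timestamps_s=np.arange(n) / fps,
        head_xy_cm=np.zeros((n, 2)),
        head_speed_cms=np.asarray(head_speed, float),
        tailbase_speed_cms=np.asarray(tail_speed if tail_speed is not None else head_speed, float),
        nose_tail_distance_cm=np.asarray(
            nt_dist if nt_dist is not None else np.full(n, body_len), float
        ),
        body_length_cm=body_len,
        signed_velocity_to_threat_cms=(
            np.asarray(signed_v, float) if signed_v is not None else None
        ),
    )


class TestFreezing:
    def test_fully_immobile_session_is_one_bout(self):
        kin = kin_from_speeds(np.zeros(300))  # 10 s at 30 fps
        bouts = detect_freezing(kin)
        assert len(bouts) == 1
        assert bouts.loc[0, "start_s"] == 0.0
        assert bouts.loc[0, "end_s"] == pytest.approx(10.0)
        assert percent_time_freezing(kin) == pytest.approx(100.0)

    def test_bout_below_minimum_duration_excluded(self):
        # 9 frames at 30 fps = 0.30 s, below the 0.33 s minimum
        speeds = np.ones(60)
        speeds[20:29] = 0.0
        assert len(detect_freezing(kin_from_speeds(speeds))) == 0
        # 10 frames = 0.333 s passes
        speeds[20:30] = 0.0
        assert len(detect_freezing(kin_from_speeds(speeds))) == 1

    def test_both_bodyparts_must_be_slow(self):
        head = np.zeros(60)
        tail = np.full(60, 1.0)  # tailbase keeps moving
        assert len(detect_freezing(kin_from_speeds(head, tail))) == 0

    def test_raising_threshold_never_decreases_percent_freezing(self, corridor_kin):
        pcts = [
            percent_time_freezing(
                corridor_kin, ClassifierParams(freeze_speed_max_cms=thr)
            )
            for thr in (0.1, 0.25, 0.5, 1.0, 2.0)
        ]
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_freezing(kin_from_speeds(np.array([])))


class TestSap:
    def test_distance_at_body_length_is_not_sap(self):
        kin = kin_from_speeds(np.zeros(60), nt_dist=np.full(60, 7.0))
        assert len(detect_sap(kin)) == 0

    def test_stretched_slow_posture_is_one_sap(self):
        # 1.3 body lengths with 0.5 cm/s tailbase for 1 s
        nt = np.full(90, 7.0)
        nt[30:60] = 1.3 * 7.0
        kin = kin_from_speeds(np.full(90, 0.5), nt_dist=nt)
        bouts = detect_sap(kin)
        assert len(bouts) == 1
        assert bouts.loc[0, "duration_s"] == pytest.approx(1.0)

    def test_fast_tailbase_vetoes_sap(self):
        nt = np.full(60, 1.3 * 7.0)
        kin = kin_from_speeds(np.full(60, 2.0), nt_dist=nt)  # tail 2 cm/s > 1
        assert len(detect_sap(kin)) == 0


class TestRuns:
    def test_stationary_mouse_has_no_runs(self):
        kin = kin_from_speeds(np.zeros(60), signed_v=np.zeros(60))
        assert len(detect_runs(kin)) == 0

    def test_slow_retreat_below_threshold_is_not_escape(self):
        kin = kin_from_speeds(np.full(60, 2.0), signed_v=np.full(60, -2.0))
        assert len(detect_runs(kin)) == 0

    def test_time_reversal_swaps_approach_and_escape(self, corridor_bundle):
        track = corridor_bundle.pose
        df = track.data.iloc[::-1].reset_index(drop=True)
        df["timestamp_s"] = track.data["timestamp_s"].to_numpy()
        df["frame"] = track.data["frame"].to_numpy()
        from defensetrack.pose import PoseTrack

        fwd = detect_runs(
            compute_kinematics(track, 1, threat_point=corridor_bundle.zonemap.threat_point)
        )
        rev = detect_runs(
            compute_kinematics(
                PoseTrack(df), 1, threat_point=corridor_bundle.zonemap.threat_point
            )
        )
        assert (fwd.label == "approach").sum() == (rev.label == "escape").sum()
        assert (fwd.label == "escape").sum() == (rev.label == "approach").sum()

    def test_missing_threat_point_rejected(self):
        with pytest.raises(ValueError, match="threat point"):
            detect_runs(kin_from_speeds(np.zeros(10)))


class TestGroundTruthRecovery:
    @pytest.mark.parametrize("label,detect", [
        ("freeze", detect_freezing),
        ("sap", detect_sap),
    ])
    def test_planted_bouts_recovered(self, corridor_bundle, corridor_kin, label, detect):
        planted = corridor_bundle.ground_truth.intervals(label)
        got = detect(corridor_kin)
        assert len(got) == len(planted)
        dt = corridor_kin.frame_period_s
        for (_, row), (s, e) in zip(got.iterrows(), planted):
            assert abs(row.start_s - s) <= dt + 1e-9
            assert abs(row.end_s - e) <= dt + 1e-9

    @pytest.mark.parametrize("label", ["approach", "escape"])
    def test_planted_runs_recovered(self, corridor_bundle, corridor_kin, label):
        planted = corridor_bundle.ground_truth.intervals(label)
        got = detect_runs(corridor_kin)
        got = got[got.label == label].reset_index(drop=True)
        assert len(got) == len(planted)
        dt = corridor_kin.frame_period_s
        for (_, row), (s, e) in zip(got.iterrows(), planted):
            assert abs(row.start_s - s) <= dt + 1e-9
            assert abs(row.end_s - e) <= dt + 1e-9

    def test_all_bouts_inside_session(self, corridor_kin):
        for det in (detect_freezing, detect_sap, detect_runs):
            bouts = det(corridor_kin)
            if len(bouts):
                assert bouts.start_s.min() >= corridor_kin.timestamps_s[0]
                assert bouts.end_s.max() <= (
                    corridor_kin.timestamps_s[-1] + corridor_kin.frame_period_s + 1e-9
                )


def brute_force_merge(intervals, gap, min_dur):
    """Interval-union oracle for postprocess_bouts."""
    out = []
    for s, e in sorted(intervals):
        if out and s - out[-1][1] < gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out if e - s >= min_dur - 1e-9]


class TestPostprocess:
    @staticmethod
    def to_bouts(intervals, label="freeze"):
        rows = [
            {"label": label, "start_s": s, "end_s": e, "duration_s": e - s,
             "mean_speed_cms": 0.0, "peak_speed_cms": 0.0}
            for s, e in intervals
        ]
        return pd.DataFrame(rows, columns=BOUT_COLUMNS)

    def test_zero_gap_is_identity(self):
        bouts = self.to_bouts([(0.0, 1.0), (2.0, 3.0)])
        out = postprocess_bouts(bouts, merge_gap_s=0.0)
        pd.testing.assert_frame_equal(out, bouts)

    def test_nearby_bouts_merged(self):
        bouts = self.to_bouts([(0.0, 1.0), (1.1, 2.0)])
        out = postprocess_bouts(bouts, merge_gap_s=0.2)
        assert len(out) == 1
        assert out.loc[0, "end_s"] == 2.0

    def test_idempotent(self):
        bouts = self.to_bouts([(0.0, 1.0), (1.1, 2.0), (5.0, 5.05)])
        once = postprocess_bouts(bouts, 0.2, 0.1)
        twice = postprocess_bouts(once, 0.2, 0.1)
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            postprocess_bouts(self.to_bouts([(0, 1)]), merge_gap_s=-1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0), st.floats(0.0, 0.5))
    def test_matches_interval_union_oracle(self, seed, gap, min_dur):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.uniform(0, 30, rng.integers(1, 12)))
        intervals = []
        last = 0.0
        for s in starts:
            s = max(s, last)
            e = s + rng.uniform(0.05, 2.0)
            intervals.append((s, e))
            last = e + 1e-6
        out = postprocess_bouts(self.to_bouts(intervals), gap, min_dur)
        oracle = brute_force_merge(intervals, gap, min_dur)
        assert len(out) == len(oracle)
        for (_, row), (s, e) in zip(out.iterrows(), oracle):
            assert row.start_s == pytest.approx(s)
            assert row.end_s == pytest.approx(e)


class TestBoutRobustness:
    def test_identical_vectors_give_perfect_correlation(self):
        # every bout longer than 1 s => both settings agree exactly
        kins = []
        rng = np.random.default_rng(0)
        for _ in range(5):
            speeds = np.ones(1800)
            for s in rng.integers(0, 1500, 4):
                speeds[s : s + 60] = 0.0  # 2-s freezes
            kins.append(kin_from_speeds(speeds))
        res = bout_robustness(kins)
        assert res["r"] == pytest.approx(1.0)

    def test_all_short_bouts_reports_diagnostic(self):
        kins = []
        for k in range(3):
            speeds = np.ones(900)
            speeds[100 : 100 + 15 + k] = 0.0  # ~0.5-s freezes only
            kins.append(kin_from_speeds(speeds))
        res = bout_robustness(kins)
        assert np.isnan(res["r"])
        assert "undefined" in res["diagnostic"]

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            bout_robustness([kin_from_speeds(np.ones(100))] * 2)
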