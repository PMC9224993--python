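"""Assay scoring: occupancy, entries, latencies, preferences, epoch contrasts."""

import numpy as np
import pandas as pd
import pytest

from defensetrack import (
    burrow_preference,
    compute_kinematics,
    count_entries,
    epoch_metrics,
    lte_contrast,
    make_zonemap,
    rtpt_preference,
    score_lte_trial,
    threat_distance,
    zone_occupancy,
)
from defensetrack.metrics import CalibrationError, NO_ENTRY_LATENCY_S
from defensetrack.schedule import EpochSchedule, make_lte_trials
from defensetrack.synth import (
    SimConfig,
    simulate_habituation,
    simulate_lte_trial,
    simulate_rtpt_session,
    simulate_session,
)

from conftest import make_track


def static_kin(xy, n=300, fps=30.0):
    return compute_kinematics(make_track(np.tile(np.asarray(xy, float), (n, 1))), 1)


class TestZoneOccupancy:
    def test_mouse_never_leaving_center(self):
        zm = make_zonemap("open_field")
        kin = static_kin([17.0, 17.0], n=300)
        occ = zone_occupancy(kin, zm)
        assert occ.loc["center", "seconds"] == pytest.approx(10.0)
        assert occ.loc["corner_sw", "seconds"] == 0.0

    def test_boundary_point_counts_inside(self):
        zm = make_zonemap("open_field")
        occ = zone_occupancy(static_kin([8.5, 8.5]), zm)  # on corner-zone edge
        assert occ.loc["corner_sw", "fraction"] == pytest.approx(1.0)

    def test_disjoint_fractions_sum_below_one(self, openfield_bundle):
        kin = compute_kinematics(openfield_bundle.pose, 1)
        zm = openfield_bundle.zonemap
        corners = [z for z in zm.zone_names() if z.startswith("corner_")]
        occ = zone_occupancy(kin, zm, corners)
        assert occ["fraction"].sum() <= 1.0 + 1e-9

    def test_simulated_occupancy_matches_ground_truth(self, openfield_bundle):
        kin = compute_kinematics(openfield_bundle.pose, 1)
        occ = zone_occupancy(kin, openfield_bundle.zonemap)
        dt = kin.frame_period_s
        for z, sec in openfield_bundle.ground_truth.zone_occupancy_s.items():
            assert abs(occ.loc[z, "seconds"] - sec) <= dt + 1e-9

    def test_out_of_arena_trajectory_flagged(self):
        zm = make_zonemap("open_field")
        with pytest.raises(CalibrationError):
            zone_occupancy(static_kin([100.0, 100.0]), zm)


class TestEntries:
    def test_never_entering_zone(self):
        zm = make_zonemap("open_field")
        count, _ = count_entries(static_kin([17.0, 17.0]), zm, "corner_sw")
        assert count == 0

    def test_constructed_crossings_counted_exactly(self):
        zm = make_zonemap("open_field")
        # oscillate between center and the SW corner zone: 6 entries
        inside, outside = np.array([4.0, 4.0]), np.array([17.0, 17.0])
        frames = []
        for _ in range(6):
            frames += [outside] * 15 + [inside] * 15
        kin = compute_kinematics(make_track(np.array(frames)), 1)
        count, times = count_entries(kin, zm, "corner_sw", min_entry_dur_s=0.2)
        assert count == 6
        assert len(times) == 6

    def test_single_frame_graze_debounced(self):
        zm = make_zonemap("open_field")
        frames = [[17.0, 17.0]] * 10 + [[4.0, 4.0]] + [[17.0, 17.0]] * 10
        kin = compute_kinematics(make_track(np.array(frames)), 1)
        count, _ = count_entries(kin, zm, "corner_sw", min_entry_dur_s=0.2)
        assert count == 0


class TestThreatDistance:
    def test_corridor_geometry(self):
        zm = make_zonemap("corridor")
        _, mean_far = threat_distance(static_kin([0.0, 12.5]), zm)
        assert mean_far == pytest.approx(70.0)
        _, mean_mid = threat_distance(static_kin([35.0, 12.5]), zm)
        assert mean_mid == pytest.approx(35.0)

    def test_matches_direct_recomputation(self, corridor_bundle, corridor_kin):
        series, _ = threat_distance(corridor_kin, corridor_bundle.zonemap)
        oracle = np.hypot(
            corridor_kin.head_xy_cm[:, 0] - 70.0, corridor_kin.head_xy_cm[:, 1] - 12.5
        )
        np.testing.assert_allclose(series, oracle, atol=1e-9)

    def test_missing_rat_wall(self):
        with pytest.raises(ValueError, match="rat wall"):
            threat_distance(static_kin([17.0, 17.0]), make_zonemap("open_field"))


class TestLteScoring:
    def test_planted_entry_recovered(self):
        pose, zm, _ = simulate_lte_trial(12.4, seed=2)
        lat = score_lte_trial(compute_kinematics(pose, 1), zm)
        assert lat == pytest.approx(12.4, abs=1 / 30 + 1e-9)

    def test_no_entry_scores_61(self):
        pose, zm, _ = simulate_lte_trial(None, seed=3)
        assert score_lte_trial(compute_kinematics(pose, 1), zm) == NO_ENTRY_LATENCY_S

    def test_entry_on_first_frame_scores_one_frame(self):
        # mouse already at the burrow when the barrier lifts
        zm = make_zonemap("lte")
        path = np.tile([6.0, 3.5], (1830, 1))
        kin = compute_kinematics(make_track(path), 1)
        assert score_lte_trial(kin, zm) == pytest.approx(1 / 30.0)

    def test_truncated_segment_rejected(self):
        zm = make_zonemap("lte")
        kin = static_kin([30.0, 30.0], n=300)  # 10 s only, no entry
        with pytest.raises(ValueError, match="trial limit"):
            score_lte_trial(kin, zm)

    def test_latency_bounds(self):
        for seed in range(3):
            pose, zm, planted = simulate_lte_trial(5.0 + 10 * seed, seed=seed)
            lat = score_lte_trial(compute_kinematics(pose, 1), zm)
            assert 1 / 30.0 <= lat <= NO_ENTRY_LATENCY_S


class TestLteContrast:
    @staticmethod
    def trials_with(on, off):
        t = make_lte_trials(list(np.arange(10) * 90.0))
        lat = np.empty(10)
        lat[t.laser_on.to_numpy()] = on
        lat[~t.laser_on.to_numpy()] = off
        t["latency_s"] = lat
        return t

    def test_identical_latencies_contrast_zero(self):
        assert lte_contrast(self.trials_with(15.0, 15.0)) == 0.0

    def test_on_minus_off_arithmetic(self):
        assert lte_contrast(self.trials_with(10.0, 20.0)) == pytest.approx(-10.0)

    def test_antisymmetric_under_label_swap(self):
        t = self.trials_with(10.0, 20.0)
        swapped = t.copy()
        swapped["laser_on"] = ~swapped["laser_on"]
        assert lte_contrast(t) == pytest.approx(-lte_contrast(swapped))

    def test_unbalanced_trials_rejected(self):
        t = self.trials_with(10.0, 20.0).iloc[:9]
        with pytest.raises(ValueError, match="unbalanced"):
            lte_contrast(t)


class TestBurrowPreference:
    def test_always_in_burrow(self):
        zm = make_zonemap("lte")
        prefers, _ = burrow_preference(static_kin([6.0, 3.5], n=600), zm)
        assert prefers

    def test_tie_fails_strict_inequality(self):
        zm = make_zonemap("lte")
        # equal time in burrow and one corner
        frames = [[6.0, 3.5]] * 150 + [[42.0, 4.0]] * 150
        kin = compute_kinematics(make_track(np.array(frames)), 1)
        prefers, occ = burrow_preference(kin, zm)
        assert occ.loc["burrow", "seconds"] == occ.loc["corner_se", "seconds"]
        assert not prefers

    @pytest.mark.parametrize("planted", [True, False])
    def test_planted_preference_recovered(self, planted):
        bundle, _ = simulate_habituation(planted, seed=4 if planted else 5)
        kin = compute_kinematics(bundle.pose, 1)
        prefers, _ = burrow_preference(kin, bundle.zonemap)
        assert prefers is planted


class TestRtpt:
    def test_identical_sessions_zero(self):
        zm = make_zonemap("rtpt")
        kin = static_kin([10.0, 10.0], n=300)
        assert rtpt_preference(kin, kin, zm) == 0.0

    def test_arithmetic(self):
        zm = make_zonemap("rtpt")
        pre = compute_kinematics(
            make_track(np.array([[10.0, 10.0]] * 9000 + [[30.0, 10.0]] * 9000)), 1
        )
        test = compute_kinematics(
            make_track(np.array([[10.0, 10.0]] * 6000 + [[30.0, 10.0]] * 12000)), 1
        )
        assert rtpt_preference(test, pre, zm) == pytest.approx(100.0, abs=0.1)

    def test_simulated_aversion_negative(self):
        pre, frac_pre = simulate_rtpt_session(0.6, seed=6, duration_s=300)
        post, frac_post = simulate_rtpt_session(0.2, seed=7, duration_s=300)
        kin_pre = compute_kinematics(pre.pose, 1)
        kin_post = compute_kinematics(post.pose, 1)
        val = rtpt_preference(kin_pre, kin_post, pre.zonemap)
        assert val < 0
        assert val == pytest.approx(300.0 * (frac_post - frac_pre), abs=1.0)

    def test_unknown_zone_rejected(self):
        zm = make_zonemap("rtpt")
        kin = static_kin([10.0, 10.0])
        with pytest.raises(KeyError):
            rtpt_preference(kin, kin, zm, zone="left_chamber")


class TestEpochMetrics:
    @staticmethod
    def alternating_schedule(epoch_s, n):
        rows = [
            {"condition": ["OFF", "ON"][i % 2], "start_s": i * epoch_s, "end_s": (i + 1) * epoch_s}
            for i in range(n)
        ]
        return EpochSchedule(pd.DataFrame(rows))

    def test_identical_conditions_zero_contrast(self):
        # constant motion: every metric equal across ON and OFF
        xs = np.column_stack([np.linspace(5, 25, 3600), np.full(3600, 17.0)])
        kin = compute_kinematics(make_track(np.vstack([xs, xs[::-1]])), 1)
        zm = make_zonemap("open_field")
        from defensetrack.behavior import detect_freezing

        bouts = detect_freezing(kin)
        sched = self.alternating_schedule(120.0, 2)
        out = epoch_metrics(kin, bouts, sched, zm,
                            metrics=("mean_speed_cms", "pct_freezing"))
        assert abs(out.loc["mean_speed_cms", "contrast"]) < 0.05
        assert out.loc["pct_freezing", "contrast"] == 0.0

    def test_planted_on_only_freezing(self):
        # OFF epochs moving, ON epochs half-frozen: contrast = +50 points
        fps, epoch = 30, 60.0
        frames = []
        x = 10.0
        for ep in range(4):
            on = ep % 2 == 1
            for i in range(int(epoch * fps)):
                if on and i < epoch * fps / 2:
                    pass  # hold still
                else:
                    x += 6.0 / fps
                    if x > 28:
                        x = 10.0
                frames.append([x, 17.0])
        kin = compute_kinematics(make_track(np.array(frames)), 1)
        from defensetrack.behavior import detect_freezing

        bouts = detect_freezing(kin)
        out = epoch_metrics(kin, bouts, self.alternating_schedule(epoch, 4),
                            make_zonemap("open_field"), metrics=("pct_freezing",))
        assert out.loc["pct_freezing", "contrast"] == pytest.approx(50.0, abs=1.0)

    def test_single_epoch_equals_whole_session(self, corridor_bundle, corridor_kin):
        from defensetrack.behavior import detect_freezing

        bouts = detect_freezing(corridor_kin)
        dur = corridor_bundle.config.duration_s
        sched = EpochSchedule(pd.DataFrame(
            [{"condition": "ON", "start_s": 0.0, "end_s": dur}]
        ))
        out = epoch_metrics(corridor_kin, bouts, sched, corridor_bundle.zonemap,
                            metrics=("mean_speed_cms", "pct_freezing", "distance_traveled_cm"))
        from defensetrack.behavior import percent_time_freezing

        assert out.loc["pct_freezing", "ON"] == pytest.approx(
            percent_time_freezing(corridor_kin), abs=0.05
        )
        assert out.loc["mean_speed_cms", "ON"] == pytest.approx(
            np.average(corridor_kin.head_speed_cms), rel=1e-6
        )

    def test_fifth_epoch_excluded_by_head(self):
        # five 2-min epochs; only the first four are analyzed (EPM protocol)
        sched = self.alternating_schedule(120.0, 5)
        trimmed = sched.head(4)
        assert len(trimmed.intervals) == 4
        assert trimmed.intervals["end_s"].max() == 480.0

    def test_empty_condition_rejected(self, corridor_kin):
        sched = EpochSchedule(pd.DataFrame(
            [{"condition": "ON", "start_s": 5000.0, "end_s": 5010.0}]
        ))
        with pytest.raises(ValueError, match="covers no frames"):
            epoch_metrics(corridor_kin, pd.DataFrame(columns=["label", "start_s", "end_s"]),
                          sched, metrics=("mean_speed_cms",))
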