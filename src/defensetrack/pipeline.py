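"""End-to-end session pipeline and the replication-check suite.

:func:`run_session` drives simulate -> kinematics -> classify -> score ->
photometry -> analyze from a single YAML configuration, writes every stage
output as plain text, and emits a manifest with content digests so
deterministic stages can be verified to reproduce byte-identically.

:func:`run_replication_suite` re-derives the pipeline's reference numbers
(screening-fraction arithmetic, the no-entry latency convention, and the
minimum-bout robustness correlation) from scratch and reports a
machine-readable pass/fail per check.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .arenas import write_zonemap
from .behavior import ClassifierParams, bout_robustness, detect_freezing, detect_runs, detect_sap
from .events import spatial_bin_dff, zone_mean_dff
from .metrics import epoch_metrics, score_lte_trial
from .photometry import process_recording
from .pose import compute_kinematics, interpolate_low_confidence, write_pose_table
from .stats import cohort_screen_fraction
from .synth import SimConfig, freezing_robustness_cohort, simulate_lte_trial, simulate_session

__all__ = ["run_session", "run_replication_suite", "load_config"]

_SCHEMA = {
    "session": {"arena", "duration_s", "seed", "tuning_sign", "tuning_mask", "dropout_prob"},
    "kinematics": {"smoothing_window_frames", "likelihood_min"},
    "classify": {"freeze_speed_max_cms", "freeze_min_dur_s", "sap_stretch_factor",
                 "sap_tail_speed_max_cms", "run_speed_min_cms"},
    "photometry": {"method"},
    "output_dir": None,
}


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    for key in cfg:
        if key not in _SCHEMA:
            raise ValueError(f"unknown config section {key!r}")
        if _SCHEMA[key] is not None:
            bad = set(cfg[key] or {}) - _SCHEMA[key]
            if bad:
                raise ValueError(f"unknown fields {sorted(bad)} in section {key!r}")
    if "session" not in cfg or "output_dir" not in cfg:
        raise ValueError("config requires 'session' and 'output_dir' sections")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_session(config_path) -> dict:
    """Run the full pipeline for one (simulated) session; returns the manifest."""
    cfg = load_config(config_path)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    sess = cfg["session"]
    sim = SimConfig(
        arena_name=sess.get("arena", "corridor"),
        duration_s=float(sess.get("duration_s", 600.0)),
        seed=int(sess.get("seed", 0)),
        tuning_sign=int(sess.get("tuning_sign", 0)),
        tuning_mask=sess.get("tuning_mask", "all"),
        dropout_prob=float(sess.get("dropout_prob", 0.0)),
    )
    bundle = simulate_session(sim)

    write_pose_table(bundle.pose, out / "pose.csv")
    dio.write_photometry_csv(bundle.photometry, out / "photometry.csv")
    write_zonemap(bundle.zonemap, out / "zones.json")
    bundle.schedule.to_json(out / "schedule.json")
    dio.write_ground_truth_json(bundle.ground_truth, out / "ground_truth.json")

    kcfg = cfg.get("kinematics") or {}
    track = interpolate_low_confidence(bundle.pose, float(kcfg.get("likelihood_min", 0.9)))
    kin = compute_kinematics(
        track,
        int(kcfg.get("smoothing_window_frames", 5)),
        threat_point=bundle.zonemap.threat_point,
    )

    params = ClassifierParams(**(cfg.get("classify") or {}))
    bouts = [detect_freezing(kin, params), detect_sap(kin, params)]
    if bundle.zonemap.threat_point is not None:
        bouts.append(detect_runs(kin, params))
    bouts = pd.concat(bouts, ignore_index=True)
    dio.write_bouts_csv(bouts, out / "bouts.csv")

    summary = epoch_metrics(
        kin,
        bouts,
        bundle.schedule,
        bundle.zonemap,
        metrics=_metrics_for(sim.arena_name),
        params=params,
    )
    summary.to_csv(out / "session_summary.csv")

    pcfg = cfg.get("photometry") or {}
    series, per_frame = process_recording(
        bundle.photometry, kin.timestamps_s, method=pcfg.get("method", "ols")
    )
    pd.DataFrame(
        {"timestamp_s": series.timestamps_s, "dff": series.dff, "zdff": series.zdff}
    ).to_csv(out / "dff.csv", index=False)

    if sim.arena_name == "corridor":
        rows = []
        for label in ("approach", "escape"):
            try:
                tun = spatial_bin_dff(
                    per_frame, kin.head_xy_cm, kin.timestamps_s, bouts, bundle.zonemap, label
                )
                rows.append({"label": label, "r_bins": tun.r, "p_bins": tun.p})
            except ValueError:
                rows.append({"label": label, "r_bins": np.nan, "p_bins": np.nan})
        zd = zone_mean_dff(per_frame, kin.head_xy_cm, bundle.zonemap)
        pd.DataFrame(rows).to_csv(out / "spatial_tuning.csv", index=False)
        pd.DataFrame([zd]).to_csv(out / "zone_dff.csv", index=False)

    manifest = {
        "seed": sim.seed,
        "config": {k: (dict(v) if isinstance(v, dict) else v) for k, v in cfg.items()},
        "sim_config": {k: v for k, v in asdict(sim).items()
                       if not isinstance(v, dict)},
        "outputs": {p.name: _digest(p) for p in sorted(out.iterdir())
                    if p.suffix in (".csv", ".json") and p.name != "manifest.json"},
        "created_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _metrics_for(arena: str) -> tuple[str, ...]:
    if arena == "corridor":
        return ("mean_speed_cms", "pct_freezing", "threat_zone_time_s", "threat_distance_cm",
                "sap_count", "approach_count", "escape_count", "escape_velocity_cms",
                "distance_traveled_cm")
    if arena == "epm":
        return ("mean_speed_cms", "pct_freezing", "open_arm_pct", "distance_traveled_cm")
    if arena == "rtpt":
        return ("mean_speed_cms", "distance_traveled_cm")
    return ("mean_speed_cms", "pct_freezing", "corner_entries", "center_time_s",
            "corner_time_s", "distance_traveled_cm")


# ---------------------------------------------------------------------------
# replication checks


def _check_t1() -> dict:
    value = cohort_screen_fraction(63, 69)
    return {"check": "t1", "value": value, "expected": 91.3, "cmp": "eq",
            "passed": bool(abs(value - 91.3) < 0.05)}


def _check_t2(seed: int, n_sessions: int, duration_s: float) -> dict:
    bundles = freezing_robustness_cohort(n_sessions=n_sessions, duration_s=duration_s, seed=seed)
    kins = [compute_kinematics(b.pose, smoothing_window_frames=1) for b in bundles]
    r = bout_robustness(kins)["r"]
    return {"check": "t2", "value": float(r), "expected": 0.95, "cmp": "ge",
            "passed": bool(r >= 0.95), "n": n_sessions}


def _check_t3(seed: int) -> dict:
    pose, zm, _ = simulate_lte_trial(None, seed=seed)
    kin = compute_kinematics(pose, smoothing_window_frames=1)
    lat = score_lte_trial(kin, zm)
    return {"check": "t3", "value": float(lat), "expected": 61.0, "cmp": "eq",
            "passed": bool(lat == 61.0)}


def run_replication_suite(
    checks: list[str],
    seed: int = 0,
    n_sessions: int = 40,
    duration_s: float = 600.0,
) -> pd.DataFrame:
    """Recompute the named reference checks; returns one row per check."""
    rows = []
    for c in checks:
        if c == "t1":
            rows.append(_check_t1())
        elif c == "t2":
            rows.append(_check_t2(seed, n_sessions, duration_s))
        elif c == "t3":
            rows.append(_check_t3(seed))
        else:
            raise ValueError(f"unknown check id {c!r}")
    return pd.DataFrame(rows, columns=["check", "value", "expected", "cmp", "passed", "n"])
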