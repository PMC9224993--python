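"""Kinematic defensive-behavior classifiers and bout post-processing.

Four behaviors are defined purely from pose kinematics:

* **freeze** - head AND tailbase speed below 0.25 cm/s for at least 0.33 s;
* **sap** (stretch-attend posture) - nose-tailbase distance above 1.2 body
  lengths while the tailbase moves slower than 1 cm/s;
* **approach** / **escape** - signed velocity toward the threat point above
  +3 cm/s / below -3 cm/s.

Conditions are evaluated per frame; maximal runs of condition-true frames
become bouts (a single supra-threshold frame splits a bout).  A frame's speed
covers the interval up to the next frame, so a run of k frames spans k frame
periods.  ``postprocess_bouts`` optionally merges nearby same-label bouts and
drops short ones; ``bout_robustness`` reproduces the published sanity check
that percent-time-freezing is insensitive to the minimum-bout setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pose import KinematicsSeries

__all__ = [
    "ClassifierParams",
    "BOUT_COLUMNS",
    "detect_freezing",
    "detect_sap",
    "detect_runs",
    "postprocess_bouts",
    "percent_time_freezing",
    "bout_robustness",
]

BOUT_COLUMNS = ["label", "start_s", "end_s", "duration_s", "mean_speed_cms", "peak_speed_cms"]


@dataclass(frozen=True)
class ClassifierParams:
    """Published thresholds for the four kinematic behavior definitions."""

    freeze_speed_max_cms: float = 0.25
    freeze_min_dur_s: float = 0.33
    sap_stretch_factor: float = 1.2
    sap_tail_speed_max_cms: float = 1.0
    run_speed_min_cms: float = 3.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


def _empty_bouts() -> pd.DataFrame:
    return pd.DataFrame(columns=BOUT_COLUMNS).astype(
        {"label": str, **{c: float for c in BOUT_COLUMNS[1:]}}
    )


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) frame indices, stop exclusive."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _runs_to_bouts(
    kin: KinematicsSeries, mask: np.ndarray, label: str, speed: np.ndarray, min_dur_s: float = 0.0
) -> pd.DataFrame:
    ts = kin.timestamps_s
    dt = kin.frame_period_s
    rows = []
    for i0, i1 in _mask_runs(mask):
        start = ts[i0]
        end = ts[i1] if i1 < len(ts) else ts[-1] + dt
        if end - start < min_dur_s - 1e-9:
            continue
        seg = speed[i0:i1]
        rows.append((label, start, end, end - start, float(seg.mean()), float(seg.max())))
    if not rows:
        return _empty_bouts()
    return pd.DataFrame(rows, columns=BOUT_COLUMNS)


def detect_freezing(kin: KinematicsSeries, params: ClassifierParams = ClassifierParams()) -> pd.DataFrame:
    """Immobility bouts: both head and tailbase below threshold, >= min duration."""
    if len(kin) == 0:
        raise ValueError("empty kinematics series")
    mask = (kin.head_speed_cms < params.freeze_speed_max_cms) & (
        kin.tailbase_speed_cms < params.freeze_speed_max_cms
    )
    return _runs_to_bouts(kin, mask, "freeze", kin.head_speed_cms, params.freeze_min_dur_s)


def detect_sap(kin: KinematicsSeries, params: ClassifierParams = ClassifierParams()) -> pd.DataFrame:
    """Stretch-attend postures: elongated body with near-stationary tailbase."""
    if not kin.body_length_cm > 0:
        raise ValueError("body length is zero or undefined")
    mask = (kin.nose_tail_distance_cm > params.sap_stretch_factor * kin.body_length_cm) & (
        kin.tailbase_speed_cms < params.sap_tail_speed_max_cms
    )
    return _runs_to_bouts(kin, mask, "sap", kin.tailbase_speed_cms)


def detect_runs(kin: KinematicsSeries, params: ClassifierParams = ClassifierParams()) -> pd.DataFrame:
    """Approach/escape bouts from the signed velocity toward the threat.

    Mean/peak speeds per bout are tailbase speeds, so the mean over escape
    bouts is the escape-velocity (flight vigor) metric.
    """
    sv = kin.signed_velocity_to_threat_cms
    if sv is None:
        raise ValueError("signed velocity unavailable: no threat point defined for this arena")
    approach = _runs_to_bouts(kin, sv > params.run_speed_min_cms, "approach", kin.tailbase_speed_cms)
    escape = _runs_to_bouts(kin, sv < -params.run_speed_min_cms, "escape", kin.tailbase_speed_cms)
    return pd.concat([approach, escape], ignore_index=True)


def postprocess_bouts(bouts: pd.DataFrame, merge_gap_s: float = 0.0, min_dur_s: float = 0.0) -> pd.DataFrame:
    """Merge same-label bouts separated by < ``merge_gap_s``; drop short bouts.

    Idempotent; with both parameters zero the input is returned unchanged
    (modulo row order, which is sorted by label then onset).
    """
    if merge_gap_s < 0 or min_dur_s < 0:
        raise ValueError("merge_gap_s and min_dur_s must be non-negative")
    out = []
    for label, grp in bouts.groupby("label", sort=True):
        grp = grp.sort_values("start_s")
        merged: list[dict] = []
        for _, row in grp.iterrows():
            if merged and row["start_s"] - merged[-1]["end_s"] < merge_gap_s:
                prev = merged[-1]
                w_prev = prev["end_s"] - prev["start_s"]
                w_new = row["end_s"] - row["start_s"]
                prev["mean_speed_cms"] = (
                    prev["mean_speed_cms"] * w_prev + row["mean_speed_cms"] * w_new
                ) / (w_prev + w_new)
                prev["peak_speed_cms"] = max(prev["peak_speed_cms"], row["peak_speed_cms"])
                prev["end_s"] = max(prev["end_s"], row["end_s"])
            else:
                merged.append(dict(row))
        for m in merged:
            m["duration_s"] = m["end_s"] - m["start_s"]
        out.extend(m for m in merged if m["duration_s"] >= min_dur_s - 1e-9)
    if not out:
        return _empty_bouts()
    return pd.DataFrame(out, columns=BOUT_COLUMNS).reset_index(drop=True)


def percent_time_freezing(
    kin: KinematicsSeries,
    params: ClassifierParams = ClassifierParams(),
    min_dur_s: float | None = None,
) -> float:
    """Total freeze-bout time as a percentage of the analyzed session time."""
    if min_dur_s is not None:
        params = ClassifierParams(
            freeze_speed_max_cms=params.freeze_speed_max_cms,
            freeze_min_dur_s=min_dur_s,
            sap_stretch_factor=params.sap_stretch_factor,
            sap_tail_speed_max_cms=params.sap_tail_speed_max_cms,
            run_speed_min_cms=params.run_speed_min_cms,
        )
    bouts = detect_freezing(kin, params)
    total = kin.timestamps_s[-1] + kin.frame_period_s - kin.timestamps_s[0]
    return 100.0 * float(bouts["duration_s"].sum()) / total


def bout_robustness(
    sessions: list[KinematicsSeries],
    params: ClassifierParams = ClassifierParams(),
    min_durs_s: tuple[float, float] = (0.33, 1.0),
) -> dict:
    """Correlate percent-time-freezing across sessions between two minimum-bout settings.

    Returns a dict with the per-session percentage vectors, the Pearson r, and
    a diagnostic when r is undefined (a constant vector).  Requires >= 3
    sessions; with fewer the correlation is unstable.
    """
    if len(sessions) < 3:
        raise ValueError("bout_robustness requires at least 3 sessions")
    v0 = np.array([percent_time_freezing(k, params, min_durs_s[0]) for k in sessions])
    v1 = np.array([percent_time_freezing(k, params, min_durs_s[1]) for k in sessions])
    result = {"min_durs_s": min_durs_s, "percent_freezing": (v0, v1)}
    if np.ptp(v0) == 0 or np.ptp(v1) == 0:
        result.update(r=np.nan, p=np.nan, diagnostic="constant percent-freezing vector; r undefined")
    else:
        r, p = stats.pearsonr(v0, v1)
        result.update(r=float(r), p=float(p), diagnostic=None)
    return result
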