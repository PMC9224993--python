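"""Zone-based assay scoring and epoch (ON-OFF / CNO-SAL) contrasts.

Scores the five assays from head-centroid trajectories against a
:class:`~defensetrack.arenas.ZoneMap`: occupancy and entries (open field,
EPM), trial latencies and the screening rule of the latency-to-enter assay,
real-time place-test preference, threat distance in the predator corridor,
and per-condition behavioral metrics with ON-minus-OFF contrasts.

Timing convention: frame ``i`` accounts for the interval up to frame ``i+1``
(the final frame gets one median frame period), so planted dwell schedules
are recovered to within one frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arenas import ZoneMap
from .behavior import ClassifierParams, detect_freezing
from .pose import KinematicsSeries
from .schedule import EpochSchedule

__all__ = [
    "CalibrationError",
    "zone_occupancy",
    "count_entries",
    "threat_distance",
    "score_lte_trial",
    "score_lte_session",
    "lte_contrast",
    "burrow_preference",
    "rtpt_preference",
    "epoch_metrics",
]

NO_ENTRY_LATENCY_S = 61.0  # no-entry trials score trial limit (60 s) + 1


class CalibrationError(ValueError):
    """Trajectory falls outside the arena too often: bad calibration or map."""


def _frame_durations(ts: np.ndarray) -> np.ndarray:
    d = np.diff(ts)
    return np.append(d, np.median(d) if len(d) else 1.0)


def _check_in_arena(kin: KinematicsSeries, zonemap: ZoneMap, tol_frac: float = 0.05) -> None:
    x, y = kin.head_xy_cm[:, 0], kin.head_xy_cm[:, 1]
    outside = ~zonemap.in_arena(x, y)
    if outside.mean() > tol_frac:
        raise CalibrationError(
            f"{100 * outside.mean():.1f}% of frames outside the arena polygon "
            "(>5%); check calibration and zone map"
        )


def zone_occupancy(
    kin: KinematicsSeries,
    zonemap: ZoneMap,
    zones: list[str] | None = None,
    frame_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Seconds and fraction of analyzed time spent in each named zone.

    ``frame_mask`` optionally restricts the analysis window (e.g. to one
    laser condition).  Fractions are relative to the analyzed time, so they
    sum to <= 1 over any disjoint zone family.
    """
    _check_in_arena(kin, zonemap)
    zones = zones if zones is not None else zonemap.zone_names()
    dur = _frame_durations(kin.timestamps_s)
    if frame_mask is not None:
        dur = np.where(frame_mask, dur, 0.0)
    total = float(dur.sum())
    if total <= 0:
        raise ValueError("empty analysis window")
    x, y = kin.head_xy_cm[:, 0], kin.head_xy_cm[:, 1]
    rows = []
    for z in zones:
        sec = float(dur[zonemap.contains(z, x, y)].sum())
        rows.append({"zone": z, "seconds": sec, "fraction": sec / total})
    return pd.DataFrame(rows).set_index("zone")


def count_entries(
    kin: KinematicsSeries,
    zonemap: ZoneMap,
    zone: str,
    min_entry_dur_s: float = 0.2,
    frame_mask: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Count outside-to-inside transitions sustained for >= ``min_entry_dur_s``.

    Returns (count, entry timestamps).  The debounce rejects single-frame
    boundary grazes; starting inside the zone does not count as an entry.
    """
    inside = zonemap.contains(zone, kin.head_xy_cm[:, 0], kin.head_xy_cm[:, 1])
    ts = kin.timestamps_s
    dur = _frame_durations(ts)
    entries = []
    i = 1
    n = len(inside)
    while i < n:
        if inside[i] and not inside[i - 1]:
            j = i
            while j < n and inside[j]:
                j += 1
            if dur[i:j].sum() >= min_entry_dur_s - 1e-9:
                entries.append(ts[i])
            i = j
        else:
            i += 1
    entries = np.asarray(entries)
    if frame_mask is not None:
        keep = np.isin(np.searchsorted(ts, entries), np.flatnonzero(frame_mask))
        entries = entries[keep]
    return len(entries), entries


def threat_distance(
    kin: KinematicsSeries, zonemap: ZoneMap, frame_mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-frame Euclidean distance from the head to the rat-wall midpoint.

    Returns the full series and its (duration-weighted) mean over the
    analyzed window.
    """
    if zonemap.rat_wall is None:
        raise ValueError(f"arena {zonemap.arena_name!r} defines no rat wall")
    (x1, y1), (x2, y2) = zonemap.rat_wall
    mid = np.array([(x1 + x2) / 2, (y1 + y2) / 2])
    series = np.linalg.norm(kin.head_xy_cm - mid, axis=1)
    dur = _frame_durations(kin.timestamps_s)
    if frame_mask is not None:
        dur = np.where(frame_mask, dur, 0.0)
    mean = float(np.average(series, weights=dur))
    return series, mean


def score_lte_trial(
    kin_segment: KinematicsSeries, zonemap: ZoneMap, trial_limit_s: float = 60.0
) -> float:
    """Latency from barrier removal (segment start) to first burrow entry.

    No entry within the trial limit scores ``trial_limit_s + 1`` (61 s by the
    published convention).  The result is floored at one frame period and
    capped at 61 s.
    """
    inside = zonemap.contains("burrow", kin_segment.head_xy_cm[:, 0], kin_segment.head_xy_cm[:, 1])
    ts = kin_segment.timestamps_s
    t0 = ts[0]
    dt = kin_segment.frame_period_s
    hits = np.flatnonzero(inside & (ts - t0 <= trial_limit_s + 1e-9))
    if hits.size == 0:
        if ts[-1] - t0 < trial_limit_s - 1e-9:
            raise ValueError(
                "segment ends before the trial limit with no burrow entry; "
                "cannot distinguish a timeout from a truncated recording"
            )
        return trial_limit_s + 1.0
    return float(max(ts[hits[0]] - t0, dt))


def score_lte_session(
    kin: KinematicsSeries, zonemap: ZoneMap, trials: pd.DataFrame
) -> pd.DataFrame:
    """Score every trial of an LTE session; adds a ``latency_s`` column.

    ``trials`` follows :func:`~defensetrack.schedule.make_lte_trials`; each
    trial's segment starts at its barrier removal and holding-zone frames are
    excluded by construction.
    """
    out = trials.copy()
    latencies = []
    ts = kin.timestamps_s
    for _, tr in trials.iterrows():
        limit = float(tr.get("trial_limit_s", 60.0))
        sel = (ts >= tr["barrier_removal_s"] - 1e-9) & (ts <= tr["barrier_removal_s"] + limit + 1.0)
        seg = KinematicsSeries(
            timestamps_s=ts[sel],
            head_xy_cm=kin.head_xy_cm[sel],
            head_speed_cms=kin.head_speed_cms[sel],
            tailbase_speed_cms=kin.tailbase_speed_cms[sel],
            nose_tail_distance_cm=kin.nose_tail_distance_cm[sel],
            body_length_cm=kin.body_length_cm,
        )
        latencies.append(score_lte_trial(seg, zonemap, limit))
    out["latency_s"] = latencies
    return out


def lte_contrast(trials: pd.DataFrame) -> float:
    """Mean laser-ON latency minus mean laser-OFF latency, seconds."""
    if "latency_s" not in trials:
        raise ValueError("trials must be scored first (missing latency_s)")
    on = trials.loc[trials["laser_on"], "latency_s"]
    off = trials.loc[~trials["laser_on"], "latency_s"]
    if len(on) != len(off) or len(on) == 0:
        raise ValueError(f"unbalanced trial counts: {len(on)} ON vs {len(off)} OFF")
    return float(on.mean() - off.mean())


def burrow_preference(kin: KinematicsSeries, zonemap: ZoneMap) -> tuple[bool, pd.DataFrame]:
    """Screening rule: strictly more habituation time in the burrow than in
    each of the other three corners.  Ties fail the screen."""
    corners = [z for z in zonemap.zone_names() if z.startswith("corner_")]
    if "burrow" not in zonemap.zones or len(corners) != 3:
        raise ValueError("burrow preference needs a burrow zone and exactly 3 corner zones")
    for c in corners:
        if zonemap.zones["burrow"].intersection(zonemap.zones[c]).area > 0:
            raise ValueError(f"burrow polygon overlaps corner zone {c!r}")
    occ = zone_occupancy(kin, zonemap, ["burrow"] + corners)
    burrow_s = occ.loc["burrow", "seconds"]
    prefers = bool(all(burrow_s > occ.loc[c, "seconds"] for c in corners))
    return prefers, occ


def rtpt_preference(
    kin_pre: KinematicsSeries,
    kin_test: KinematicsSeries,
    zonemap: ZoneMap,
    zone: str = "stim_chamber",
) -> float:
    """Stimulated-chamber seconds during test minus during pre-exposure."""
    if zone not in zonemap.zones:
        raise KeyError(f"zone {zone!r} missing from zone map")
    pre = zone_occupancy(kin_pre, zonemap, [zone]).loc[zone, "seconds"]
    test = zone_occupancy(kin_test, zonemap, [zone]).loc[zone, "seconds"]
    return float(test - pre)


def _bout_time_in_intervals(bouts: pd.DataFrame, intervals: np.ndarray) -> float:
    tot = 0.0
    for _, b in bouts.iterrows():
        for s, e in intervals:
            tot += max(0.0, min(b["end_s"], e) - max(b["start_s"], s))
    return tot


def _bout_count_in_intervals(bouts: pd.DataFrame, intervals: np.ndarray) -> int:
    onsets = bouts["start_s"].to_numpy(float)
    return int(sum(((onsets >= s) & (onsets < e)).sum() for s, e in intervals))


ALL_EPOCH_METRICS = (
    "mean_speed_cms",
    "pct_freezing",
    "corner_entries",
    "center_time_s",
    "corner_time_s",
    "open_arm_pct",
    "threat_zone_time_s",
    "threat_distance_cm",
    "sap_count",
    "approach_count",
    "escape_count",
    "escape_velocity_cms",
    "distance_traveled_cm",
)


def epoch_metrics(
    kin: KinematicsSeries,
    bouts: pd.DataFrame,
    schedule: EpochSchedule,
    zonemap: ZoneMap | None = None,
    metrics: tuple[str, ...] | None = None,
    n_epochs: int | None = None,
    params: ClassifierParams = ClassifierParams(),
) -> pd.DataFrame:
    """Per-condition behavioral metrics and the ON-minus-OFF contrast.

    Counts (entries, SAPs, approaches, escapes) are reported per condition,
    not as rates, matching the published presentation.  ``n_epochs`` keeps
    only the leading epochs of the schedule (the EPM protocol analyzes the
    first four of its five 2-min epochs).  When the schedule's conditions are
    exactly {ON, OFF}, a ``contrast`` column (ON - OFF) is added.
    """
    if n_epochs is not None:
        schedule = schedule.head(n_epochs)
    ts = kin.timestamps_s
    if len(schedule.intervals) == 0:
        raise ValueError("empty schedule")
    metrics = metrics if metrics is not None else ALL_EPOCH_METRICS
    dur_all = _frame_durations(ts)
    corner_zones = [z for z in (zonemap.zone_names() if zonemap else []) if z.startswith("corner_")]
    open_arms = [z for z in (zonemap.zone_names() if zonemap else []) if z.startswith("open_arm")]

    table: dict[str, dict[str, float]] = {}
    for cond in schedule.conditions():
        mask = schedule.mask(ts, cond)
        if not mask.any():
            raise ValueError(f"condition {cond!r} covers no frames")
        ivals = schedule.condition_intervals(cond)
        dur = np.where(mask, dur_all, 0.0)
        cond_time = float(dur.sum())
        vals: dict[str, float] = {}
        for m in metrics:
            if m == "mean_speed_cms":
                vals[m] = float(np.average(kin.head_speed_cms, weights=dur))
            elif m == "pct_freezing":
                fr = bouts[bouts["label"] == "freeze"]
                if fr.empty:
                    fr = detect_freezing(kin, params)
                vals[m] = 100.0 * _bout_time_in_intervals(fr, ivals) / cond_time
            elif m == "corner_entries":
                vals[m] = float(
                    sum(count_entries(kin, zonemap, z, frame_mask=mask)[0] for z in corner_zones)
                )
            elif m == "center_time_s":
                vals[m] = zone_occupancy(kin, zonemap, ["center"], mask).loc["center", "seconds"]
            elif m == "corner_time_s":
                occ = zone_occupancy(kin, zonemap, corner_zones, mask)
                vals[m] = float(occ["seconds"].sum())
            elif m == "open_arm_pct":
                occ = zone_occupancy(kin, zonemap, open_arms, mask)
                vals[m] = 100.0 * float(occ["fraction"].sum())
            elif m == "threat_zone_time_s":
                vals[m] = zone_occupancy(kin, zonemap, ["threat_zone"], mask).loc[
                    "threat_zone", "seconds"
                ]
            elif m == "threat_distance_cm":
                vals[m] = threat_distance(kin, zonemap, mask)[1]
            elif m in ("sap_count", "approach_count", "escape_count"):
                label = m.split("_")[0]
                vals[m] = float(_bout_count_in_intervals(bouts[bouts["label"] == label], ivals))
            elif m == "escape_velocity_cms":
                esc = bouts[bouts["label"] == "escape"]
                onsets = esc["start_s"].to_numpy(float)
                sel = np.zeros(len(esc), bool)
                for s, e in ivals:
                    sel |= (onsets >= s) & (onsets < e)
                vals[m] = float(esc.loc[sel, "mean_speed_cms"].mean()) if sel.any() else np.nan
            elif m == "distance_traveled_cm":
                vals[m] = float((kin.head_speed_cms * dur).sum())
            else:
                raise ValueError(f"unknown metric {m!r}")
        table[cond] = vals

    out = pd.DataFrame(table)
    if set(out.columns) == {"ON", "OFF"}:
        out["contrast"] = out["ON"] - out["OFF"]
    return out
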