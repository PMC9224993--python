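"""Peri-event, spatial-tuning, and zone-contrast analyses of frame-aligned z-dF/F.

All functions operate on the per-frame z-scored dF/F produced by
:mod:`defensetrack.photometry` together with behavior-frame timestamps,
positions, and bout tables:

* :func:`peri_event_average` - event-aligned traces +/- a symmetric window
  around bout onsets, with edge events dropped;
* :func:`arm_entry_response` - mean z-dF/F in the second following EPM arm
  entries, contrasting open vs closed arms;
* :func:`spatial_bin_dff` - mean z-dF/F in equal-width bins of distance from
  the corridor safe wall, restricted to approach or escape frames, with a
  Pearson correlation over the bin means (the published per-bin analysis, 10
  bins) and a sample-level correlation alongside;
* :func:`zone_mean_dff` - safe-third vs threat-two-thirds means; their
  occupancy-weighted combination equals the whole-corridor mean;
* :func:`speed_dff_control` - speed/z-dF/F correlation control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arenas import ZoneMap
from .stats import pearson_r

__all__ = [
    "PeriEventTensor",
    "SpatialTuning",
    "peri_event_average",
    "arm_entry_response",
    "spatial_bin_dff",
    "zone_mean_dff",
    "speed_dff_control",
]


@dataclass
class PeriEventTensor:
    """Events x time-offset matrix of z-dF/F around event onsets."""

    offsets_s: np.ndarray
    traces: np.ndarray  # (n_valid_events, n_offsets)
    label: str
    mean_trace: np.ndarray
    n_dropped: int


@dataclass
class SpatialTuning:
    """Binned z-dF/F versus distance from the safe wall for one run type."""

    bin_centers_cm: np.ndarray
    bin_mean: np.ndarray
    bin_sem: np.ndarray
    bin_count: np.ndarray
    label: str
    r: float
    p: float
    r_samples: float
    p_samples: float
    empty_bins: list[int]


def peri_event_average(
    zdff_frames: np.ndarray,
    frame_timestamps_s: np.ndarray,
    event_times_s: np.ndarray,
    window_s: float = 5.0,
    label: str = "event",
) -> PeriEventTensor:
    """Average z-dF/F in a symmetric window around event onsets.

    Events whose window leaves the recording are dropped (masked); at least
    one valid event is required.
    """
    ts = np.asarray(frame_timestamps_s, float)
    z = np.asarray(zdff_frames, float)
    dt = float(np.median(np.diff(ts)))
    half = int(round(window_s / dt))
    offsets = np.arange(-half, half + 1) * dt
    rows = []
    dropped = 0
    for ev in np.asarray(event_times_s, float):
        i = int(np.argmin(np.abs(ts - ev)))
        if i - half < 0 or i + half >= len(ts):
            dropped += 1
            continue
        seg = z[i - half : i + half + 1]
        if np.any(np.isnan(seg)):
            dropped += 1
            continue
        rows.append(seg)
    if not rows:
        raise ValueError(f"no valid {label!r} events inside the recording window")
    traces = np.vstack(rows)
    return PeriEventTensor(offsets, traces, label, traces.mean(axis=0), dropped)


def arm_entry_response(
    zdff_frames: np.ndarray,
    frame_timestamps_s: np.ndarray,
    entries: pd.DataFrame,
    post_window_s: float = 1.0,
) -> dict:
    """Mean z-dF/F in the window (entry, entry + 1 s] per EPM arm type.

    ``entries`` has columns ``time_s`` and ``arm_type`` in {open, closed}.
    Entries within ``post_window_s`` of the recording end are excluded.
    Returns per-entry means, per-arm-type means, and the open-closed
    contrast.
    """
    ts = np.asarray(frame_timestamps_s, float)
    z = np.asarray(zdff_frames, float)
    per_entry = []
    for _, row in entries.iterrows():
        t0 = float(row["time_s"])
        if t0 + post_window_s > ts[-1]:
            continue
        sel = (ts > t0) & (ts <= t0 + post_window_s)
        if not sel.any() or np.all(np.isnan(z[sel])):
            continue
        per_entry.append({"arm_type": row["arm_type"], "time_s": t0,
                          "mean_zdff": float(np.nanmean(z[sel]))})
    per_entry = pd.DataFrame(per_entry)
    means = {}
    for arm in ("open", "closed"):
        vals = per_entry.loc[per_entry["arm_type"] == arm, "mean_zdff"] if len(per_entry) else []
        if len(vals) == 0:
            raise ValueError(f"no valid {arm}-arm entries")
        means[arm] = float(np.mean(vals))
    return {
        "per_entry": per_entry,
        "open_mean": means["open"],
        "closed_mean": means["closed"],
        "contrast": means["open"] - means["closed"],
    }


def _mask_from_bouts(ts: np.ndarray, bouts: pd.DataFrame, label: str) -> np.ndarray:
    mask = np.zeros(len(ts), bool)
    for _, b in bouts[bouts["label"] == label].iterrows():
        mask |= (ts >= b["start_s"]) & (ts < b["end_s"])
    return mask


def spatial_bin_dff(
    zdff_frames: np.ndarray,
    positions_cm: np.ndarray,
    frame_timestamps_s: np.ndarray,
    bouts: pd.DataFrame,
    zonemap: ZoneMap,
    label: str = "approach",
    n_bins: int = 10,
) -> SpatialTuning:
    """Spatial tuning of z-dF/F along the corridor during approach or escape.

    Frames inside bouts of ``label`` are binned by distance from the safe
    wall into ``n_bins`` equal-width bins spanning the corridor length.
    The headline Pearson r is computed on the (bin center, bin mean) pairs;
    a sample-level r is reported alongside.  Empty bins are flagged and
    excluded pairwise from the correlation.
    """
    ts = np.asarray(frame_timestamps_s, float)
    z = np.asarray(zdff_frames, float)
    dist = np.abs(np.asarray(positions_cm, float)[:, 0] - zonemap.safe_wall_x)
    length = zonemap.arena.bounds[2] - zonemap.arena.bounds[0]
    mask = _mask_from_bouts(ts, bouts, label) & ~np.isnan(z)
    if not mask.any():
        raise ValueError(f"no {label!r} frames with valid z-dF/F")
    edges = np.linspace(0.0, length, n_bins + 1)
    which = np.clip(np.digitize(dist[mask], edges) - 1, 0, n_bins - 1)
    zm = z[mask]
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_mean = np.full(n_bins, np.nan)
    bin_sem = np.full(n_bins, np.nan)
    bin_count = np.zeros(n_bins, int)
    for b in range(n_bins):
        sel = which == b
        bin_count[b] = int(sel.sum())
        if bin_count[b]:
            bin_mean[b] = zm[sel].mean()
            bin_sem[b] = zm[sel].std(ddof=1) / np.sqrt(bin_count[b]) if bin_count[b] > 1 else np.nan
    good = bin_count > 0
    if good.sum() < 3:
        raise ValueError("fewer than 3 occupied bins; tuning curve undefined")
    r, p = pearson_r(centers[good], bin_mean[good])
    r_s, p_s = pearson_r(dist[mask], zm)
    return SpatialTuning(
        centers, bin_mean, bin_sem, bin_count, label,
        r, p, r_s, p_s, list(np.flatnonzero(~good)),
    )


def zone_mean_dff(
    zdff_frames: np.ndarray,
    positions_cm: np.ndarray,
    zonemap: ZoneMap,
) -> dict:
    """Safe-zone vs threat-zone mean z-dF/F in the corridor.

    The safe zone is the third nearest the safe wall; the threat zone the
    remaining two-thirds.  Returns both means, the paired contrast
    (threat - safe), occupancy fractions, and the whole-corridor mean (which
    the occupancy-weighted zone means recombine to exactly).
    """
    z = np.asarray(zdff_frames, float)
    pos = np.asarray(positions_cm, float)
    valid = ~np.isnan(z)
    length = zonemap.arena.bounds[2] - zonemap.arena.bounds[0]
    dist = np.abs(pos[:, 0] - zonemap.safe_wall_x)
    safe = valid & (dist <= length / 3.0)
    threat = valid & (dist > length / 3.0)
    if not safe.any() or not threat.any():
        raise ValueError("session never visits one of the corridor zones")
    n = int(valid.sum())
    out = {
        "safe_mean": float(z[safe].mean()),
        "threat_mean": float(z[threat].mean()),
        "safe_frac": float(safe.sum()) / n,
        "threat_frac": float(threat.sum()) / n,
        "overall_mean": float(z[valid].mean()),
    }
    out["contrast"] = out["threat_mean"] - out["safe_mean"]
    return out


def speed_dff_control(zdff_frames: np.ndarray, speed_cms: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between locomotion speed and z-dF/F (control)."""
    z = np.asarray(zdff_frames, float)
    s = np.asarray(speed_cms, float)
    valid = ~np.isnan(z) & ~np.isnan(s)
    if np.ptp(s[valid]) == 0:
        raise ValueError("constant speed; correlation undefined")
    return pearson_r(s[valid], z[valid])
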