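"""Two-channel fiber-photometry processing: isosbestic correction to z-dF/F.

Raw recordings interleave a calcium-dependent 470-nm channel with a 405-nm
isosbestic reference sampled on alternating pulses.  Photobleaching and
motion artifacts appear in both channels; calcium transients only in the
signal channel.  The pipeline is:

1. :func:`deinterleave` - split channels, interpolate the reference onto the
   signal timestamps (rates are read from timestamps, never assumed);
2. :func:`correct_reference` - least-squares fit of the reference onto the
   signal; dF/F = (signal - fitted) / fitted, removing shared bleach and
   motion terms;
3. :func:`zscore_dff` - z-score over a normalization window (default whole
   session);
4. :func:`align_to_frames` - assign each behavior video frame the nearest
   photometry sample within one sample period.

A Theil-Sen robust fit is available for artifact-heavy sessions.  No
filtering is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SIGNAL_CHANNEL",
    "REFERENCE_CHANNEL",
    "DffSeries",
    "deinterleave",
    "correct_reference",
    "zscore_dff",
    "align_to_frames",
    "process_recording",
]

SIGNAL_CHANNEL = 470
REFERENCE_CHANNEL = 405


@dataclass
class DffSeries:
    """Corrected dF/F on the signal-channel clock.

    ``zdff`` has mean 0 and SD 1 over the normalization window.
    ``frame_index`` maps photometry samples to behavior frames after
    :func:`align_to_frames` (filled by :func:`process_recording`).
    """

    timestamps_s: np.ndarray
    dff: np.ndarray
    zdff: np.ndarray
    fit_slope: float
    fit_intercept: float
    frame_index: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.timestamps_s)

    @property
    def sample_period_s(self) -> float:
        return float(np.median(np.diff(self.timestamps_s)))


def deinterleave(recording: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw interleaved stream into signal and reference series.

    ``recording`` has columns ``timestamp_s``, ``channel`` (470 or 405) and
    ``value``, with channels strictly alternating.  Returns
    ``(signal, reference_on_signal_clock)`` DataFrames with columns
    ``timestamp_s`` and ``value``; the reference is linearly interpolated
    onto the signal timestamps.
    """
    for c in ("timestamp_s", "channel", "value"):
        if c not in recording.columns:
            raise ValueError(f"recording missing column {c!r}")
    ch = recording["channel"].to_numpy()
    ts = recording["timestamp_s"].to_numpy(float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("raw timestamps must be strictly increasing")
    if np.any(ch[1:] == ch[:-1]):
        i = int(np.flatnonzero(ch[1:] == ch[:-1])[0]) + 1
        raise ValueError(f"channels do not alternate at sample {i} (t={ts[i]:.3f}s)")
    unknown = set(np.unique(ch)) - {SIGNAL_CHANNEL, REFERENCE_CHANNEL}
    if unknown:
        raise ValueError(f"unknown channel tags {unknown}")
    sig = recording[ch == SIGNAL_CHANNEL][["timestamp_s", "value"]].reset_index(drop=True)
    ref = recording[ch == REFERENCE_CHANNEL][["timestamp_s", "value"]].reset_index(drop=True)
    ref_i = np.interp(sig["timestamp_s"], ref["timestamp_s"], ref["value"])
    ref_on_sig = pd.DataFrame({"timestamp_s": sig["timestamp_s"], "value": ref_i})
    return sig, ref_on_sig


def correct_reference(
    signal: pd.DataFrame, reference: pd.DataFrame, method: str = "ols"
) -> DffSeries:
    """Regress the reference onto the signal and form dF/F on the residual.

    ``fitted = slope * reference + intercept`` captures the calcium-
    independent component (bleach, motion); ``dff = (signal - fitted) /
    fitted``.  ``method`` is ``"ols"`` (default) or ``"theilsen"`` for
    artifact-heavy sessions.
    """
    if len(signal) != len(reference):
        raise ValueError("signal and reference must be aligned and equal length")
    if len(signal) < 100:
        raise ValueError("need at least 100 aligned samples for a stable fit")
    s = signal["value"].to_numpy(float)
    r = reference["value"].to_numpy(float)
    if np.ptp(r) == 0:
        raise ValueError("zero-variance reference channel")
    if method == "ols":
        slope, intercept = np.polyfit(r, s, 1)
    elif method == "theilsen":
        res = stats.theilslopes(s, r)
        slope, intercept = res.slope, res.intercept
    else:
        raise ValueError(f"unknown fit method {method!r}")
    fitted = slope * r + intercept
    if np.any(fitted <= 0):
        raise ValueError("fitted reference crosses zero; cannot normalize dF/F")
    dff = (s - fitted) / fitted
    return DffSeries(
        timestamps_s=signal["timestamp_s"].to_numpy(float),
        dff=dff,
        zdff=np.full_like(dff, np.nan),
        fit_slope=float(slope),
        fit_intercept=float(intercept),
    )


def zscore_dff(series: DffSeries, window_s: tuple[float, float] | None = None) -> DffSeries:
    """Z-score dF/F using mean/SD from ``window_s`` (default: whole session)."""
    ts, dff = series.timestamps_s, series.dff
    if window_s is None:
        sel = slice(None)
    else:
        lo, hi = window_s
        sel = (ts >= lo) & (ts <= hi)
        if not np.any(sel):
            raise ValueError("normalization window contains no samples")
    mu = float(np.mean(dff[sel]))
    sd = float(np.std(dff[sel]))
    if sd == 0:
        raise ValueError("zero-variance dF/F in normalization window")
    return DffSeries(ts, dff, (dff - mu) / sd, series.fit_slope, series.fit_intercept,
                     series.frame_index)


def align_to_frames(
    series: DffSeries, frame_timestamps_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame z-dF/F by nearest-sample assignment.

    Each behavior frame takes the nearest-in-time photometry sample within
    one sample period; frames outside coverage are NaN with a False validity
    mask.  Returns ``(per_frame_zdff, valid_mask)``.
    """
    ft = np.asarray(frame_timestamps_s, float)
    ts = series.timestamps_s
    if ft[-1] < ts[0] or ft[0] > ts[-1]:
        raise ValueError("no temporal overlap between frames and photometry")
    period = series.sample_period_s
    idx = np.searchsorted(ts, ft)
    idx = np.clip(idx, 1, len(ts) - 1)
    left, right = ts[idx - 1], ts[idx]
    nearest = np.where(ft - left <= right - ft, idx - 1, idx)
    valid = np.abs(ts[nearest] - ft) <= period + 1e-9
    out = np.where(valid, series.zdff[nearest], np.nan)
    return out, valid


def process_recording(
    recording: pd.DataFrame,
    frame_timestamps_s: np.ndarray | None = None,
    method: str = "ols",
    zscore_window_s: tuple[float, float] | None = None,
) -> tuple[DffSeries, np.ndarray | None]:
    """Full pipeline: deinterleave, correct, z-score, optionally frame-align.

    Returns ``(DffSeries, per_frame_zdff_or_None)``.
    """
    sig, ref = deinterleave(recording)
    series = zscore_dff(correct_reference(sig, ref, method=method), zscore_window_s)
    per_frame = None
    if frame_timestamps_s is not None:
        per_frame, _ = align_to_frames(series, frame_timestamps_s)
        # per-sample index of the nearest behavior frame
        ft = np.asarray(frame_timestamps_s, float)
        idx = np.clip(np.searchsorted(ft, series.timestamps_s), 1, len(ft) - 1)
        left = series.timestamps_s - ft[idx - 1] <= ft[idx] - series.timestamps_s
        series.frame_index = np.where(left, idx - 1, idx)
    return series, per_frame
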