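"""Pose tables, confidence-based cleaning, and kinematic series.

The pose estimator emits, per video frame, x/y coordinates and a likelihood
for four bodyparts (nose, both ears, tailbase).  This module validates those
tables, interpolates low-confidence points, calibrates pixels to centimetres,
and differentiates positions into the speed/posture series every behavior
classifier consumes.

Conventions (package defaults, stated here because the upstream protocol does
not fix them):

* "head" position = centroid of nose and both ears - robust to nose dropouts;
* positions are boxcar-smoothed (default 5 frames, ~0.17 s at 30 fps) before
  differentiation so video jitter cannot break the 0.25 cm/s freezing
  threshold; pass ``smoothing_window_frames=1`` for noise-free tracks;
* speeds use forward differences padded by edge replication to keep series
  the same length as the input track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "BODYPARTS",
    "PoseTrack",
    "KinematicsSeries",
    "read_pose_table",
    "write_pose_table",
    "interpolate_low_confidence",
    "compute_kinematics",
]

BODYPARTS = ("nose", "ear_left", "ear_right", "tailbase")

_COLUMNS = ["frame", "timestamp_s"] + [
    f"{bp}_{f}" for bp in BODYPARTS for f in ("x", "y", "likelihood")
]


@dataclass
class PoseTrack:
    """Per-frame bodypart coordinates, likelihoods and timestamps.

    ``data`` holds one row per frame with columns ``frame``, ``timestamp_s``
    and ``{bodypart}_{x,y,likelihood}``.  Coordinates are in pixels scaled by
    ``cm_per_px`` relative to ``origin_px`` (arena lower-left); synthetic
    tracks use ``cm_per_px=1`` so coordinates are already centimetres.
    """

    data: pd.DataFrame
    cm_per_px: float = 1.0
    origin_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"pose table missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("pose table is empty")
        ts = self.data["timestamp_s"].to_numpy(float)
        if np.any(~np.isfinite(ts)) or np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be finite and strictly increasing")
        for bp in BODYPARTS:
            lk = self.data[f"{bp}_likelihood"].to_numpy(float)
            if np.any((lk < 0) | (lk > 1) | ~np.isfinite(lk)):
                raise ValueError(f"{bp} likelihoods outside [0, 1]")
        if self.cm_per_px <= 0:
            raise ValueError("cm_per_px must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps_s(self) -> np.ndarray:
        return self.data["timestamp_s"].to_numpy(float)

    def xy_cm(self, bodypart: str) -> np.ndarray:
        """(n, 2) calibrated coordinates of one bodypart."""
        x = (self.data[f"{bodypart}_x"].to_numpy(float) - self.origin_px[0]) * self.cm_per_px
        y = (self.data[f"{bodypart}_y"].to_numpy(float) - self.origin_px[1]) * self.cm_per_px
        return np.column_stack([x, y])


@dataclass
class KinematicsSeries:
    """Derived kinematics aligned to the pose frames.

    ``signed_velocity_to_threat_cms`` is positive when the head moves toward
    the threat point (approach) and ``None`` when no threat point was given.
    """

    timestamps_s: np.ndarray
    head_xy_cm: np.ndarray  # (n, 2) head-centroid position
    head_speed_cms: np.ndarray
    tailbase_speed_cms: np.ndarray
    nose_tail_distance_cm: np.ndarray
    body_length_cm: float
    signed_velocity_to_threat_cms: np.ndarray | None = None
    threat_point: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.timestamps_s)

    @property
    def frame_period_s(self) -> float:
        return float(np.median(np.diff(self.timestamps_s)))


def read_pose_table(path, cm_per_px: float = 1.0, origin_px=(0.0, 0.0)) -> PoseTrack:
    """Read a pose table (``frame, timestamp_s, {bp}_x/_y/_likelihood``).

    CSV by default; ``.h5``/``.hdf5`` files with the same column semantics
    are read through pandas.
    """
    if str(path).endswith((".h5", ".hdf5")):
        df = pd.read_hdf(path)
    else:
        df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"empty pose table: {path}")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose table {path} missing columns: {missing}")
    for c in _COLUMNS:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"non-numeric values in column {c!r} of {path}")
    # reject rows breaking timestamp monotonicity (duplicated/reordered frames)
    ts = df["timestamp_s"].to_numpy(float)
    keep = np.ones(len(df), bool)
    last = -np.inf
    for i, t in enumerate(ts):
        if t > last:
            last = t
        else:
            keep[i] = False
    return PoseTrack(df.loc[keep].reset_index(drop=True), cm_per_px, tuple(origin_px))


def write_pose_table(track: PoseTrack, path) -> None:
    track.data.to_csv(path, index=False)


def interpolate_low_confidence(track: PoseTrack, likelihood_min: float = 0.9) -> PoseTrack:
    """Replace low-confidence coordinates by linear interpolation in time.

    Coordinates with ``likelihood < likelihood_min`` are interpolated between
    the nearest confident frames; leading/trailing gaps take the nearest
    confident value.  Filled frames are flagged by setting their likelihood to
    exactly ``likelihood_min`` so downstream code can identify them.
    """
    if not 0.0 <= likelihood_min <= 1.0:
        raise ValueError("likelihood_min must lie in [0, 1]")
    df = track.data.copy()
    ts = df["timestamp_s"].to_numpy(float)
    for bp in BODYPARTS:
        lk = df[f"{bp}_likelihood"].to_numpy(float)
        good = lk >= likelihood_min
        if not good.any():
            raise ValueError(f"bodypart {bp!r} has no frames above likelihood_min")
        if good.all():
            continue
        for axis in ("x", "y"):
            col = f"{bp}_{axis}"
            v = df[col].to_numpy(float)
            v[~good] = np.interp(ts[~good], ts[good], v[good])
            df[col] = v
        lk = lk.copy()
        lk[~good] = likelihood_min
        df[f"{bp}_likelihood"] = lk
    return replace(track, data=df)


def _boxcar(xy: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar smoothing of an (n, 2) position series, edge-replicated."""
    if window == 1:
        return xy
    half = window // 2
    pad = np.concatenate([np.repeat(xy[:1], half, 0), xy, np.repeat(xy[-1:], half, 0)])
    kernel = np.full(window, 1.0 / window)
    out = np.empty_like(xy)
    for k in range(xy.shape[1]):
        out[:, k] = np.convolve(pad[:, k], kernel, mode="valid")
    return out


def _forward_speed(xy: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """|dposition|/dt by forward difference, last value edge-replicated."""
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1) / np.diff(ts)
    return np.append(d, d[-1]) if len(d) else np.zeros(1)


def compute_kinematics(
    track: PoseTrack,
    smoothing_window_frames: int = 5,
    threat_point: tuple[float, float] | None = None,
) -> KinematicsSeries:
    """Differentiate a pose track into the classifier input series.

    Head position is the centroid of nose and both ears; positions are boxcar
    smoothed over ``smoothing_window_frames`` (odd, >= 1) before forward
    differencing.  ``body_length_cm`` is the session median nose-tailbase
    distance.  With a ``threat_point``, the signed velocity toward the threat
    (-d(distance)/dt, positive = approaching) is also returned.
    """
    if smoothing_window_frames < 1 or smoothing_window_frames % 2 == 0:
        raise ValueError("smoothing window must be an odd integer >= 1")
    if len(track) < max(2, smoothing_window_frames):
        raise ValueError("track shorter than smoothing window")

    ts = track.timestamps_s
    nose = track.xy_cm("nose")
    ears = 0.5 * (track.xy_cm("ear_left") + track.xy_cm("ear_right"))
    head = _boxcar((nose + 2.0 * ears) / 3.0, smoothing_window_frames)
    tail = _boxcar(track.xy_cm("tailbase"), smoothing_window_frames)
    nose_s = _boxcar(nose, smoothing_window_frames)

    nt_dist = np.linalg.norm(nose_s - tail, axis=1)
    signed_v = None
    if threat_point is not None:
        dist = np.linalg.norm(head - np.asarray(threat_point, float), axis=1)
        dv = -np.diff(dist) / np.diff(ts)
        signed_v = np.append(dv, dv[-1]) if len(dv) else np.zeros(1)

    return KinematicsSeries(
        timestamps_s=ts,
        head_xy_cm=head,
        head_speed_cms=_forward_speed(head, ts),
        tailbase_speed_cms=_forward_speed(tail, ts),
        nose_tail_distance_cm=nt_dist,
        body_length_cm=float(np.median(nt_dist)),
        signed_velocity_to_threat_cms=signed_v,
        threat_point=tuple(threat_point) if threat_point is not None else None,
    )
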