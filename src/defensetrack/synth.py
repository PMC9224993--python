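"""Synthetic behavioral sessions with exact ground truth.

Generates pose tracks, interleaved two-channel photometry, condition
schedules and zone maps with the statistical structure the analysis assumes,
so every pipeline stage can be validated without any recorded videos.

Trajectories follow a semi-Markov state machine over
``{locomote, pause, freeze, sap, approach, escape, burrow_dwell}``; dwell
times are exponential except freeze bouts, which are log-normal (defensive
immobility has a heavy-tailed duration distribution, which the minimum-bout
robustness analysis needs).  Trajectories are engineered so the kinematic
behavior definitions hold *exactly* inside planted intervals and fail
outside them:

* corridor sessions evolve in polar coordinates around the threat point, so
  tangential states have identically zero signed velocity toward the threat
  and radial states exactly the planted run speed;
* the head centroid is steered directly and the ears are placed so that
  centroid(nose, ears) equals it identically;
* freezes hold every bodypart; stretch-attend postures freeze the tailbase,
  set the nose-tailbase distance to the planted stretch factor, and keep a
  small head drift so immobility is never co-detected.

Photometry: both channels share a double-exponential bleach and a smooth
multiplicative motion artifact; calcium transients (Poisson events convolved
with a rise/decay kernel) enter the 470-nm channel only.  The transient rate
is modulated by position along the corridor with a configurable sign:
``tuning_sign=-1`` mimics the CCK-like pattern (rate falls with distance
from the safe wall), ``+1`` the pan-neuronal pattern; ``tuning_mask="escape"``
restricts modulation to escape epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .arenas import ARENA_DIMS_CM, ZoneMap, make_zonemap
from .pose import BODYPARTS, PoseTrack
from .schedule import EpochSchedule, make_alternating_epochs

__all__ = [
    "StateParams",
    "TransientKernel",
    "BleachParams",
    "SimConfig",
    "GroundTruth",
    "SessionBundle",
    "simulate_session",
    "simulate_cohort",
    "freezing_robustness_cohort",
    "simulate_habituation",
    "simulate_lte_trial",
]

# ---------------------------------------------------------------------------
# configuration

#: planted head speed per state, cm/s (locomote/approach/escape sampled per bout)
_PAUSE_SPEED = 1.5  # above the 0.25 cm/s freeze threshold, below run threshold
_SAP_HEAD_SPEED = 0.5  # keeps SAP holds from being co-detected as freezing
_BURROW_SPEED = 1.0
_BODY_LEN_CM = 7.0
_HEAD_OFFSET = 0.8  # head centroid sits 0.8 body lengths ahead of tailbase
_EAR_HALFSPAN = 1.2
_R_MIN, _R_MAX = 10.0, 60.0  # corridor radial band around the threat point
_Y_BAND = 4.0  # corridor |y - midline| bound for the head
_RECT_MARGIN = 6.0  # head inset from walls in rectangular arenas

_ALLOWED_STATES = {
    "open_field": ("locomote", "pause", "freeze", "sap"),
    "lte": ("locomote", "pause", "freeze", "sap", "burrow_dwell"),
    "corridor": ("locomote", "pause", "freeze", "sap", "approach", "escape"),
    "epm": ("locomote", "pause", "freeze", "sap"),
    "rtpt": ("locomote", "pause"),
}


@dataclass(frozen=True)
class StateParams:
    """Mean dwell time (s) and relative transition weight of one state."""

    mean_dwell_s: float
    weight: float


def _default_state_rates(arena: str) -> dict[str, StateParams]:
    rates = {
        "locomote": StateParams(3.0, 3.0),
        "pause": StateParams(2.0, 2.0),
        "freeze": StateParams(2.0, 1.0),
        "sap": StateParams(1.5, 1.0),
    }
    if arena == "corridor":
        rates["locomote"] = StateParams(2.0, 2.0)
        rates["approach"] = StateParams(1.5, 2.0)
        rates["escape"] = StateParams(1.2, 2.0)
    if arena == "lte":
        rates["burrow_dwell"] = StateParams(8.0, 1.0)
    if arena == "rtpt":
        rates = {"locomote": StateParams(3.0, 3.0), "pause": StateParams(2.0, 2.0)}
    return rates


@dataclass(frozen=True)
class TransientKernel:
    """GCaMP6f-like difference-of-exponentials transient shape."""

    amplitude_dff: float = 0.05
    rise_s: float = 0.1
    decay_s: float = 1.0


@dataclass(frozen=True)
class BleachParams:
    """Double-exponential photobleaching, shared by both channels."""

    amp_fast: float = 0.15
    tau_fast_s: float = 60.0
    amp_slow: float = 0.10
    tau_slow_s: float = 600.0


@dataclass
class SimConfig:
    """Parameters of one synthetic session."""

    arena_name: str = "corridor"
    frame_rate_hz: float = 30.0
    duration_s: float = 600.0
    state_rates: dict[str, StateParams] | None = None
    freeze_bout_median_s: float = 2.0
    freeze_bout_sigma: float = 0.8
    locomotion_speed_cms: tuple[float, float] = (8.0, 1.5)
    sap_stretch_factor: float = 1.35  # planted stretch, above the 1.2 detector threshold
    tuning_sign: int = 0
    tuning_mask: str = "all"  # or "escape"
    tuning_depth: float = 0.8
    base_transient_rate_hz: float = 0.8
    transient_kernel: TransientKernel = field(default_factory=TransientKernel)
    bleach_params: BleachParams = field(default_factory=BleachParams)
    artifact_sd: float = 0.02
    noise_sd: float = 0.5  # absolute fluorescence units, signal channel
    noise_sd_reference: float | None = None  # defaults to noise_sd
    photometry_rate_hz: float = 20.0  # total, alternating channels
    channel_gain_470: float = 200.0
    channel_gain_405: float = 120.0
    dropout_prob: float = 0.0
    dropout_jitter_cm: float = 2.0
    epoch_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arena_name not in ARENA_DIMS_CM:
            raise ValueError(f"unknown arena {self.arena_name!r}")
        for name in ("frame_rate_hz", "duration_s", "freeze_bout_median_s", "freeze_bout_sigma",
                     "photometry_rate_hz", "epoch_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.base_transient_rate_hz < 0:
            raise ValueError("base_transient_rate_hz must be non-negative")
        if self.tuning_sign not in (-1, 0, 1):
            raise ValueError("tuning_sign must be -1, 0 or +1")
        if self.tuning_mask not in ("all", "escape"):
            raise ValueError("tuning_mask must be 'all' or 'escape'")
        if self.state_rates is None:
            self.state_rates = _default_state_rates(self.arena_name)
        bad = set(self.state_rates) - set(_ALLOWED_STATES[self.arena_name])
        if bad:
            raise ValueError(
                f"states {sorted(bad)} cannot occur in arena {self.arena_name!r}"
            )
        for s, p in self.state_rates.items():
            if not (p.mean_dwell_s > 0 and p.weight >= 0):
                raise ValueError(f"invalid rates for state {s!r}")


@dataclass
class GroundTruth:
    """Planted truth of one session.

    ``state_intervals`` are the planted behavior intervals (sorted,
    non-overlapping, inside [0, duration]); ``latent_rate``/``latent_dff``
    live on the 470-nm sample clock; ``zone_occupancy_s`` and
    ``entry_times`` are derived from the emitted trajectory with plain
    rectangle arithmetic, independent of the scoring code path.
    """

    state_intervals: list[tuple[str, float, float]]
    transient_times: np.ndarray
    latent_rate: np.ndarray
    latent_dff: np.ndarray
    entry_times: dict[str, np.ndarray]
    zone_occupancy_s: dict[str, float]
    signal_times_s: np.ndarray
    raw_multiplicative: np.ndarray  # bleach*(1+artifact) on the raw clock
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = {}
        for label, s, e in self.state_intervals:
            if e <= s or s < -1e-9:
                raise ValueError("state intervals must be positive-length and non-negative")
            if s < prev_end.get(label, -1) - 1e-9:
                raise ValueError("state intervals overlap within a label")
            prev_end[label] = e
        if np.any(np.diff(self.transient_times) < 0):
            raise ValueError("transient times must be sorted")

    def intervals(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for lab, s, e in self.state_intervals if lab == label]


class SessionBundle(NamedTuple):
    pose: PoseTrack
    photometry: pd.DataFrame
    schedule: EpochSchedule
    zonemap: ZoneMap
    ground_truth: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# state sequencing


def _avoid_truncated_freeze(state: str, n: int, cfg: SimConfig) -> str:
    """A freeze block cut below the 0.33-s definition is not a freeze bout;
    substitute a pause when one is available."""
    if state == "freeze" and n < _min_freeze_frames(cfg):
        for alt in ("pause", "locomote"):
            if alt in cfg.state_rates:
                return alt
    return state


def _min_freeze_frames(cfg: SimConfig) -> int:
    # planted freezes must satisfy the 0.33-s definition with >= 1 frame margin
    return int(math.ceil(0.33 * cfg.frame_rate_hz)) + 2


def _sample_dwell_frames(state: str, cfg: SimConfig, rng: np.random.Generator) -> int:
    if state == "freeze":
        dwell = float(rng.lognormal(math.log(cfg.freeze_bout_median_s), cfg.freeze_bout_sigma))
        return max(_min_freeze_frames(cfg), int(round(dwell * cfg.frame_rate_hz)))
    dwell = float(rng.exponential(cfg.state_rates[state].mean_dwell_s))
    return max(2, int(round(dwell * cfg.frame_rate_hz)))


def _next_state(current: str | None, cfg: SimConfig, rng: np.random.Generator) -> str:
    states = [s for s in cfg.state_rates if s != current and cfg.state_rates[s].weight > 0]
    if not states:  # degenerate single-state machine
        states = [s for s in cfg.state_rates if cfg.state_rates[s].weight > 0]
        if not states:
            raise ValueError("no state has positive weight")
    w = np.array([cfg.state_rates[s].weight for s in states])
    return states[rng.choice(len(states), p=w / w.sum())]


def _merge_adjacent(labels: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    merged: list[list] = []
    for lab, i0, i1 in labels:
        if merged and merged[-1][0] == lab and merged[-1][2] == i0:
            merged[-1][2] = i1
        else:
            merged.append([lab, i0, i1])
    return [tuple(m) for m in merged]


# ---------------------------------------------------------------------------
# trajectory engines.  Each returns (head, tail, nose, labels) with one row
# per frame; ears are derived afterwards so that centroid(nose, ears) == head.


def _corridor_engine(cfg: SimConfig, rng: np.random.Generator, n_frames: int):
    dt = 1.0 / cfg.frame_rate_hz
    lx, ly = ARENA_DIMS_CM["corridor"]
    cxy = np.array([lx, ly / 2.0])  # threat point: rat-wall midpoint
    b = _BODY_LEN_CM

    r, phi, s_tan = 35.0, 0.0, 1.0
    u = np.array([0.0, -1.0])
    e = b

    def pos(r_, phi_):
        return np.array([lx - r_ * math.cos(phi_), ly / 2.0 - r_ * math.sin(phi_)])

    head = np.empty((n_frames, 2))
    tail = np.empty((n_frames, 2))
    nose = np.empty((n_frames, 2))
    labels: list[tuple[str, int, int]] = []
    h = pos(r, phi)
    p = h - _HEAD_OFFSET * b * u
    i = 0
    state: str | None = None
    while i < n_frames:
        state = _next_state(state, cfg, rng)
        n = min(_sample_dwell_frames(state, cfg, rng), n_frames - i)
        state = _avoid_truncated_freeze(state, n, cfg)
        if state in ("approach", "escape"):
            v = float(np.clip(rng.normal(8.0, 1.5), 5.0, 11.0))
            if state == "approach":
                room = r - _R_MIN
            else:
                # escapes move along a fixed ray: keep the lateral offset
                # r*sin(phi) inside the corridor band while r grows
                r_band = _Y_BAND / max(abs(math.sin(phi)), 1e-9)
                room = min(_R_MAX, r_band) - r
            cap = int(room / (v * dt))
            if cap < 3:
                state = "locomote"  # no radial room; fall back to tangential motion
            else:
                n = min(n, cap)
        i0 = i
        if state == "freeze":
            for _ in range(n):
                head[i], tail[i], nose[i] = h, p, p + e * u
                i += 1
        elif state == "sap":
            e_sap = cfg.sap_stretch_factor * b
            u_hold = u.copy()
            p_hold = p.copy()
            for _ in range(n):
                phi, s_tan = _tan_step(phi, s_tan, r, _SAP_HEAD_SPEED, dt)
                h = pos(r, phi)
                head[i], tail[i], nose[i] = h, p_hold, p_hold + e_sap * u_hold
                i += 1
            p = p_hold
        elif state in ("approach", "escape"):
            sign = -1.0 if state == "approach" else 1.0
            for _ in range(n):
                r += sign * v * dt
                h = pos(r, phi)
                d = (cxy - h)
                u = d / np.linalg.norm(d) * (-sign)
                p = h - _HEAD_OFFSET * b * u
                head[i], tail[i], nose[i] = h, p, p + b * u
                i += 1
        else:  # locomote / pause: tangential, zero signed velocity to threat
            v = _PAUSE_SPEED if state == "pause" else float(
                np.clip(rng.normal(*cfg.locomotion_speed_cms), 4.0, 12.0)
            )
            for _ in range(n):
                prev = h
                phi, s_tan = _tan_step(phi, s_tan, r, v, dt)
                h = pos(r, phi)
                step = h - prev
                nrm = np.linalg.norm(step)
                if nrm > 1e-12:
                    u = step / nrm
                p = h - _HEAD_OFFSET * b * u
                head[i], tail[i], nose[i] = h, p, p + b * u
                i += 1
        labels.append((state, i0, i))
    return head, tail, nose, labels


def _tan_step(phi: float, s_tan: float, r: float, v: float, dt: float):
    phimax = math.asin(min(1.0, _Y_BAND / r))
    phi_new = phi + s_tan * v * dt / r
    if abs(phi_new) > phimax:
        s_tan = -s_tan
        phi_new = max(-phimax, min(phimax, phi_new))
    return phi_new, s_tan


def _rect_engine(
    cfg: SimConfig,
    rng: np.random.Generator,
    n_frames: int,
    scripted: list[tuple[str, int, dict]] | None = None,
):
    """Waypoint-walk engine for open_field / lte / rtpt.

    ``scripted`` optionally fixes the block sequence as (state, n_frames,
    options) tuples; options may carry a ``target_box`` restricting waypoint
    sampling (used for planted dwell schedules and LTE trials).
    """
    dt = 1.0 / cfg.frame_rate_hz
    lx, ly = ARENA_DIMS_CM[cfg.arena_name]
    m = _RECT_MARGIN
    default_box = (m, m, lx - m, ly - m)
    zm = make_zonemap(cfg.arena_name)
    burrow_box = None
    if "burrow" in zm.zones:
        x0, y0, x1, y1 = zm.zones["burrow"].bounds
        burrow_box = (x0 + 4.5, y0 + 2.5, x1 - 4.0, y1 - 2.5)
    b = _BODY_LEN_CM

    h = np.array([lx / 2.0, ly / 2.0])
    u = np.array([1.0, 0.0])
    p = h - _HEAD_OFFSET * b * u
    target = None

    def draw_target(box):
        return np.array([rng.uniform(box[0], box[2]), rng.uniform(box[1], box[3])])

    head = np.empty((n_frames, 2))
    tail = np.empty((n_frames, 2))
    nose = np.empty((n_frames, 2))
    labels: list[tuple[str, int, int]] = []
    i = 0
    state: str | None = None
    queue = list(scripted) if scripted is not None else None
    while i < n_frames:
        opts: dict = {}
        if queue is not None:
            if not queue:
                break
            state, n, opts = queue.pop(0)
            n = min(n, n_frames - i)
        else:
            state = _next_state(state, cfg, rng)
            n = min(_sample_dwell_frames(state, cfg, rng), n_frames - i)
            state = _avoid_truncated_freeze(state, n, cfg)
        i0 = i
        if state == "freeze":
            for _ in range(n):
                head[i], tail[i], nose[i] = h, p, p + b * u
                i += 1
        elif state == "sap":
            e_sap = cfg.sap_stretch_factor * b
            p_hold, u_hold = p.copy(), u.copy()
            drift = np.array([-u[1], u[0]])  # drift sideways, tail planted
            for _ in range(n):
                h2 = h + _SAP_HEAD_SPEED * dt * drift
                if not (default_box[0] <= h2[0] <= default_box[2] and default_box[1] <= h2[1] <= default_box[3]):
                    drift = -drift
                    h2 = h + _SAP_HEAD_SPEED * dt * drift
                h = h2
                head[i], tail[i], nose[i] = h, p_hold, p_hold + e_sap * u_hold
                i += 1
            p = p_hold
        else:
            if state == "burrow_dwell" and burrow_box is not None:
                box = burrow_box
                v = _BURROW_SPEED
            else:
                box = opts.get("target_box", default_box)
                v = (
                    _PAUSE_SPEED
                    if state == "pause"
                    else float(np.clip(rng.normal(*cfg.locomotion_speed_cms), 4.0, 12.0))
                )
                v = opts.get("speed", v)
            if state == "burrow_dwell":
                # walk into the burrow first, then drift inside it
                target = draw_target(box)
            for _ in range(n):
                if target is None or not (
                    box[0] - 1e-9 <= target[0] <= box[2] + 1e-9
                    and box[1] - 1e-9 <= target[1] <= box[3] + 1e-9
                ):
                    target = draw_target(box)
                d = target - h
                dist = np.linalg.norm(d)
                vf = v
                if state == "burrow_dwell" and dist > 4.0:
                    vf = 8.0  # walk briskly into the burrow, then drift inside
                step = vf * dt
                if dist <= step:
                    h = target.copy()
                    target = draw_target(box)
                else:
                    u = d / dist
                    h = h + step * u
                p = h - _HEAD_OFFSET * b * u
                head[i], tail[i], nose[i] = h, p, p + b * u
                i += 1
        labels.append((state, i0, i))
    return head[:i], tail[:i], nose[:i], labels


def _epm_engine(cfg: SimConfig, rng: np.random.Generator, n_frames: int):
    """Walk along the plus-maze centerlines through the hub."""
    dt = 1.0 / cfg.frame_rate_hz
    c = 33.5
    ends = {
        "open_arm_west": np.array([6.0, c]),
        "open_arm_east": np.array([61.0, c]),
        "closed_arm_south": np.array([c, 6.0]),
        "closed_arm_north": np.array([c, 61.0]),
    }
    center = np.array([c, c])
    b = _BODY_LEN_CM

    h = center.copy()
    u = np.array([1.0, 0.0])
    p = h - _HEAD_OFFSET * b * u
    route: list[np.ndarray] = []

    head = np.empty((n_frames, 2))
    tail = np.empty((n_frames, 2))
    nose = np.empty((n_frames, 2))
    labels: list[tuple[str, int, int]] = []
    i = 0
    state: str | None = None
    arm_names = list(ends)
    while i < n_frames:
        state = _next_state(state, cfg, rng)
        n = min(_sample_dwell_frames(state, cfg, rng), n_frames - i)
        state = _avoid_truncated_freeze(state, n, cfg)
        i0 = i
        if state == "freeze":
            for _ in range(n):
                head[i], tail[i], nose[i] = h, p, p + b * u
                i += 1
        elif state == "sap":
            e_sap = cfg.sap_stretch_factor * b
            p_hold, u_hold = p.copy(), u.copy()
            drift = u.copy()
            for _ in range(n):
                h = h + _SAP_HEAD_SPEED * dt * drift
                head[i], tail[i], nose[i] = h, p_hold, p_hold + e_sap * u_hold
                i += 1
            p = p_hold
        else:
            v = _PAUSE_SPEED if state == "pause" else float(
                np.clip(rng.normal(*cfg.locomotion_speed_cms), 4.0, 12.0)
            )
            for _ in range(n):
                if not route:
                    route = [center.copy(), ends[arm_names[rng.integers(len(arm_names))]].copy()]
                d = route[0] - h
                dist = np.linalg.norm(d)
                step = v * dt
                if dist <= step:
                    h = route.pop(0)
                else:
                    u = d / dist
                    h = h + step * u
                p = h - _HEAD_OFFSET * b * u
                head[i], tail[i], nose[i] = h, p, p + b * u
                i += 1
        labels.append((state, i0, i))
    return head, tail, nose, labels


# ---------------------------------------------------------------------------
# assembly


def _ears_from(head: np.ndarray, nose: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Place ears so that centroid(nose, ear_left, ear_right) == head exactly."""
    base = 0.5 * (3.0 * head - nose)
    axis = nose - base
    nrm = np.linalg.norm(axis, axis=1, keepdims=True)
    nrm[nrm < 1e-12] = 1.0
    perp = np.column_stack([-axis[:, 1], axis[:, 0]]) / nrm
    return base + _EAR_HALFSPAN * perp, base - _EAR_HALFSPAN * perp


def _make_pose(
    cfg: SimConfig,
    rng: np.random.Generator,
    ts: np.ndarray,
    head: np.ndarray,
    tail: np.ndarray,
    nose: np.ndarray,
) -> PoseTrack:
    ear_l, ear_r = _ears_from(head, nose)
    cols = {"frame": np.arange(len(ts)), "timestamp_s": ts}
    for bp, xy in zip(BODYPARTS, (nose, ear_l, ear_r, tail)):
        x, y = xy[:, 0].copy(), xy[:, 1].copy()
        lk = np.clip(rng.beta(20, 1, len(ts)), 0.0, 1.0)
        if cfg.dropout_prob > 0:
            drop = rng.random(len(ts)) < cfg.dropout_prob
            lk[drop] = rng.uniform(0.0, 0.5, drop.sum())
            x[drop] += rng.uniform(-cfg.dropout_jitter_cm, cfg.dropout_jitter_cm, drop.sum())
            y[drop] += rng.uniform(-cfg.dropout_jitter_cm, cfg.dropout_jitter_cm, drop.sum())
        cols[f"{bp}_x"], cols[f"{bp}_y"], cols[f"{bp}_likelihood"] = x, y, lk
    return PoseTrack(pd.DataFrame(cols), cm_per_px=1.0)


def _zone_truth(zonemap: ZoneMap, ts: np.ndarray, head: np.ndarray):
    """Occupancy seconds and entry times per zone by direct rectangle tests."""
    dt = float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
    dur = np.append(np.diff(ts), dt)
    occ, entries = {}, {}
    for name, poly in zonemap.zones.items():
        x0, y0, x1, y1 = poly.bounds
        inside = (
            (head[:, 0] >= x0) & (head[:, 0] <= x1) & (head[:, 1] >= y0) & (head[:, 1] <= y1)
        )
        occ[name] = float(dur[inside].sum())
        cross = np.flatnonzero(inside[1:] & ~inside[:-1]) + 1
        entries[name] = ts[cross]
    return occ, entries


def _simulate_photometry(
    cfg: SimConfig,
    rng: np.random.Generator,
    ts_frames: np.ndarray,
    head: np.ndarray,
    escape_mask_frames: np.ndarray,
    zonemap: ZoneMap,
):
    """Interleaved raw stream + latent truth.  Reference (405) leads."""
    dt_raw = 1.0 / cfg.photometry_rate_hz
    t_raw = np.arange(dt_raw / 2.0, cfg.duration_s, dt_raw)
    n_raw = len(t_raw)
    channels = np.where(np.arange(n_raw) % 2 == 0, 405, 470)
    t_sig = t_raw[channels == 470]

    bl = cfg.bleach_params
    bleach = 1.0 + bl.amp_fast * np.exp(-t_raw / bl.tau_fast_s) + bl.amp_slow * np.exp(
        -t_raw / bl.tau_slow_s
    )
    art = rng.standard_normal(n_raw)
    art = gaussian_filter1d(art, sigma=max(1.0, 0.3 / dt_raw))
    sd = art.std()
    art = cfg.artifact_sd * art / sd if sd > 0 else art * 0.0

    # transient rate on the signal clock, modulated by distance from the safe wall
    rate = np.full(len(t_sig), cfg.base_transient_rate_hz)
    if cfg.tuning_sign != 0 and cfg.arena_name == "corridor":
        lx = ARENA_DIMS_CM["corridor"][0]
        x_sig = np.interp(t_sig, ts_frames, head[:, 0])
        g = 2.0 * np.clip(x_sig / lx, 0.0, 1.0) - 1.0  # monotone in distance from safe wall
        mod = cfg.base_transient_rate_hz * (1.0 + cfg.tuning_sign * cfg.tuning_depth * g)
        if cfg.tuning_mask == "escape":
            esc = np.interp(t_sig, ts_frames, escape_mask_frames.astype(float)) > 0.5
            rate = np.where(esc, mod, rate)
        else:
            rate = mod
    rate = np.clip(rate, 0.0 if cfg.base_transient_rate_hz == 0 else 0.02, None)

    # inhomogeneous Poisson events by thinning
    lam_max = float(rate.max())
    n_cand = rng.poisson(lam_max * cfg.duration_s)
    cand = np.sort(rng.uniform(0.0, cfg.duration_s, n_cand))
    keep = rng.random(n_cand) < np.interp(cand, t_sig, rate) / lam_max
    events = cand[keep]

    # transient trace on the signal clock
    k = cfg.transient_kernel
    dt_sig = float(np.median(np.diff(t_sig))) if len(t_sig) > 1 else dt_raw * 2
    tk = np.arange(0.0, 5.0 * k.decay_s, dt_sig)
    kern = np.exp(-tk / k.decay_s) - np.exp(-tk / k.rise_s)
    if kern.max() > 0:
        kern = k.amplitude_dff * kern / kern.max()
    impulses = np.zeros(len(t_sig))
    idx = np.clip(np.searchsorted(t_sig, events), 0, len(t_sig) - 1)
    np.add.at(impulses, idx, 1.0)
    latent_dff = np.convolve(impulses, kern)[: len(t_sig)]

    mult = bleach * (1.0 + art)
    transients_raw = np.zeros(n_raw)
    transients_raw[channels == 470] = latent_dff
    gain = np.where(channels == 470, cfg.channel_gain_470, cfg.channel_gain_405)
    ref_sd = cfg.noise_sd if cfg.noise_sd_reference is None else cfg.noise_sd_reference
    noise_sd = np.where(channels == 470, cfg.noise_sd, ref_sd)
    values = gain * mult * (1.0 + transients_raw) + noise_sd * rng.standard_normal(n_raw)
    rec = pd.DataFrame({"timestamp_s": t_raw, "channel": channels, "value": values})
    return rec, events, rate, latent_dff, t_sig, mult


def simulate_session(config: SimConfig) -> SessionBundle:
    """Simulate one full session: pose, photometry, schedule, zones, truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fps = cfg.frame_rate_hz
    n_frames = int(round(cfg.duration_s * fps))
    if n_frames < 2:
        raise ValueError("duration too short for the configured frame rate")
    ts = np.arange(n_frames) / fps
    zonemap = make_zonemap(cfg.arena_name)

    if cfg.arena_name == "corridor":
        head, tail, nose, labels = _corridor_engine(cfg, rng, n_frames)
    elif cfg.arena_name == "epm":
        head, tail, nose, labels = _epm_engine(cfg, rng, n_frames)
    else:
        head, tail, nose, labels = _rect_engine(cfg, rng, n_frames)

    pose = _make_pose(cfg, rng, ts, head, tail, nose)
    labels = _merge_adjacent(labels)
    state_intervals = [(lab, i0 / fps, i1 / fps) for lab, i0, i1 in labels]
    escape_mask = np.zeros(n_frames, bool)
    for lab, i0, i1 in labels:
        if lab == "escape":
            escape_mask[i0:i1] = True

    rec, events, rate, latent_dff, t_sig, mult = _simulate_photometry(
        cfg, rng, ts, head, escape_mask, zonemap
    )
    occ, entries = _zone_truth(zonemap, ts, head)

    epoch_s = min(cfg.epoch_s, cfg.duration_s / 2.0)
    schedule = make_alternating_epochs(epoch_s, max(2, int(cfg.duration_s // epoch_s)))

    gt = GroundTruth(
        state_intervals=state_intervals,
        transient_times=events,
        latent_rate=rate,
        latent_dff=latent_dff,
        entry_times=entries,
        zone_occupancy_s=occ,
        signal_times_s=t_sig,
        raw_multiplicative=mult,
        extras={"head_xy_cm": head, "tailbase_xy_cm": tail},
    )
    return SessionBundle(pose, rec, schedule, zonemap, gt, cfg)


# ---------------------------------------------------------------------------
# cohorts and scripted sessions


def simulate_cohort(
    config_list: list[SimConfig],
    n_per_group: int,
    seed: int,
    group_labels: list[str] | None = None,
) -> list[dict]:
    """Independent seeded sessions for each config, ``n_per_group`` each.

    Returns a list of dicts with ``session_id``, ``group`` and ``bundle``.
    Session seeds derive from ``seed`` so the cohort is reproducible.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    labels = group_labels or [f"group{j}" for j in range(len(config_list))]
    if len(labels) != len(config_list) or len(set(labels)) != len(labels):
        raise ValueError("duplicate or mismatched group labels")
    rng = np.random.default_rng(seed)
    out = []
    seen = set()
    for label, cfg in zip(labels, config_list):
        for i in range(n_per_group):
            sid = f"{label}_{i:03d}"
            if sid in seen:
                raise ValueError(f"duplicate session identifier {sid}")
            seen.add(sid)
            s_cfg = replace(cfg, seed=int(rng.integers(2**31)))
            out.append({"session_id": sid, "group": label, "bundle": simulate_session(s_cfg)})
    return out


def freezing_robustness_cohort(
    n_sessions: int = 40,
    duration_s: float = 600.0,
    seed: int = 0,
    freeze_median_s: float = 2.0,
    freeze_sigma: float = 0.8,
    propensity_range: tuple[float, float] = (0.10, 0.60),
) -> list[SessionBundle]:
    """Open-field sessions with heterogeneous per-session freezing propensity.

    Each session's target freezing fraction is drawn uniformly from
    ``propensity_range`` and converted to a freeze transition weight through
    the semi-Markov occupancy identity (weight x mean dwell over the total)."""
    rng = np.random.default_rng(seed)
    base = _default_state_rates("open_field")
    other = sum(p.weight * p.mean_dwell_s for s, p in base.items() if s != "freeze")
    e_freeze = freeze_median_s * math.exp(freeze_sigma**2 / 2.0)
    bundles = []
    for _ in range(n_sessions):
        f = rng.uniform(*propensity_range)
        w = f * other / ((1.0 - f) * e_freeze)
        rates = dict(base)
        rates["freeze"] = StateParams(e_freeze, w)
        cfg = SimConfig(
            arena_name="open_field",
            duration_s=duration_s,
            state_rates=rates,
            freeze_bout_median_s=freeze_median_s,
            freeze_bout_sigma=freeze_sigma,
            seed=int(rng.integers(2**31)),
        )
        bundles.append(simulate_session(cfg))
    return bundles


def simulate_habituation(
    prefers_burrow: bool, seed: int = 0, duration_s: float = 600.0
) -> tuple[SessionBundle, dict]:
    """LTE habituation with a planted burrow-vs-corner preference.

    Dwell schedules are engineered with a wide margin (the burrow exceeds, or
    a favored corner matches-or-exceeds, every competitor by >= 20 s), so the
    realized occupancy reproduces the intent despite travel time.  Returns
    the bundle and the planted dwell seconds per zone.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(arena_name="lte", duration_s=duration_s, seed=int(rng.integers(2**31)))
    zm = make_zonemap("lte")
    corners = [z for z in zm.zone_names() if z.startswith("corner_")]
    corner_s = {c: float(rng.uniform(30.0, 70.0)) for c in corners}
    if prefers_burrow:
        burrow_s = max(corner_s.values()) + float(rng.uniform(40.0, 90.0))
    else:
        burrow_s = float(rng.uniform(30.0, 60.0))
        favored = corners[int(rng.integers(len(corners)))]
        corner_s[favored] = burrow_s + float(rng.uniform(30.0, 60.0))
    planted = {"burrow": burrow_s, **corner_s}

    fps = cfg.frame_rate_hz
    inset = 4.0
    boxes = {}
    for z in ["burrow"] + corners:
        x0, y0, x1, y1 = zm.zones[z].bounds
        if z == "burrow":
            boxes[z] = (x0 + 4.5, y0 + 2.5, x1 - 4.0, y1 - 2.5)
        else:
            boxes[z] = (x0 + inset, y0 + inset, x1 - inset, y1 - inset)
    lx, ly = ARENA_DIMS_CM["lte"]
    mid_box = (0.34 * lx, 0.34 * ly, 0.66 * lx, 0.66 * ly)

    script: list[tuple[str, int, dict]] = []
    order = ["burrow"] + corners
    rng.shuffle(order)
    for z in order:
        # travel toward the zone, then drift inside it for the planted dwell
        script.append(("locomote", int(3.5 * fps), {"target_box": boxes[z], "speed": 10.0}))
        script.append(("pause", int(planted[z] * fps), {"target_box": boxes[z]}))
        script.append(("locomote", int(3.5 * fps), {"target_box": mid_box, "speed": 10.0}))
    script.append(("locomote", 10**9, {"target_box": mid_box}))

    n_frames = int(round(duration_s * fps))
    ts = np.arange(n_frames) / fps
    head, tail, nose, labels = _rect_engine(cfg, np.random.default_rng(cfg.seed), n_frames, script)
    pose = _make_pose(cfg, np.random.default_rng(cfg.seed + 1), ts, head, tail, nose)
    occ, entries = _zone_truth(zm, ts, head)
    gt = GroundTruth(
        state_intervals=[(lab, i0 / fps, i1 / fps) for lab, i0, i1 in labels],
        transient_times=np.array([]),
        latent_rate=np.array([]),
        latent_dff=np.array([]),
        entry_times=entries,
        zone_occupancy_s=occ,
        signal_times_s=np.array([]),
        raw_multiplicative=np.array([]),
        extras={"head_xy_cm": head, "prefers_burrow": prefers_burrow},
    )
    schedule = make_alternating_epochs(duration_s / 2.0, 2)
    return SessionBundle(pose, pd.DataFrame(), schedule, zm, gt, cfg), planted


def simulate_lte_trial(
    entry_latency_s: float | None,
    seed: int = 0,
    trial_limit_s: float = 60.0,
    frame_rate_hz: float = 30.0,
) -> tuple[PoseTrack, ZoneMap, float | None]:
    """One LTE trial segment starting at barrier removal.

    With ``entry_latency_s`` set, the trajectory wanders away from the burrow
    and first crosses the burrow boundary at (within one frame of) that
    latency; with ``None`` it avoids the burrow for the whole trial.
    """
    if entry_latency_s is not None and not 0 < entry_latency_s <= trial_limit_s:
        raise ValueError("entry latency must lie in (0, trial_limit_s]")
    rng = np.random.default_rng(seed)
    zm = make_zonemap("lte")
    lx, ly = ARENA_DIMS_CM["lte"]
    fps = frame_rate_hz
    dt = 1.0 / fps
    duration = trial_limit_s + 3.0
    n_frames = int(round(duration * fps))
    ts = np.arange(n_frames) / fps

    bx0, by0, bx1, by1 = zm.zones["burrow"].bounds
    # wander region well clear of the burrow (burrow sits in the SW corner)
    wander = (20.0, 14.0, lx - _RECT_MARGIN, ly - _RECT_MARGIN)
    h = np.array([lx - 8.0, ly - 8.0])  # released from the holding corner
    target = np.array([rng.uniform(wander[0], wander[2]), rng.uniform(wander[1], wander[3])])
    v_wander = 8.0
    # approach the burrow from directly above its top edge, then descend
    # vertically so the boundary crossing is timed to the planted latency
    staging = np.array([0.5 * (bx0 + bx1) + 1.5, by1 + 6.0])
    descend_s = 0.6
    deep_goal = np.array([bx0 + 4.5, by0 + 2.5])

    head = np.empty((n_frames, 2))
    mode = "wander"
    for i in range(n_frames):
        t = i * dt
        t_left = (entry_latency_s - t) if entry_latency_s is not None else np.inf
        if mode == "wander" and np.isfinite(t_left):
            t_stage = np.linalg.norm(staging - h) / v_wander
            if t_left <= t_stage + descend_s + 2 * dt:
                mode = "stage"
                v_stage = float(np.clip(np.linalg.norm(staging - h) / max(t_left - descend_s, dt), 4.0, 80.0))
        if mode == "wander":
            d = target - h
            dist = np.linalg.norm(d)
            if dist <= v_wander * dt:
                h = target.copy()
                target = np.array(
                    [rng.uniform(wander[0], wander[2]), rng.uniform(wander[1], wander[3])]
                )
            else:
                h = h + v_wander * dt * d / dist
        elif mode == "stage":
            d = staging - h
            dist = np.linalg.norm(d)
            if dist <= v_stage * dt:
                h = staging.copy()
                if t_left > descend_s + dt:
                    mode = "hover"
                else:
                    mode = "descend"
                    v_desc = (h[1] - by1) / max(t_left, dt)
            else:
                h = h + v_stage * dt * d / dist
        elif mode == "hover":
            h = h + np.array([1.5 * dt, 0.0]) * (1 if (i % 20) < 10 else -1)
            if t_left <= descend_s + dt:
                mode = "descend"
                v_desc = (h[1] - by1) / max(t_left, dt)
        elif mode == "descend":
            h = h + np.array([0.0, -v_desc * dt])
            if h[1] <= by1:
                mode = "inside"
        else:  # settle deeper into the burrow
            d = deep_goal - h
            dist = np.linalg.norm(d)
            if dist > 1e-6:
                h = h + min(dist, 2.0 * dt) * d / dist
        head[i] = h

    disp = np.diff(head, axis=0)
    nrm = np.linalg.norm(disp, axis=1, keepdims=True)
    nrm[nrm < 1e-12] = 1.0
    dirs = np.vstack([disp / nrm, (disp / nrm)[-1:]])
    tail = head - _HEAD_OFFSET * _BODY_LEN_CM * dirs
    nose = tail + _BODY_LEN_CM * dirs
    pose = _make_pose(
        SimConfig(arena_name="lte", duration_s=duration, frame_rate_hz=fps, seed=seed),
        rng,
        ts,
        head,
        tail,
        nose,
    )
    return pose, zm, entry_latency_s


def simulate_rtpt_session(
    stim_frac: float, seed: int = 0, duration_s: float = 600.0
) -> tuple[SessionBundle, float]:
    """Two-chamber place-test session with a planted stim-chamber occupancy.

    The walk alternates planted dwell blocks between the two chambers so
    that roughly ``stim_frac`` of the session is spent in the stimulated
    chamber.  Returns the bundle and the realized stim-chamber fraction
    (computed from the emitted trajectory by rectangle arithmetic).
    """
    if not 0.05 <= stim_frac <= 0.95:
        raise ValueError("stim_frac must lie in [0.05, 0.95]")
    rng = np.random.default_rng(seed)
    cfg = SimConfig(arena_name="rtpt", duration_s=duration_s, seed=int(rng.integers(2**31)))
    zm = make_zonemap("rtpt")
    lx, ly = ARENA_DIMS_CM["rtpt"]
    m = _RECT_MARGIN
    stim_box = (m, m, lx / 2 - 2.0, ly - m)
    nostim_box = (lx / 2 + 2.0, m, lx - m, ly - m)
    block_s = 20.0
    fps = cfg.frame_rate_hz
    n_blocks = max(2, int(round(duration_s / block_s)))
    n_stim = int(round(stim_frac * n_blocks))
    flags = np.array([True] * n_stim + [False] * (n_blocks - n_stim))
    rng.shuffle(flags)
    script: list[tuple[str, int, dict]] = [
        ("locomote", int(block_s * fps), {"target_box": stim_box if f else nostim_box})
        for f in flags
    ]
    n_frames = int(round(duration_s * fps))
    ts = np.arange(n_frames) / fps
    head, tail, nose, labels = _rect_engine(cfg, np.random.default_rng(cfg.seed), n_frames, script)
    pose = _make_pose(cfg, np.random.default_rng(cfg.seed + 1), ts, head, tail, nose)
    occ, entries = _zone_truth(zm, ts, head)
    gt = GroundTruth(
        state_intervals=[(lab, i0 / fps, i1 / fps) for lab, i0, i1 in _merge_adjacent(labels)],
        transient_times=np.array([]),
        latent_rate=np.array([]),
        latent_dff=np.array([]),
        entry_times=entries,
        zone_occupancy_s=occ,
        signal_times_s=np.array([]),
        raw_multiplicative=np.array([]),
        extras={"head_xy_cm": head},
    )
    schedule = make_alternating_epochs(duration_s / 2.0, 2)
    bundle = SessionBundle(pose, pd.DataFrame(), schedule, zm, gt, cfg)
    return bundle, occ["stim_chamber"] / duration_s
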