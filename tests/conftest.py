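"""Shared fixtures: simulated sessions reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from defensetrack import compute_kinematics
from defensetrack.pose import BODYPARTS, PoseTrack
from defensetrack.synth import SimConfig, simulate_session


def make_track(head_xy, tail_xy=None, nose_xy=None, fps=30.0, likelihood=1.0):
    """Build a PoseTrack from explicit coordinates (ears flank the nose)."""
    head_xy = np.asarray(head_xy, float)
    n = len(head_xy)
    tail_xy = np.asarray(tail_xy, float) if tail_xy is not None else head_xy - [5.0, 0.0]
    nose_xy = np.asarray(nose_xy, float) if nose_xy is not None else head_xy + [1.5, 0.0]
    base = 0.5 * (3.0 * head_xy - nose_xy)
    axis = nose_xy - base
    nrm = np.linalg.norm(axis, axis=1, keepdims=True)
    nrm[nrm < 1e-12] = 1.0
    perp = np.column_stack([-axis[:, 1], axis[:, 0]]) / nrm
    parts = {
        "nose": nose_xy,
        "ear_left": base + 1.2 * perp,
        "ear_right": base - 1.2 * perp,
        "tailbase": tail_xy,
    }
    cols = {"frame": np.arange(n), "timestamp_s": np.arange(n) / fps}
    for bp in BODYPARTS:
        cols[f"{bp}_x"] = parts[bp][:, 0]
        cols[f"{bp}_y"] = parts[bp][:, 1]
        cols[f"{bp}_likelihood"] = np.full(n, likelihood)
    return PoseTrack(pd.DataFrame(cols))


@pytest.fixture(scope="session")
def corridor_bundle():
    """Corridor session with all four behavior states and CCK-like tuning."""
    return simulate_session(SimConfig(arena_name="corridor", duration_s=180.0, seed=11,
                                      tuning_sign=-1))


@pytest.fixture(scope="session")
def corridor_kin(corridor_bundle):
    return compute_kinematics(
        corridor_bundle.pose, smoothing_window_frames=1,
        threat_point=corridor_bundle.zonemap.threat_point,
    )


@pytest.fixture(scope="session")
def openfield_bundle():
    return simulate_session(SimConfig(arena_name="open_field", duration_s=120.0, seed=5))
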