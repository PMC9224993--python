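"""Plain-text readers/writers for the pipeline's file formats.

Pose tables and photometry recordings travel as CSV, zone maps and
schedules as JSON (see :mod:`defensetrack.arenas` and
:mod:`defensetrack.schedule` for those), bout tables and session summaries
as CSV.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .behavior import BOUT_COLUMNS
from .photometry import REFERENCE_CHANNEL, SIGNAL_CHANNEL

__all__ = [
    "read_photometry_csv",
    "write_photometry_csv",
    "read_bouts_csv",
    "write_bouts_csv",
    "write_ground_truth_json",
]


def write_photometry_csv(recording: pd.DataFrame, path) -> None:
    recording[["timestamp_s", "channel", "value"]].to_csv(path, index=False)


def read_photometry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("timestamp_s", "channel", "value"):
        if c not in df.columns:
            raise ValueError(f"photometry file {path} missing column {c!r}")
    bad = set(df["channel"].unique()) - {SIGNAL_CHANNEL, REFERENCE_CHANNEL}
    if bad:
        raise ValueError(f"unknown photometry channel tags {bad} in {path}")
    return df


def write_bouts_csv(bouts: pd.DataFrame, path) -> None:
    bouts[BOUT_COLUMNS].to_csv(path, index=False)


def read_bouts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bout table {path} missing columns {missing}")
    return df


def write_ground_truth_json(gt, path) -> None:
    """Serialize a synthetic session's ground truth (arrays as lists)."""
    d = {
        "state_intervals": [[lab, float(s), float(e)] for lab, s, e in gt.state_intervals],
        "transient_times": np.asarray(gt.transient_times, float).tolist(),
        "entry_times": {k: np.asarray(v, float).tolist() for k, v in gt.entry_times.items()},
        "zone_occupancy_s": gt.zone_occupancy_s,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)
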