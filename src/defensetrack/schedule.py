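"""Condition schedules: laser ON/OFF epochs and drug condition labels.

An :class:`EpochSchedule` is an ordered list of labeled, non-overlapping
intervals.  Helpers build the standard protocols: alternating 2-min OFF/ON
epochs (open field, predator exposure, EPM) and the 10-trial alternating
laser schedule of the latency-to-enter assay (which always begins with a
light-off trial).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EpochSchedule", "make_alternating_epochs", "make_lte_trials"]


@dataclass
class EpochSchedule:
    """Ordered (condition, start_s, end_s) intervals for contrast statistics."""

    intervals: pd.DataFrame  # columns: condition, start_s, end_s

    def __post_init__(self) -> None:
        df = self.intervals
        for c in ("condition", "start_s", "end_s"):
            if c not in df.columns:
                raise ValueError(f"schedule missing column {c!r}")
        if len(df) and np.any(df["end_s"].to_numpy() <= df["start_s"].to_numpy()):
            raise ValueError("schedule intervals must have end_s > start_s")
        starts = df["start_s"].to_numpy()
        ends = df["end_s"].to_numpy()
        if len(df) > 1 and np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("schedule intervals overlap or are unsorted")

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.intervals["condition"]))

    def condition_intervals(self, condition: str) -> np.ndarray:
        sel = self.intervals[self.intervals["condition"] == condition]
        return sel[["start_s", "end_s"]].to_numpy(float)

    def head(self, n_epochs: int) -> "EpochSchedule":
        """Schedule restricted to the first ``n_epochs`` intervals (e.g. the
        EPM convention of analyzing only the first four of five epochs)."""
        return EpochSchedule(self.intervals.iloc[:n_epochs].reset_index(drop=True))

    def mask(self, timestamps_s: np.ndarray, condition: str) -> np.ndarray:
        """Boolean frame mask for one condition (start inclusive, end exclusive)."""
        t = np.asarray(timestamps_s, float)
        m = np.zeros(t.shape, bool)
        for s, e in self.condition_intervals(condition):
            m |= (t >= s) & (t < e)
        return m

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"intervals": self.intervals.to_dict("records")}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EpochSchedule":
        with open(path) as fh:
            return cls(pd.DataFrame(json.load(fh)["intervals"]))


def make_alternating_epochs(
    epoch_s: float = 120.0,
    n_epochs: int = 4,
    labels: tuple[str, str] = ("OFF", "ON"),
    start_s: float = 0.0,
) -> EpochSchedule:
    """Alternating fixed-duration epochs beginning with ``labels[0]`` (OFF)."""
    rows = [
        {"condition": labels[i % 2], "start_s": start_s + i * epoch_s, "end_s": start_s + (i + 1) * epoch_s}
        for i in range(n_epochs)
    ]
    return EpochSchedule(pd.DataFrame(rows))


def make_lte_trials(barrier_removal_s: list[float], trial_limit_s: float = 60.0) -> pd.DataFrame:
    """Trial table for the 10-trial LTE protocol, laser alternating OFF first.

    Returns one row per trial with ``trial_index`` (1-based), ``laser_on``,
    and ``barrier_removal_s``; latencies are filled in by the scorer.
    """
    if len(barrier_removal_s) != 10:
        raise ValueError("the LTE protocol has exactly 10 trials")
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, 11),
            "laser_on": [bool(i % 2) for i in range(10)],
            "barrier_removal_s": np.asarray(barrier_removal_s, float),
            "trial_limit_s": trial_limit_s,
        }
    )
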