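"""Per-scan temporal metrics of state expression: fractional occupancy,
dwell times, switching rate.

Labels are 1-based state indices, one per retained volume.  Metrics are
computed per scan; group-level statistics operate on these scan-level
values downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusteringSolution, EigenvectorStack
from .exceptions import ValidationError

__all__ = [
    "StateOccupancyTable",
    "fractional_occupancy",
    "dwell_times",
    "switching_rate",
    "occupancy_table",
]


def _check_labels(labels: np.ndarray, K: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or labels.size < 1:
        raise ValidationError("labels must be a non-empty 1-D sequence")
    if labels.min() < 1 or labels.max() > K:
        raise ValidationError(f"labels must lie in 1..{K}")
    return labels


def fractional_occupancy(labels: np.ndarray, K: int) -> np.ndarray:
    """Proportion of volumes assigned to each of the K states.

    ``FO[k-1] = #{t : label_t = k} / len(labels)``; sums to 1.
    """
    labels = _check_labels(labels, K)
    counts = np.bincount(labels - 1, minlength=K)
    return counts / labels.size


def _run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) of each maximal consecutive run."""
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return labels[starts], ends - starts


def dwell_times(labels: np.ndarray, K: int, tr: float) -> np.ndarray:
    """Mean duration (seconds) of maximal consecutive runs of each state.

    Runs truncated by the scan boundaries count in full.  States never
    visited get NaN.
    """
    labels = _check_labels(labels, K)
    states, lengths = _run_lengths(labels)
    out = np.full(K, np.nan)
    for k in range(1, K + 1):
        mask = states == k
        if mask.any():
            out[k - 1] = lengths[mask].mean() * tr
    return out


def switching_rate(labels: np.ndarray, tr: float) -> float:
    """State transitions per second: #{t: l_{t+1} != l_t} / ((T-1) TR)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise ValidationError("switching rate needs at least 2 volumes")
    n_switch = int(np.count_nonzero(np.diff(labels)))
    return n_switch / ((labels.size - 1) * tr)


@dataclass
class StateOccupancyTable:
    """Fractional occupancy per scan (rows) and state (columns) for one K."""

    FO: np.ndarray
    scan_ids: list[str]
    groups: list[str]
    K: int

    def __post_init__(self) -> None:
        if self.FO.shape != (len(self.scan_ids), self.K):
            raise ValidationError("FO must be scans x K")
        if np.abs(self.FO.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValidationError("every FO row must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        """Long format: scan_id, group, K, state, FO."""
        records = [
            (sid, grp, self.K, k + 1, self.FO[i, k])
            for i, (sid, grp) in enumerate(zip(self.scan_ids, self.groups))
            for k in range(self.K)
        ]
        return pd.DataFrame(records, columns=["scan_id", "group", "K", "state", "FO"])


def occupancy_table(
    solution: ClusteringSolution, stack: EigenvectorStack
) -> StateOccupancyTable:
    """Per-scan fractional occupancy under one clustering solution."""
    scan_ids = stack.scan_ids
    group_of_scan = {}
    for sid, grp in zip(stack.scan_of_row, stack.group_of_row):
        group_of_scan.setdefault(sid, grp)
    FO = np.empty((len(scan_ids), solution.K))
    for i, sid in enumerate(scan_ids):
        mask = stack.scan_of_row == sid
        FO[i] = fractional_occupancy(solution.labels[mask], solution.K)
    return StateOccupancyTable(
        FO=FO,
        scan_ids=scan_ids,
        groups=[group_of_scan[s] for s in scan_ids],
        K=solution.K,
    )
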