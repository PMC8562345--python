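"""Discrete-response indices.

* **coincidence index** — fraction of deliveries with the subject inside the
  dispenser zone (10-cm radius by default) at some point during the 3-s
  availability window;
* **intensity index** — per-session head-entry count normalized by the
  maximum count over all sessions of the same subject and dispenser;
* **precision index** — fraction of a session's head entries to a dispenser
  that fall inside an availability window of that dispenser;
* **proportion contacted** — fraction of deliveries followed by at least one
  head entry during the availability window;
* **percentile filter** — drops per-session values below a low percentile
  (default 5) within each subject-dispenser series, to palliate floor or
  ceiling effects.

Undefined ratios (no deliveries, no entries, an all-zero count series) are
reported as missing (NaN), never as 0.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .session_io import ArenaSpec, Event, Trajectory

__all__ = [
    "coincidence_index",
    "intensity_index",
    "precision_index",
    "proportion_contacted",
    "percentile_filter",
]


def coincidence_index(
    traj: Trajectory,
    deliveries,
    arena: ArenaSpec,
    dispenser: str,
    radius: float = 10.0,
    window: float = 3.0,
    min_dwell_frames: int = 1,
    at_onset_only: bool = False,
) -> float:
    """Fraction of deliveries with the subject inside ``radius`` of the
    dispenser during the availability window [onset, onset + window].

    ``min_dwell_frames`` sets how many sampled frames inside the radius count
    as presence (default 1). ``at_onset_only=True`` instead checks only the
    sample at (or just before) the delivery onset. Returns NaN when the
    session has no deliveries to the dispenser.
    """
    dx, dy = arena.landmark(dispenser)
    onsets = [e.onset for e in deliveries if e.kind == "delivery" and e.dispenser == dispenser]
    if not onsets:
        return math.nan
    dist = np.hypot(traj.x - dx, traj.y - dy)
    inside = dist <= radius
    hits = 0
    for onset in onsets:
        if at_onset_only:
            idx = int(np.searchsorted(traj.t, onset + 1e-12, side="right")) - 1
            if idx >= 0 and inside[idx]:
                hits += 1
            continue
        lo = int(np.searchsorted(traj.t, onset - 1e-9, side="left"))
        hi = int(np.searchsorted(traj.t, onset + window + 1e-9, side="right"))
        if int(inside[lo:hi].sum()) >= min_dwell_frames:
            hits += 1
    return hits / len(onsets)


def intensity_index(entry_counts) -> np.ndarray:
    """Normalize a subject-dispenser series of per-session head-entry counts
    by its maximum, so the busiest session scores 1.0.

    An all-zero series is undefined (0/0) and returns NaN throughout, with a
    warning.
    """
    counts = np.asarray(entry_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("entry counts must be >= 0")
    peak = counts.max() if counts.size else 0.0
    if peak == 0:
        warnings.warn("all-zero entry-count series: intensity undefined", stacklevel=2)
        return np.full_like(counts, np.nan)
    return counts / peak


def _in_any_window(onset: float, starts: np.ndarray, window: float) -> bool:
    idx = int(np.searchsorted(starts, onset + 1e-12, side="right")) - 1
    return idx >= 0 and onset <= starts[idx] + window + 1e-12


def precision_index(entries, deliveries, dispenser: str, window: float = 3.0) -> float:
    """Fraction of head entries to ``dispenser`` that occur while its
    commodity is available. NaN when the session has no entries there."""
    entry_onsets = [e.onset for e in entries if e.kind == "head_entry" and e.dispenser == dispenser]
    if not entry_onsets:
        return math.nan
    starts = np.sort(
        [e.onset for e in deliveries if e.kind == "delivery" and e.dispenser == dispenser]
    )
    hits = sum(_in_any_window(t, starts, window) for t in entry_onsets)
    return hits / len(entry_onsets)


def proportion_contacted(deliveries, entries, dispenser: str, window: float = 3.0) -> float:
    """Fraction of deliveries followed by >= 1 head entry to the same
    dispenser during the availability window. NaN with zero deliveries."""
    delivery_onsets = [
        e.onset for e in deliveries if e.kind == "delivery" and e.dispenser == dispenser
    ]
    if not delivery_onsets:
        return math.nan
    entry_onsets = np.sort(
        [e.onset for e in entries if e.kind == "head_entry" and e.dispenser == dispenser]
    )
    contacted = 0
    for onset in delivery_onsets:
        lo = int(np.searchsorted(entry_onsets, onset - 1e-12, side="left"))
        hi = int(np.searchsorted(entry_onsets, onset + window + 1e-12, side="right"))
        if hi > lo:
            contacted += 1
    return contacted / len(delivery_onsets)


def percentile_filter(values, p: float = 5.0) -> np.ndarray:
    """Boolean retention mask: False for values strictly below the p-th
    percentile (linear interpolation between order statistics)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile_filter needs at least one value")
    threshold = np.percentile(values, p)
    return values >= threshold
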