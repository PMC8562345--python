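"""First-order spatial measures per session.

Traveled distance, per-frame velocity, distance-to-landmark series (absolute
cm or relative to the maximum possible distance), trailing moving-average
smoothing, and subject location at event onsets (e.g., location at the
moment of water delivery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session_io import ArenaSpec, Event, SessionRecord, Trajectory

__all__ = [
    "DistanceSeries",
    "KinematicsSummary",
    "traveled_distance",
    "step_lengths",
    "max_velocity",
    "distance_series",
    "moving_average",
    "locations_at_events",
    "kinematics_summary",
]


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame distance to a landmark.

    ``mode="absolute"`` is in cm; ``mode="relative"`` divides by the maximum
    possible distance (landmark to the farthest arena corner), so values close
    to 1 mean the subject is as far from the landmark as the arena allows and
    values close to 0 mean it is at the landmark.
    """

    values: np.ndarray
    mode: str
    landmark: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class KinematicsSummary:
    traveled_distance: float
    max_velocity: float
    mean_distance: dict[str, float]  # landmark -> mean relative distance
    mean_distance_cm: dict[str, float]  # landmark -> mean absolute distance


def step_lengths(traj: Trajectory) -> np.ndarray:
    """Euclidean length of each inter-frame step, cm (length T-1)."""
    return np.hypot(np.diff(traj.x), np.diff(traj.y))


def traveled_distance(traj: Trajectory) -> float:
    """Total path length: the sum of Euclidean step lengths, in cm."""
    return float(step_lengths(traj).sum())


def max_velocity(traj: Trajectory) -> float:
    """Maximum per-frame speed (step length / dt), in cm/s."""
    return float(step_lengths(traj).max() / traj.dt)


def landmark_max_distance(arena: ArenaSpec, landmark: str) -> float:
    """Distance from a landmark to its farthest arena corner."""
    lx, ly = arena.landmark(landmark)
    corners = [(0.0, 0.0), (arena.width, 0.0), (0.0, arena.height), (arena.width, arena.height)]
    return max(np.hypot(lx - cx, ly - cy) for cx, cy in corners)


def distance_series(
    traj: Trajectory, arena: ArenaSpec, landmark: str, mode: str = "relative"
) -> DistanceSeries:
    """Per-frame Euclidean distance from the subject to a named landmark."""
    lx, ly = arena.landmark(landmark)
    d = np.hypot(traj.x - lx, traj.y - ly)
    if mode == "relative":
        d = d / landmark_max_distance(arena, landmark)
    elif mode != "absolute":
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceSeries(values=d, mode=mode, landmark=landmark)


def moving_average(series: DistanceSeries | np.ndarray, window: int = 200):
    """Trailing (causal) moving average; partial windows at the start.

    Frame i averages frames max(0, i-window+1)..i, so the output has the same
    length as the input. The default window of 200 frames is 40 s at 5 Hz.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series, dtype=float)
    smoothed = pd.Series(values).rolling(window, min_periods=1).mean().to_numpy()
    if isinstance(series, DistanceSeries):
        return DistanceSeries(values=smoothed, mode=series.mode, landmark=series.landmark)
    return smoothed


def locations_at_events(
    traj: Trajectory, events, kind: str, dispenser: str | None = None
) -> list[tuple[float, float]]:
    """Subject position at each event onset (sample at or before the onset).

    At 5 Hz the at-or-before sample is within 0.2 s of the true onset, so no
    interpolation is performed.
    """
    out: list[tuple[float, float]] = []
    for e in events:
        if e.kind != kind:
            continue
        if dispenser is not None and e.dispenser != dispenser:
            continue
        idx = int(np.searchsorted(traj.t, e.onset + 1e-12, side="right")) - 1
        if idx < 0:
            raise ValueError(f"event at {e.onset} s precedes the first trajectory sample")
        out.append((float(traj.x[idx]), float(traj.y[idx])))
    return out


def kinematics_summary(record: SessionRecord, landmarks: list[str] | None = None) -> KinematicsSummary:
    """First-order summary of a session over the requested landmarks.

    By default summarizes every arena landmark plus the arena center.
    """
    traj, arena = record.trajectory, record.arena
    if landmarks is None:
        landmarks = list(arena.landmarks)
        if "center" not in landmarks:
            landmarks.append("center")
    mean_rel = {}
    mean_abs = {}
    for lm in landmarks:
        abs_series = distance_series(traj, arena, lm, mode="absolute")
        mean_abs[lm] = abs_series.mean()
        mean_rel[lm] = mean_abs[lm] / landmark_max_distance(arena, lm)
    return KinematicsSummary(
        traveled_distance=traveled_distance(traj),
        max_velocity=max_velocity(traj),
        mean_distance=mean_rel,
        mean_distance_cm=mean_abs,
    )
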