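"""Non-first-order measures on the zone-discretized trajectory.

The arena is tiled by a G x G matrix of virtual zones (default 10 x 10).
From the per-frame zone series this module derives

* the occupancy distribution (fraction of session time per zone),
* its Shannon entropy in bits — the variability of the subject's location,
* a between-session divergence comparing two occupancy distributions
  (Jensen-Shannon by default; bounded, symmetric, defined on zero-count
  zones), and
* categorical recurrence plots: the T x T binary matrix marking frame pairs
  that occupy the same zone, with streaming summaries (recurrence rate,
  mean same-zone run length, transition count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import entropy as _scipy_entropy

from .session_io import ArenaSpec, Trajectory

__all__ = [
    "ZoneGrid",
    "RecurrenceResult",
    "zone_of",
    "zone_series",
    "occupancy",
    "entropy_bits",
    "session_divergence",
    "recurrence",
]


@dataclass(frozen=True)
class ZoneGrid:
    """G x G tiling of the arena into virtual zones, row-major ids.

    Bins are half-open [lo, hi) except the last bin on each axis, which is
    closed so the far walls belong to the outermost zones.
    """

    arena: ArenaSpec
    divisions: int | None = None

    def __post_init__(self) -> None:
        if self.divisions is None:
            object.__setattr__(self, "divisions", self.arena.grid_divisions)
        if self.divisions < 1:
            raise ValueError("divisions must be >= 1")

    @property
    def n_zones(self) -> int:
        return self.divisions**2


def _axis_bin(v: np.ndarray, extent: float, g: int) -> np.ndarray:
    idx = np.floor(v * g / extent).astype(int)
    return np.minimum(idx, g - 1)  # closed top edge


def zone_of(position: tuple[float, float], grid: ZoneGrid) -> int:
    """Zone id of a single in-bounds position: row(y) * G + col(x)."""
    x, y = position
    arena, g = grid.arena, grid.divisions
    if not arena.contains(x, y):
        raise ValueError(f"position ({x}, {y}) outside arena bounds")
    col = int(_axis_bin(np.asarray([x]), arena.width, g)[0])
    row = int(_axis_bin(np.asarray([y]), arena.height, g)[0])
    return row * g + col


def zone_series(traj: Trajectory, grid: ZoneGrid) -> np.ndarray:
    """Per-frame zone ids for a whole trajectory (vectorized)."""
    arena, g = grid.arena, grid.divisions
    if np.any(traj.x < 0) or np.any(traj.x > arena.width) or np.any(traj.y < 0) or np.any(traj.y > arena.height):
        raise ValueError("trajectory leaves arena bounds; clamp at parse time")
    col = _axis_bin(traj.x, arena.width, g)
    row = _axis_bin(traj.y, arena.height, g)
    return row * g + col


def occupancy(zones: np.ndarray, grid: ZoneGrid) -> np.ndarray:
    """Occupancy distribution: frame counts per zone divided by T."""
    zones = np.asarray(zones)
    if zones.size == 0:
        raise ValueError("empty zone series")
    counts = np.bincount(zones, minlength=grid.n_zones)
    return counts / zones.size


def entropy_bits(dist: np.ndarray) -> float:
    """Shannon entropy of an occupancy distribution, in bits.

    0 for a degenerate distribution, log2(Z) for the uniform one.
    """
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability distribution")
    return float(_scipy_entropy(dist, base=2))


def session_divergence(
    p: np.ndarray, q: np.ndarray, method: str = "js"
) -> float:
    """Divergence between two sessions' occupancy distributions.

    ``method="js"`` (default) is the Jensen-Shannon divergence, base 2:
    0.5*KL(p||m) + 0.5*KL(q||m) with m = (p+q)/2. It is symmetric, 0 iff
    p == q, and at most 1 (disjoint supports). ``method="kl"`` is the
    Kullback-Leibler divergence KL(p||q) after additive 1/Z smoothing of both
    distributions (KL is undefined on the empty zones real sessions always
    have).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must be over the same grid")
    if method == "js":
        # scipy returns the JS *distance* (the square root of the divergence)
        return float(jensenshannon(p, q, base=2) ** 2)
    if method == "kl":
        z = p.size
        ps = (p + 1.0 / z) / (1.0 + 1.0)
        qs = (q + 1.0 / z) / (1.0 + 1.0)
        return float(_scipy_entropy(ps, qs, base=2))
    raise ValueError(f"unknown divergence method {method!r}")


@dataclass(frozen=True)
class RecurrenceResult:
    """Summaries of the categorical recurrence structure of a zone series.

    ``recurrence_rate`` is the off-diagonal density of the T x T same-zone
    indicator matrix; ``permanence`` is the mean length (frames) of maximal
    constant-zone runs; ``transition_count`` the number of frame-to-frame
    zone changes. ``matrix`` is only populated when materialization was
    requested (it is O(T^2) memory and only needed for plotting).
    """

    recurrence_rate: float
    permanence: float
    transition_count: int
    n_frames: int
    matrix: np.ndarray | None = None


def recurrence(zones: np.ndarray, materialize: bool = False) -> RecurrenceResult:
    """Recurrence summaries of a zone series, optionally with the full matrix.

    The rate is computed from streaming zone counts: with n_k frames in zone
    k, the number of ordered recurrent pairs is sum_k n_k (n_k - 1), out of
    T (T - 1) ordered off-diagonal pairs.
    """
    zones = np.asarray(zones)
    t = zones.size
    if t == 0:
        raise ValueError("empty zone series")
    counts = np.bincount(zones)
    if t == 1:
        rate = 1.0
    else:
        rate = float((counts * (counts - 1)).sum() / (t * (t - 1)))
    changes = int(np.count_nonzero(np.diff(zones)))
    n_runs = changes + 1
    result_matrix = None
    if materialize:
        result_matrix = (zones[:, None] == zones[None, :]).astype(np.uint8)
    return RecurrenceResult(
        recurrence_rate=rate,
        permanence=t / n_runs,
        transition_count=changes,
        n_frames=t,
        matrix=result_matrix,
    )
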