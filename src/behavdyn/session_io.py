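"""Data model, readers/writers, and validation for tracking sessions.

A *session* is one subject in one arena for a fixed duration: a uniformly
sampled 2-D trajectory (center-of-mass position at 5 Hz), a log of discrete
events (commodity deliveries with a limited-availability window, and head
entries into dispenser receptacles), and metadata (subject, condition,
deprivation sequence, session number).

File dialect: comma-separated UTF-8 with a header row.

* trajectory CSV: columns ``t,x,y`` (seconds, cm, cm)
* event CSV: columns ``t,kind,dispenser``
* manifest CSV: ``subject,condition,sequence,session,trajectory_file,event_file``
* arena: TOML with ``[arena]`` and ``[landmarks]`` tables

Coordinate convention: origin at the arena's lower-left corner, x rightward,
y upward, units cm.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ArenaSpec",
    "Trajectory",
    "Event",
    "SessionRecord",
    "ParseReport",
    "ParseError",
    "TrackingGapError",
    "parse_trajectory_table",
    "parse_event_table",
    "load_manifest",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_events_csv",
    "write_events_csv",
    "read_arena_toml",
    "write_arena_toml",
    "write_corpus",
    "load_corpus",
    "validate_session",
]

#: samples are considered equally spaced if |Δt - dt| stays below this
TIME_TOLERANCE = 1e-6

#: a run of more than this many consecutive missing frames (5 s at 5 Hz)
#: invalidates the session
MAX_MISSING_RUN = 25


class ParseError(ValueError):
    """Raised for malformed trajectory, event, or manifest tables."""


class TrackingGapError(ParseError):
    """Raised when a run of missing tracking frames is too long to repair."""


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the experimental chamber.

    Parameters
    ----------
    width, height : float
        Chamber dimensions in cm (e.g., 100 x 100 for the single-dispenser
        open field; 92 x 92 for the two-dispenser chamber).
    grid_divisions : int
        Number of virtual zones per axis for occupancy analysis (default 10,
        i.e., a 10 x 10 zone matrix).
    landmarks : dict
        Named focal points in cm, e.g., ``{"dispenser": (50.0, 50.0)}``.
    entry_radius : float
        Coincidence radius around a dispenser in cm (default 10).
    availability_duration : float
        How long a delivered commodity remains available, in s (default 3).
    """

    width: float
    height: float
    grid_divisions: int = 10
    landmarks: dict[str, tuple[float, float]] = field(default_factory=dict)
    entry_radius: float = 10.0
    availability_duration: float = 3.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.grid_divisions < 1:
            raise ValueError("grid_divisions must be >= 1")
        if self.entry_radius <= 0:
            raise ValueError("entry_radius must be positive")
        if self.availability_duration <= 0:
            raise ValueError("availability_duration must be positive")
        for name, (x, y) in self.landmarks.items():
            if not (0 <= x <= self.width and 0 <= y <= self.height):
                raise ValueError(f"landmark {name!r} at ({x}, {y}) outside arena")

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)

    def landmark(self, name: str) -> tuple[float, float]:
        """Resolve a landmark; ``"center"`` falls back to the geometric center."""
        if name in self.landmarks:
            return self.landmarks[name]
        if name == "center":
            return self.center
        raise KeyError(f"unknown landmark {name!r}")

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width and 0 <= y <= self.height

    def with_landmarks(self, **landmarks: tuple[float, float]) -> "ArenaSpec":
        merged = {**self.landmarks, **landmarks}
        return replace(self, landmarks=merged)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled (t, x, y) path of one subject in one session."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float = 0.2

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ParseError("timestamps must be strictly increasing")
        if np.any(np.abs(steps - self.dt) > TIME_TOLERANCE):
            raise ParseError(f"sampling period is not constant at dt={self.dt}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        """(T, 2) array of positions."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class Event:
    """A discrete event: a commodity delivery or a head entry.

    Deliveries carry an ``availability`` window (s); head entries do not.
    """

    kind: str
    dispenser: str
    onset: float
    availability: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("delivery", "head_entry"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")
        if self.kind == "delivery":
            if self.availability is None or self.availability <= 0:
                raise ValueError("deliveries require availability > 0")


@dataclass(frozen=True)
class SessionRecord:
    """One experimental session: trajectory + events + metadata."""

    subject: str
    condition: str
    session_number: int
    trajectory: Trajectory
    events: tuple[Event, ...]
    arena: ArenaSpec
    sequence: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.session_number < 1:
            raise ValueError("session_number must be >= 1")

    @property
    def duration(self) -> float:
        return self.trajectory.duration

    def events_of(self, kind: str, dispenser: str | None = None) -> list[Event]:
        out = [e for e in self.events if e.kind == kind]
        if dispenser is not None:
            out = [e for e in out if e.dispenser == dispenser]
        return out


@dataclass
class ParseReport:
    """What the trajectory parser had to repair."""

    n_clamped: int = 0
    n_filled: int = 0
    messages: list[str] = field(default_factory=list)


def parse_trajectory_table(
    rows, arena: ArenaSpec, dt: float = 0.2
) -> tuple[Trajectory, ParseReport]:
    """Validate and repair a raw (t, x, y) table.

    Missing (NaN) coordinates are forward-filled from the last valid sample;
    a run of more than ``MAX_MISSING_RUN`` consecutive missing frames raises
    :class:`TrackingGapError`, and a missing leading sample is unrecoverable.
    Out-of-bounds coordinates are clamped to the nearest arena boundary and
    counted in the report.
    """
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise ParseError("expected a non-empty table of (t, x, y) rows")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t, x, y = arr[:, 0], arr[:, 1].copy(), arr[:, 2].copy()
    if np.any(np.isnan(t)):
        raise ParseError("missing timestamp")
    if np.any(np.diff(t) <= 0):
        raise ParseError("timestamps must be strictly increasing")
    report = ParseReport()

    missing = np.isnan(x) | np.isnan(y)
    if missing[0]:
        raise ParseError("leading sample has missing coordinates")
    if missing.any():
        # longest run of consecutive missing frames
        run = longest = 0
        for m in missing:
            run = run + 1 if m else 0
            longest = max(longest, run)
        if longest > MAX_MISSING_RUN:
            raise TrackingGapError(
                f"run of {longest} consecutive missing frames exceeds "
                f"{MAX_MISSING_RUN}; session invalid"
            )
        idx = np.where(missing, 0, np.arange(len(x)))
        idx = np.maximum.accumulate(idx)
        x, y = x[idx], y[idx]
        report.n_filled = int(missing.sum())
        report.messages.append(f"forward-filled {report.n_filled} missing frames")

    xc = np.clip(x, 0.0, arena.width)
    yc = np.clip(y, 0.0, arena.height)
    clamped = (xc != x) | (yc != y)
    if clamped.any():
        report.n_clamped = int(clamped.sum())
        report.messages.append(
            f"clamped {report.n_clamped} out-of-bounds samples to the boundary"
        )
    return Trajectory(t=t, x=xc, y=yc, dt=dt), report


def parse_event_table(rows, arena: ArenaSpec) -> list[Event]:
    """Build a sorted event list from raw (t, kind, dispenser) records.

    Deliveries inherit the arena's availability duration unless the record
    carries an explicit fourth field overriding it.
    """
    events: list[Event] = []
    for row in rows:
        t, kind, dispenser = row[0], row[1], row[2]
        t = float(t)
        if t < 0:
            raise ParseError(f"negative event onset {t}")
        if dispenser not in arena.landmarks:
            raise ParseError(f"event references unknown dispenser {dispenser!r}")
        availability = None
        if kind == "delivery":
            availability = float(row[3]) if len(row) > 3 and row[3] is not None else arena.availability_duration
        events.append(Event(kind=kind, dispenser=dispenser, onset=t, availability=availability))
    events.sort(key=lambda e: e.onset)
    return events


# ---------------------------------------------------------------------------
# CSV / TOML round-tripping

def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(path, index=False)


def read_trajectory_csv(path, arena: ArenaSpec, dt: float = 0.2) -> tuple[Trajectory, ParseReport]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("t", "x", "y") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return parse_trajectory_table(df[["t", "x", "y"]].to_numpy(), arena, dt=dt)


def write_events_csv(events, path) -> None:
    pd.DataFrame(
        {
            "t": [e.onset for e in events],
            "kind": [e.kind for e in events],
            "dispenser": [e.dispenser for e in events],
        }
    ).to_csv(path, index=False)


def read_events_csv(path, arena: ArenaSpec) -> list[Event]:
    df = pd.read_csv(path)
    if len(df) == 0:
        return []
    rows = df[["t", "kind", "dispenser"]].itertuples(index=False)
    return parse_event_table(list(rows), arena)


def write_arena_toml(arena: ArenaSpec, path) -> None:
    lines = [
        "[arena]",
        f"width = {arena.width}",
        f"height = {arena.height}",
        f"grid_divisions = {arena.grid_divisions}",
        f"entry_radius = {arena.entry_radius}",
        f"availability_duration = {arena.availability_duration}",
        "",
        "[landmarks]",
    ]
    for name, (x, y) in arena.landmarks.items():
        lines.append(f"{name} = [{x}, {y}]")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_arena_toml(path) -> ArenaSpec:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    a = doc["arena"]
    landmarks = {k: (float(v[0]), float(v[1])) for k, v in doc.get("landmarks", {}).items()}
    return ArenaSpec(
        width=float(a["width"]),
        height=float(a["height"]),
        grid_divisions=int(a.get("grid_divisions", 10)),
        landmarks=landmarks,
        entry_radius=float(a.get("entry_radius", 10.0)),
        availability_duration=float(a.get("availability_duration", 3.0)),
    )


# ---------------------------------------------------------------------------
# Manifest / corpus

def load_manifest(path, arena: ArenaSpec, dt: float = 0.2) -> list[SessionRecord]:
    """Load every session listed in a manifest CSV.

    Data file paths are resolved relative to the manifest's directory.
    Duplicate (subject, session) pairs and missing files are errors that name
    the offending session.
    """
    path = Path(path)
    base = path.parent
    df = pd.read_csv(path, dtype={"subject": str, "condition": str, "sequence": str})
    records: list[SessionRecord] = []
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        key = (str(row.subject), int(row.session))
        if key in seen:
            raise ParseError(f"duplicate manifest entry for subject {key[0]} session {key[1]}")
        seen.add(key)
        traj_path = base / str(row.trajectory_file)
        event_path = base / str(row.event_file)
        for p in (traj_path, event_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"subject {key[0]} session {key[1]}: data file {p} not found"
                )
        traj, _ = read_trajectory_csv(traj_path, arena, dt=dt)
        events = read_events_csv(event_path, arena)
        seq = None if pd.isna(row.sequence) else str(row.sequence)
        records.append(
            SessionRecord(
                subject=str(row.subject),
                condition=str(row.condition),
                sequence=seq,
                session_number=int(row.session),
                trajectory=traj,
                events=tuple(events),
                arena=arena,
            )
        )
    return records


def write_corpus(sessions, outdir) -> Path:
    """Write a corpus (arena.toml + per-session CSVs + manifest.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sessions = list(sessions)
    write_arena_toml(sessions[0].arena, outdir / "arena.toml")
    rows = []
    for s in sessions:
        stem = f"{s.subject}_s{s.session_number:02d}"
        write_trajectory_csv(s.trajectory, outdir / f"{stem}_traj.csv")
        write_events_csv(s.events, outdir / f"{stem}_events.csv")
        rows.append(
            {
                "subject": s.subject,
                "condition": s.condition,
                "sequence": s.sequence if s.sequence is not None else "",
                "session": s.session_number,
                "trajectory_file": f"{stem}_traj.csv",
                "event_file": f"{stem}_events.csv",
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir / "manifest.csv"


def load_corpus(outdir, dt: float = 0.2) -> list[SessionRecord]:
    outdir = Path(outdir)
    arena = read_arena_toml(outdir / "arena.toml")
    return load_manifest(outdir / "manifest.csv", arena, dt=dt)


def validate_session(record: SessionRecord) -> None:
    """Check every cross-field invariant of a session; raise ValueError on breach."""
    traj, arena = record.trajectory, record.arena
    if np.any(traj.x < 0) or np.any(traj.x > arena.width):
        raise ValueError("trajectory x out of arena bounds")
    if np.any(traj.y < 0) or np.any(traj.y > arena.height):
        raise ValueError("trajectory y out of arena bounds")
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    for e in record.events:
        if not (t0 <= e.onset <= t1):
            raise ValueError(f"event onset {e.onset} outside session extent [{t0}, {t1}]")
        if e.dispenser not in arena.landmarks:
            raise ValueError(f"event dispenser {e.dispenser!r} is not an arena landmark")
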