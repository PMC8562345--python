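import numpy as np
import pytest

from behavdyn.session_io import ArenaSpec, Event, SessionRecord, Trajectory


@pytest.fixture
def arena() -> ArenaSpec:
    """100 x 100 cm single-dispenser open field, dispenser at the center."""
    return ArenaSpec(width=100.0, height=100.0, landmarks={"dispenser": (50.0, 50.0)})


@pytest.fixture
def two_dispenser_arena() -> ArenaSpec:
    """92 x 92 cm chamber with dispensers at the centers of opposing walls."""
    return ArenaSpec(
        width=92.0, height=92.0, landmarks={"food": (46.0, 92.0), "water": (46.0, 0.0)}
    )


def make_trajectory(xy: np.ndarray, dt: float = 0.2) -> Trajectory:
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * dt
    return Trajectory(t=t, x=xy[:, 0], y=xy[:, 1], dt=dt)


@pytest.fixture
def random_walk() -> Trajectory:
    """Seeded 1000-step random walk confined to the arena."""
    rng = np.random.default_rng(42)
    steps = rng.normal(0, 1.5, size=(1000, 2))
    xy = np.clip(50 + np.cumsum(steps, axis=0), 0, 100)
    return make_trajectory(xy)


def make_session(
    xy,
    arena: ArenaSpec,
    events=(),
    subject: str = "R1",
    condition: str = "FT",
    session_number: int = 1,
    sequence: str | None = None,
) -> SessionRecord:
    return SessionRecord(
        subject=subject,
        condition=condition,
        sequence=sequence,
        session_number=session_number,
        trajectory=make_trajectory(xy),
        events=tuple(events),
        arena=arena,
    )
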