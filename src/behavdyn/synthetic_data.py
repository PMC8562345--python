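"""Synthetic tracking-session generator.

Generates :class:`~behavdyn.session_io.SessionRecord` corpora with the
statistical structure the analysis pipeline assumes: schedule-driven
approach-withdrawal kinematics, dwell/consumption episodes at dispensers,
stochastic head-entry emission, condition contrasts (fixed-time vs
variable-time water schedules; food vs water deprivation under concurrent
schedules), and a geometric acquisition ramp across sessions.

The agent is a discrete-time two-mode stochastic process at 5 Hz:

* **explore** — diffusive wander (optionally pulled toward a per-session
  home base), with a hazard of starting an approach bout. Under a
  fixed-time schedule that hazard rises sigmoidally as the schedule clock
  nears the next delivery (anticipation); under variable-time or concurrent
  schedules it is constant.
* **approach** — exponential contraction toward the goal dispenser,
  ``x <- x + lambda * dt * (g - x) + sigma * sqrt(dt) * eps``, with
  reflection at the walls. On entering the dispenser zone the agent dwells
  for an exponential time; a contacted delivery refreshes the dwell clock.

Head entries are emitted per frame with a fixed probability while the agent
is inside the entry radius of a dispenser. Everything is reproducible from
a single master seed; per-session child seeds are derived with a stable
splitting scheme so adding sessions never reshuffles earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .session_io import ArenaSpec, Event, SessionRecord, Trajectory

__all__ = [
    "ScheduleSpec",
    "AgentParams",
    "SimDesign",
    "FT_PARAMS",
    "VT_PARAMS",
    "FD_PARAMS",
    "WD_PARAMS",
    "make_schedule",
    "simulate_session",
    "simulate_experiment1",
    "simulate_experiment2",
    "EXP1_ARENA",
    "EXP2_ARENA",
]


@dataclass(frozen=True)
class ScheduleSpec:
    """A time-based (response-independent) delivery schedule.

    ``FT`` delivers at every multiple of ``mean_interval``; ``VT`` draws
    inter-delivery intervals from an exponential with the stated mean,
    rejection-resampled into ``vt_bounds``; ``CONC_FT_FT`` runs two
    independent FT streams, one per dispenser.
    """

    type: str = "FT"
    mean_interval: float = 30.0
    availability: float = 3.0
    vt_bounds: tuple[float, float] = (5.0, 90.0)

    def __post_init__(self) -> None:
        if self.type not in ("FT", "VT", "CONC_FT_FT"):
            raise ValueError(f"unknown schedule type {self.type!r}")
        if self.mean_interval <= 0 or self.availability <= 0:
            raise ValueError("mean_interval and availability must be positive")


def _vt_intervals(spec: ScheduleSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n truncated-exponential intervals (constant hazard within bounds)."""
    lo, hi = spec.vt_bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.exponential(spec.mean_interval, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = keep[: n - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    return out


def make_schedule(
    spec: ScheduleSpec,
    duration: float,
    rng: np.random.Generator,
    dispensers: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Delivery onsets per dispenser over [0, duration]."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dispensers is None:
        dispensers = ("food", "water") if spec.type == "CONC_FT_FT" else ("dispenser",)

    def one_ft() -> np.ndarray:
        n = int(math.floor(duration / spec.mean_interval))
        return spec.mean_interval * np.arange(1, n + 1)

    def one_vt() -> np.ndarray:
        onsets = []
        t = 0.0
        while True:
            t += float(_vt_intervals(spec, 1, rng)[0])
            if t > duration:
                break
            onsets.append(t)
        return np.asarray(onsets)

    if spec.type == "FT":
        return {dispensers[0]: one_ft()}
    if spec.type == "VT":
        return {dispensers[0]: one_vt()}
    return {d: one_ft() for d in dispensers}


@dataclass(frozen=True)
class AgentParams:
    """Tunable parameters of the simulated forager.

    Rates are per second; converting a hazard h to a per-frame probability
    uses 1 - exp(-h * dt). ``entry_prob`` is already per frame.
    """

    approach_gain: float = 1.2  # 1/s, contraction rate toward the goal
    sigma_explore: float = 6.0  # cm/sqrt(s), diffusion while exploring
    sigma_approach: float = 4.0
    sigma_dwell: float = 1.5
    dwell_mean: float = 3.0  # s, mean dwell episode at a dispenser
    anticipation_lead: float = 6.0  # s before the next FT delivery
    anticipation_slope: float = 1.5  # s, width of the sigmoidal hazard rise
    anticipation_hazard: float = 0.35  # 1/s, peak approach hazard near delivery
    explore_hazard: float = 0.02  # 1/s, baseline approach-bout hazard
    home_attraction: float = 0.0  # 1/s, pull toward the per-session home base
    goal_weight_food: float = 1.0  # P(bout targets the food dispenser), CONC only
    entry_radius: float = 10.0  # cm
    entry_prob: float = 0.26  # per-frame head-entry probability in the zone
    acquisition_ramp: float = 1.03  # per-session multiplier on approach_gain

    def __post_init__(self) -> None:
        for name in ("approach_gain", "sigma_explore", "sigma_approach", "sigma_dwell", "dwell_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("goal_weight_food", "entry_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# condition presets: these defaults ARE the study conditions the generator
# emulates; see docs/methods.md for the calibration rationale
FT_PARAMS = AgentParams()
VT_PARAMS = AgentParams(
    approach_gain=0.5,
    sigma_explore=3.5,
    sigma_approach=3.0,
    dwell_mean=6.0,
    anticipation_hazard=0.0,
    explore_hazard=0.12,
    home_attraction=0.25,
)
FD_PARAMS = AgentParams(
    approach_gain=1.0,
    sigma_explore=3.0,
    sigma_approach=3.0,
    dwell_mean=6.0,
    anticipation_hazard=0.0,
    explore_hazard=0.10,
    goal_weight_food=0.85,
    acquisition_ramp=1.02,
)
WD_PARAMS = AgentParams(
    approach_gain=1.0,
    sigma_explore=4.5,
    sigma_approach=3.0,
    dwell_mean=4.0,
    anticipation_hazard=0.0,
    explore_hazard=0.18,
    goal_weight_food=0.35,
    acquisition_ramp=1.02,
)

EXP1_ARENA = ArenaSpec(width=100.0, height=100.0, landmarks={"dispenser": (50.0, 50.0)})
EXP2_ARENA = ArenaSpec(width=92.0, height=92.0, landmarks={"food": (46.0, 92.0), "water": (46.0, 0.0)})


@dataclass(frozen=True)
class SimDesign:
    """Corpus-level design: subjects, sessions, duration, master seed."""

    subjects_per_condition: int = 2
    sessions_per_subject: int = 20
    session_duration: float = 1200.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.subjects_per_condition < 1 or self.sessions_per_subject < 1:
            raise ValueError("counts must be >= 1")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")


_EXPLORE, _APPROACH, _DWELL = 0, 1, 2


def simulate_session(
    schedule: dict[str, np.ndarray],
    agent: AgentParams,
    arena: ArenaSpec,
    duration: float,
    rng: np.random.Generator,
    dt: float = 0.2,
    session_number: int = 1,
    schedule_interval: float | None = None,
    condition: str = "SIM",
    subject: str = "R1",
    sequence: str | None = None,
    availability: float = 3.0,
) -> SessionRecord:
    """Simulate one session and return a fully populated SessionRecord.

    ``schedule`` maps dispenser labels (which must be arena landmarks) to
    delivery onset arrays. ``schedule_interval`` enables anticipation: when
    given (an FT schedule with a single dispenser), the approach-bout hazard
    rises sigmoidally as the clock nears the next scheduled delivery.
    """
    n_frames = int(round(duration / dt)) + 1
    goals = {d: arena.landmark(d) for d in schedule}
    goal_names = sorted(schedule)
    lam = agent.approach_gain * agent.acquisition_ramp ** (session_number - 1)
    lam_dt = min(lam * dt, 0.95)
    sqdt = math.sqrt(dt)
    p_base = 1.0 - math.exp(-agent.explore_hazard * dt)

    # per-frame bout-start probability profile over one FT interval (anticipation)
    profile = None
    if schedule_interval is not None and agent.anticipation_hazard > 0:
        period = int(round(schedule_interval / dt))
        phase = np.arange(period) * dt
        remaining = schedule_interval - phase
        hazard = agent.explore_hazard + agent.anticipation_hazard / (
            1.0 + np.exp((remaining - agent.anticipation_lead) / agent.anticipation_slope)
        )
        profile = 1.0 - np.exp(-hazard * dt)

    eps = rng.standard_normal((n_frames, 2))
    u_mode = rng.random(n_frames)
    u_entry = rng.random(n_frames)
    u_goal = rng.random(n_frames)

    home = None
    if agent.home_attraction > 0:
        home = (rng.uniform(0, arena.width), rng.uniform(0, arena.height))

    # delivery bookkeeping per dispenser: sorted onsets + contact flags
    onsets = {d: np.sort(np.asarray(v, dtype=float)) for d, v in schedule.items()}
    contacted = {d: np.zeros(len(v), dtype=bool) for d, v in onsets.items()}
    pointer = {d: 0 for d in onsets}

    x = np.empty(n_frames)
    y = np.empty(n_frames)
    x[0] = rng.uniform(0, arena.width)
    y[0] = rng.uniform(0, arena.height)
    mode = _EXPLORE
    goal = goal_names[0]
    dwell_until = -1.0
    entries: list[Event] = []

    w, h = arena.width, arena.height
    radius = agent.entry_radius
    for i in range(1, n_frames):
        t = (i - 1) * dt
        px, py = x[i - 1], y[i - 1]

        if mode == _EXPLORE:
            if profile is not None:
                p_start = profile[int(round(t / dt)) % len(profile)]
            else:
                p_start = p_base
            if u_mode[i] < p_start:
                mode = _APPROACH
                if len(goal_names) > 1:
                    goal = goal_names[0] if u_goal[i] < agent.goal_weight_food else goal_names[1]
                # goal_names sorted => ("food", "water") for two dispensers
        gx, gy = goals[goal]
        if mode == _APPROACH and math.hypot(px - gx, py - gy) <= radius:
            mode = _DWELL
            dwell_until = t + rng.exponential(agent.dwell_mean)
        elif mode == _DWELL and t >= dwell_until:
            mode = _EXPLORE

        if mode == _APPROACH:
            nx = px + lam_dt * (gx - px) + agent.sigma_approach * sqdt * eps[i, 0]
            ny = py + lam_dt * (gy - py) + agent.sigma_approach * sqdt * eps[i, 1]
        elif mode == _DWELL:
            nx = px + min(2.0 * dt, 0.95) * (gx - px) + agent.sigma_dwell * sqdt * eps[i, 0]
            ny = py + min(2.0 * dt, 0.95) * (gy - py) + agent.sigma_dwell * sqdt * eps[i, 1]
        else:
            if home is not None:
                nx = px + agent.home_attraction * dt * (home[0] - px)
                ny = py + agent.home_attraction * dt * (home[1] - py)
            else:
                nx, ny = px, py
            nx += agent.sigma_explore * sqdt * eps[i, 0]
            ny += agent.sigma_explore * sqdt * eps[i, 1]
        # reflect at the walls
        if nx < 0:
            nx = -nx
        elif nx > w:
            nx = 2 * w - nx
        nx = min(max(nx, 0.0), w)
        if ny < 0:
            ny = -ny
        elif ny > h:
            ny = 2 * h - ny
        ny = min(max(ny, 0.0), h)
        x[i], y[i] = nx, ny

        tnow = i * dt
        for d in goal_names:
            ddx, ddy = goals[d]
            near = math.hypot(nx - ddx, ny - ddy) <= radius
            if not near:
                continue
            # head-entry emission inside the dispenser zone
            if u_entry[i] < agent.entry_prob:
                entries.append(Event(kind="head_entry", dispenser=d, onset=round(tnow, 6)))
            # delivery contact: consume the active window, refresh the dwell
            ons = onsets[d]
            ptr = pointer[d]
            while ptr < len(ons) and ons[ptr] + availability < tnow:
                ptr += 1
            pointer[d] = ptr
            if ptr < len(ons) and ons[ptr] <= tnow and not contacted[d][ptr]:
                contacted[d][ptr] = True
                if mode in (_APPROACH, _DWELL) and d == goal:
                    mode = _DWELL
                    dwell_until = max(dwell_until, tnow + rng.exponential(agent.dwell_mean))

    t_axis = np.arange(n_frames) * dt
    traj = Trajectory(t=t_axis, x=x, y=y, dt=dt)
    deliveries = [
        Event(kind="delivery", dispenser=d, onset=float(o), availability=availability)
        for d in goal_names
        for o in onsets[d]
    ]
    events = tuple(sorted(deliveries + entries, key=lambda e: (e.onset, e.kind, e.dispenser)))
    return SessionRecord(
        subject=subject,
        condition=condition,
        sequence=sequence,
        session_number=session_number,
        trajectory=traj,
        events=events,
        arena=arena,
    )


def _child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Stable per-(condition, subject, session) stream split."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


def simulate_experiment1(
    design: SimDesign | None = None,
    ft_params: AgentParams = FT_PARAMS,
    vt_params: AgentParams = VT_PARAMS,
    arena: ArenaSpec = EXP1_ARENA,
) -> list[SessionRecord]:
    """Simulate the single-dispenser FT-vs-VT water-schedule study.

    Default design: 2 subjects per condition x 20 sessions of 20 min on a
    100 x 100 cm arena with a central water dispenser, FT 30 s vs VT 30 s.
    """
    if design is None:
        design = SimDesign()
    records: list[SessionRecord] = []
    subject_idx = 0
    for cond_idx, (condition, params) in enumerate([("FT", ft_params), ("VT", vt_params)]):
        spec = ScheduleSpec(type=condition)
        for s in range(design.subjects_per_condition):
            subject_idx += 1
            subject = f"R{subject_idx}"
            for session in range(1, design.sessions_per_subject + 1):
                rng = _child_rng(design.master_seed, cond_idx, s, session)
                schedule = make_schedule(spec, design.session_duration, rng)
                records.append(
                    simulate_session(
                        schedule,
                        params,
                        arena,
                        design.session_duration,
                        rng,
                        session_number=session,
                        schedule_interval=spec.mean_interval if condition == "FT" else None,
                        condition=condition,
                        subject=subject,
                        availability=spec.availability,
                    )
                )
    return records


#: approach-gain values for the parameter-recovery sweep; chosen within the
#: regime where the gain still limits dispenser arrival (above ~0.5 /s the
#: anticipation ceiling, not the gain, caps the coincidence index)
SWEEP_GAINS = (0.03, 0.06, 0.12, 0.24, 0.48)


def sweep_approach_gain(
    gains=SWEEP_GAINS,
    seed: int = 0,
    n_sessions: int = 10,
    duration: float = 1200.0,
    base_params: AgentParams = FT_PARAMS,
    arena: ArenaSpec = EXP1_ARENA,
):
    """Parameter recovery: per gain value, the coincidence index and mean
    relative distance to the dispenser averaged over ``n_sessions`` FT
    sessions. Sessions are paired across gain values (common random numbers)
    so the sweep isolates the effect of the gain itself.

    Returns ``(gains, mean_coincidence, mean_distance)`` arrays.
    """
    from . import event_indices, kinematics  # deferred: avoids an import cycle

    spec = ScheduleSpec(type="FT")
    coincidence = np.empty(len(gains))
    distance = np.empty(len(gains))
    for gi, gain in enumerate(gains):
        params = replace(base_params, approach_gain=gain, acquisition_ramp=1.0)
        cs, ds = [], []
        for j in range(n_sessions):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))
            schedule = make_schedule(spec, duration, rng)
            rec = simulate_session(
                schedule,
                params,
                arena,
                duration,
                rng,
                session_number=j + 1,
                schedule_interval=spec.mean_interval,
                availability=spec.availability,
            )
            cs.append(
                event_indices.coincidence_index(
                    rec.trajectory, rec.events, arena, "dispenser"
                )
            )
            ds.append(
                kinematics.distance_series(
                    rec.trajectory, arena, "dispenser", mode="relative"
                ).mean()
            )
        coincidence[gi] = np.mean(cs)
        distance[gi] = np.mean(ds)
    return np.asarray(gains, dtype=float), coincidence, distance


DEFAULT_SEQUENCES = {"1": ("WD", "FD"), "2": ("FD", "WD")}


def simulate_experiment2(
    design: SimDesign | None = None,
    fd_params: AgentParams = FD_PARAMS,
    wd_params: AgentParams = WD_PARAMS,
    sequences: dict[str, tuple[str, str]] | None = None,
    arena: ArenaSpec = EXP2_ARENA,
    n_subjects: int = 6,
    sessions_per_deprivation: int = 3,
) -> list[SessionRecord]:
    """Simulate the two-dispenser deprivation study.

    Default design: 6 subjects, each through 2 deprivation conditions
    (food- and water-deprivation) x 3 sessions of 30 min on a 92 x 92 cm
    arena with food and water dispensers at the centers of opposing walls,
    under concurrent FT 30 s FT 30 s. Half the subjects run sequence 1
    (WD then FD), half sequence 2 (FD then WD).
    """
    if design is None:
        design = SimDesign(session_duration=1800.0)
    if sequences is None:
        sequences = DEFAULT_SEQUENCES
    params = {"FD": fd_params, "WD": wd_params}
    spec = ScheduleSpec(type="CONC_FT_FT")
    seq_labels = sorted(sequences)
    records: list[SessionRecord] = []
    for s in range(n_subjects):
        subject = f"R{s + 1}"
        seq = seq_labels[s % len(seq_labels)]
        order = sequences[seq]
        session = 0
        for phase_idx, condition in enumerate(order):
            for _ in range(sessions_per_deprivation):
                session += 1
                rng = _child_rng(design.master_seed, 100 + s, phase_idx, session)
                schedule = make_schedule(spec, design.session_duration, rng)
                records.append(
                    simulate_session(
                        schedule,
                        params[condition],
                        arena,
                        design.session_duration,
                        rng,
                        session_number=session,
                        condition=condition,
                        subject=subject,
                        sequence=seq,
                        availability=spec.availability,
                    )
                )
    return records
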