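"""Per-session feature tables for the machine-learning stage.

Two assemblies mirror the two study designs:

* single-dispenser sessions under FT/VT water schedules — 7 features
  (traveled distance, entropy, divergence, max velocity, coincidence index,
  mean distance to dispenser, session number);
* two-dispenser concurrent-schedule sessions under food/water deprivation —
  13 features (distances to food/water dispensers and the arena center,
  entropy, divergence, intensity/precision/proportion-contacted per
  dispenser, session number, deprivation sequence).

Missing values (e.g., the first session's divergence, or precision values
removed by the percentile filter) are explicit NaN entries; rows containing
any masked feature are excluded from multivariate operations downstream but
retained for univariate summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import event_indices, kinematics, occupancy
from .session_io import SessionRecord

__all__ = [
    "FeatureTable",
    "EXP1_FEATURES",
    "EXP2_FEATURES",
    "assemble_exp1",
    "assemble_exp2",
    "standardize",
]

EXP1_FEATURES = [
    "traveled_distance",
    "entropy",
    "divergence",
    "max_velocity",
    "coincidence_index",
    "mean_distance_dispenser",
    "session",
]

EXP2_FEATURES = [
    "dist_food_dispenser",
    "dist_water_dispenser",
    "dist_center",
    "entropy",
    "divergence",
    "intensity_food",
    "intensity_water",
    "precision_food",
    "precision_water",
    "proportion_food",
    "proportion_water",
    "session",
    "sequence",
]


@dataclass(frozen=True)
class FeatureTable:
    """Sessions x named features with a condition target label.

    ``data`` holds metadata columns, the target column, and the feature
    columns; NaN in a feature column is an explicit missing-value mask.
    """

    data: pd.DataFrame
    feature_names: tuple[str, ...]
    target: str = "condition"
    metadata: tuple[str, ...] = ("subject", "session_number", "sequence")

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "metadata", tuple(self.metadata))
        names = list(self.feature_names)
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        missing = [c for c in names + [self.target] if c not in self.data.columns]
        if missing:
            raise ValueError(f"columns absent from data: {missing}")
        if self.data[self.target].isna().any():
            raise ValueError("target label missing for some rows")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[list(self.feature_names)]

    @property
    def y(self) -> pd.Series:
        return self.data[self.target]

    @property
    def complete_mask(self) -> np.ndarray:
        """True for rows with no masked feature value."""
        return ~self.features.isna().any(axis=1).to_numpy()

    def complete(self) -> "FeatureTable":
        """Restrict to rows usable by multivariate operations."""
        return replace(self, data=self.data.loc[self.complete_mask].reset_index(drop=True))

    def to_csv(self, path, **kwargs) -> None:
        self.data.to_csv(path, index=False, **kwargs)


def _sorted_grouped(sessions) -> dict[str, list[SessionRecord]]:
    """Group by subject, sort by session number, check contiguity from 1."""
    by_subject: dict[str, list[SessionRecord]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject, []).append(s)
    for subject, recs in by_subject.items():
        recs.sort(key=lambda r: r.session_number)
        numbers = [r.session_number for r in recs]
        if numbers != list(range(1, len(recs) + 1)):
            raise ValueError(
                f"subject {subject}: session numbers {numbers} are not contiguous from 1"
            )
    return dict(sorted(by_subject.items()))


def _session_occupancy(record: SessionRecord, grid: occupancy.ZoneGrid) -> np.ndarray:
    zones = occupancy.zone_series(record.trajectory, grid)
    return occupancy.occupancy(zones, grid)


def assemble_exp1(
    sessions,
    dispenser: str = "dispenser",
    radius: float | None = None,
    window: float | None = None,
) -> FeatureTable:
    """Build the 7-feature table for single-dispenser FT/VT sessions.

    Divergence of session s (s >= 2) compares the occupancy distributions of
    sessions s-1 and s of the same subject; session 1 has no predecessor and
    its divergence is masked missing.
    """
    by_subject = _sorted_grouped(sessions)
    rows = []
    for subject, recs in by_subject.items():
        arena = recs[0].arena
        grid = occupancy.ZoneGrid(arena)
        rad = radius if radius is not None else arena.entry_radius
        win = window if window is not None else arena.availability_duration
        prev_occ = None
        for rec in recs:
            occ = _session_occupancy(rec, grid)
            div = np.nan if prev_occ is None else occupancy.session_divergence(prev_occ, occ)
            prev_occ = occ
            rel = kinematics.distance_series(rec.trajectory, arena, dispenser, mode="relative")
            rows.append(
                {
                    "subject": subject,
                    "condition": rec.condition,
                    "sequence": rec.sequence,
                    "session_number": rec.session_number,
                    "traveled_distance": kinematics.traveled_distance(rec.trajectory),
                    "entropy": occupancy.entropy_bits(occ),
                    "divergence": div,
                    "max_velocity": kinematics.max_velocity(rec.trajectory),
                    "coincidence_index": event_indices.coincidence_index(
                        rec.trajectory, rec.events, arena, dispenser, radius=rad, window=win
                    ),
                    "mean_distance_dispenser": rel.mean(),
                    "mean_distance_dispenser_cm": rel.mean()
                    * kinematics.landmark_max_distance(arena, dispenser),
                    "session": rec.session_number,
                }
            )
    data = pd.DataFrame(rows)
    return FeatureTable(
        data=data,
        feature_names=tuple(EXP1_FEATURES),
        metadata=("subject", "session_number", "sequence", "mean_distance_dispenser_cm"),
    )


_SEQUENCE_CODES = {"1": 1, "2": 2, 1: 1, 2: 2}


def assemble_exp2(
    sessions,
    food: str = "food",
    water: str = "water",
    window: float | None = None,
    filter_percentile: float = 5.0,
) -> FeatureTable:
    """Build the 13-feature table for two-dispenser deprivation sessions.

    Intensity normalizes each session's head-entry count by the maximum over
    all of that subject's sessions for the same dispenser. Precision values
    below the given percentile within each subject-dispenser series are
    masked missing rather than zero-filled.
    """
    by_subject = _sorted_grouped(sessions)
    rows = []
    for subject, recs in by_subject.items():
        arena = recs[0].arena
        for disp in (food, water):
            if disp not in arena.landmarks:
                raise ValueError(f"arena lacks the {disp!r} dispenser landmark")
        grid = occupancy.ZoneGrid(arena)
        win = window if window is not None else arena.availability_duration

        entry_counts = {
            disp: np.array([len(r.events_of("head_entry", disp)) for r in recs])
            for disp in (food, water)
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-zero series legitimately yields NaN
            intensities = {d: event_indices.intensity_index(c) for d, c in entry_counts.items()}
        precisions = {
            disp: np.array(
                [
                    event_indices.precision_index(r.events, r.events, disp, window=win)
                    for r in recs
                ]
            )
            for disp in (food, water)
        }
        # percentile filter on defined precision values, per subject-dispenser
        for disp in (food, water):
            vals = precisions[disp]
            defined = ~np.isnan(vals)
            if defined.sum() > 0:
                keep = event_indices.percentile_filter(vals[defined], p=filter_percentile)
                dropped = np.where(defined)[0][~keep]
                vals[dropped] = np.nan

        prev_occ = None
        for i, rec in enumerate(recs):
            occ = _session_occupancy(rec, grid)
            div = np.nan if prev_occ is None else occupancy.session_divergence(prev_occ, occ)
            prev_occ = occ
            if rec.sequence not in _SEQUENCE_CODES:
                raise ValueError(f"subject {subject}: sequence label {rec.sequence!r} not in {{1, 2}}")
            rows.append(
                {
                    "subject": subject,
                    "condition": rec.condition,
                    "sequence_label": rec.sequence,
                    "session_number": rec.session_number,
                    "dist_food_dispenser": kinematics.distance_series(
                        rec.trajectory, arena, food, mode="relative"
                    ).mean(),
                    "dist_water_dispenser": kinematics.distance_series(
                        rec.trajectory, arena, water, mode="relative"
                    ).mean(),
                    "dist_center": kinematics.distance_series(
                        rec.trajectory, arena, "center", mode="relative"
                    ).mean(),
                    "entropy": occupancy.entropy_bits(occ),
                    "divergence": div,
                    "intensity_food": intensities[food][i],
                    "intensity_water": intensities[water][i],
                    "precision_food": precisions[food][i],
                    "precision_water": precisions[water][i],
                    "proportion_food": event_indices.proportion_contacted(
                        rec.events, rec.events, food, window=win
                    ),
                    "proportion_water": event_indices.proportion_contacted(
                        rec.events, rec.events, water, window=win
                    ),
                    "session": rec.session_number,
                    "sequence": _SEQUENCE_CODES[rec.sequence],
                }
            )
    data = pd.DataFrame(rows)
    return FeatureTable(
        data=data,
        feature_names=tuple(EXP2_FEATURES),
        metadata=("subject", "session_number", "sequence_label"),
    )


def standardize(table: FeatureTable) -> FeatureTable:
    """Z-score every feature over its non-missing rows.

    Constant features become all-zero with a warning; target and metadata
    columns are untouched; masked cells remain masked.
    """
    if len(table) < 2:
        raise ValueError("standardize needs at least 2 rows")
    data = table.data.copy()
    for name in table.feature_names:
        col = data[name].astype(float)
        mean = col.mean(skipna=True)
        sd = col.std(skipna=True, ddof=0)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"feature {name!r} is constant; standardized to zeros", stacklevel=2)
            data[name] = np.where(col.isna(), np.nan, 0.0)
        else:
            data[name] = (col - mean) / sd
    return replace(table, data=data)
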