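import numpy as np
import pytest

from behavdyn.session_io import (
    ArenaSpec,
    Event,
    ParseError,
    TrackingGapError,
    load_manifest,
    parse_event_table,
    parse_trajectory_table,
    read_arena_toml,
    load_corpus,
    write_arena_toml,
    write_corpus,
    read_trajectory_csv,
    write_trajectory_csv,
    validate_session,
)

from conftest import make_session, make_trajectory


class TestArenaSpec:
    def test_landmarks_must_lie_inside(self):
        with pytest.raises(ValueError):
            ArenaSpec(width=100, height=100, landmarks={"d": (150.0, 50.0)})

    @pytest.mark.parametrize(
        "kwargs",
        [dict(width=-1, height=100), dict(width=100, height=100, grid_divisions=0),
         dict(width=100, height=100, entry_radius=0)],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ArenaSpec(**kwargs)

    def test_center_fallback_landmark(self, arena):
        assert arena.landmark("center") == (50.0, 50.0)
        with pytest.raises(KeyError):
            arena.landmark("north")


class TestParseTrajectory:
    def test_accepts_regular_5hz_rows(self, arena):
        rows = [(0.0, 10, 10), (0.2, 11, 10), (0.4, 12, 10)]
        traj, report = parse_trajectory_table(rows, arena, dt=0.2)
        assert traj.n_samples == 3
        assert report.n_clamped == 0 and report.n_filled == 0

    def test_out_of_bounds_clamped_and_counted(self, arena):
        rows = [(0.0, 10, 10), (0.2, 105, 10), (0.4, 12, 10)]
        traj, report = parse_trajectory_table(rows, arena, dt=0.2)
        assert traj.x[1] == 100.0
        assert report.n_clamped == 1

    def test_clamping_leaves_in_bounds_samples_alone(self, arena):
        rng = np.random.default_rng(0)
        rows = np.column_stack([np.arange(50) * 0.2, rng.uniform(0, 100, 50), rng.uniform(0, 100, 50)])
        traj, report = parse_trajectory_table(rows, arena)
        assert report.n_clamped == 0
        np.testing.assert_array_equal(traj.x, rows[:, 1])

    def test_non_monotonic_time_rejected(self, arena):
        with pytest.raises(ParseError):
            parse_trajectory_table([(0.0, 1, 1), (0.2, 1, 1), (0.1, 1, 1)], arena)

    def test_missing_frames_forward_filled(self, arena):
        rows = [(0.0, 10, 10), (0.2, np.nan, np.nan), (0.4, 12, 10)]
        traj, report = parse_trajectory_table(rows, arena)
        assert traj.x[1] == 10 and traj.y[1] == 10
        assert report.n_filled == 1

    def test_leading_missing_sample_is_fatal(self, arena):
        with pytest.raises(ParseError):
            parse_trajectory_table([(0.0, np.nan, 5), (0.2, 1, 1)], arena)

    def test_long_dropout_invalidates_session(self, arena):
        rows = [(i * 0.2, 50.0, 50.0) for i in range(40)]
        for i in range(2, 29):  # 27 consecutive missing frames > 25 allowed
            rows[i] = (i * 0.2, np.nan, np.nan)
        with pytest.raises(TrackingGapError):
            parse_trajectory_table(rows, arena)


class TestParseEvents:
    def test_delivery_inherits_availability(self, arena):
        events = parse_event_table([(30.0, "delivery", "dispenser")], arena)
        assert len(events) == 1
        assert events[0].availability == 3.0

    def test_empty_table(self, arena):
        assert parse_event_table([], arena) == []

    def test_unknown_dispenser_rejected(self, arena):
        with pytest.raises(ParseError):
            parse_event_table([(5.0, "delivery", "north")], arena)

    def test_events_sorted_by_onset(self, arena):
        events = parse_event_table(
            [(60.0, "head_entry", "dispenser"), (30.0, "delivery", "dispenser")], arena
        )
        assert [e.onset for e in events] == [30.0, 60.0]

    def test_negative_onset_rejected(self, arena):
        with pytest.raises(ParseError):
            parse_event_table([(-1.0, "delivery", "dispenser")], arena)


class TestRoundTrips:
    def test_trajectory_csv_round_trip_exact(self, tmp_path, arena, random_walk):
        path = tmp_path / "traj.csv"
        write_trajectory_csv(random_walk, path)
        back, report = read_trajectory_csv(path, arena)
        np.testing.assert_array_equal(back.x, random_walk.x)
        np.testing.assert_array_equal(back.y, random_walk.y)
        assert report.n_clamped == 0

    def test_arena_toml_round_trip(self, tmp_path, two_dispenser_arena):
        path = tmp_path / "arena.toml"
        write_arena_toml(two_dispenser_arena, path)
        back = read_arena_toml(path)
        assert back == two_dispenser_arena

    def test_corpus_round_trip_and_validation(self, tmp_path, arena):
        rng = np.random.default_rng(3)
        sessions = [
            make_session(
                rng.uniform(0, 100, (50, 2)),
                arena,
                events=[Event("delivery", "dispenser", 3.0, 3.0)],
                subject=f"R{i}",
            )
            for i in (1, 2)
        ]
        write_corpus(sessions, tmp_path / "corpus")
        back = load_corpus(tmp_path / "corpus")
        assert [s.subject for s in back] == ["R1", "R2"]
        np.testing.assert_array_equal(back[0].trajectory.x, sessions[0].trajectory.x)
        for s in back:
            validate_session(s)


class TestManifest:
    def _write(self, tmp_path, arena, rows):
        import pandas as pd

        traj = make_trajectory(np.full((10, 2), 50.0))
        write_trajectory_csv(traj, tmp_path / "t.csv")
        (tmp_path / "e.csv").write_text("t,kind,dispenser\n")
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
        return tmp_path / "manifest.csv"

    def _row(self, subject="R1", session=1, traj="t.csv"):
        return {
            "subject": subject, "condition": "FT", "sequence": "",
            "session": session, "trajectory_file": traj, "event_file": "e.csv",
        }

    def test_sessions_load_in_manifest_order(self, tmp_path, arena):
        path = self._write(tmp_path, arena, [self._row("R2"), self._row("R1")])
        records = load_manifest(path, arena)
        assert [r.subject for r in records] == ["R2", "R1"]

    def test_missing_file_error_names_session(self, tmp_path, arena):
        path = self._write(tmp_path, arena, [self._row(traj="absent.csv")])
        with pytest.raises(FileNotFoundError, match="R1 session 1"):
            load_manifest(path, arena)

    def test_duplicate_subject_session_rejected(self, tmp_path, arena):
        path = self._write(tmp_path, arena, [self._row(), self._row()])
        with pytest.raises(ParseError, match="duplicate"):
            load_manifest(path, arena)
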