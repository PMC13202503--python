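"""Recording round-trips, format errors, and coordinate conventions."""

import json

import numpy as np
import pytest

from eyehand.session_model import (
    BodyStream,
    FormatError,
    GazeStream,
    HandStream,
    HeadStream,
    InteractionEvent,
    ParseError,
    RigidTransform,
    SessionRecording,
    ValidationError,
    read_recording,
    rotate_yaw,
    to_table_frame,
    write_recording,
    yaw_of,
)
from eyehand.behavior_sim import render_sensors, simulate_truth, BehaviorParams, SensorParams
from eyehand.task_schedule import SessionSchedule


def _small_recording(schedule) -> SessionRecording:
    t = np.arange(10) * 0.025
    d = np.tile([0.0, 0.6, -0.8], (10, 1))
    gaze = GazeStream(t, np.tile([0.0, -0.5, 0.5], (10, 1)), d, ["table"] * 9 + [None])
    pos = np.random.default_rng(0).normal(size=(10, 3))
    valid = np.ones(10, dtype=bool)
    valid[3] = False
    pos[3] = np.nan
    hands = {
        "headset": HandStream(t, pos, valid, "headset"),
        "external": HandStream(
            t + 0.09,
            np.nan_to_num(pos, nan=0.5) + 0.02,
            np.ones(10, bool),
            "external",
            t_send=t,
        ),
    }
    head = HeadStream(t, np.tile([0.0, -0.5, 0.5], (10, 1)), np.tile([0.0, 1.0, 0.0], (10, 1)))
    joints = {"shoulder_left": np.tile([-0.2, -0.5, 0.45], (10, 1))}
    body = BodyStream(t + 0.09, joints, {"shoulder_left": np.ones(10, bool)}, t_send=t)
    events = [
        InteractionEvent(0.0, "paper_appear", 0),
        InteractionEvent(0.2, "stamp", 0),
    ]
    return SessionRecording(
        schedule=schedule,
        gaze=gaze,
        hands=hands,
        head=head,
        body=body,
        events=events,
        metadata={"participant": "p0", "seed": 0},
    )


def _assert_recordings_equal(a: SessionRecording, b: SessionRecording, tol=1e-9):
    np.testing.assert_allclose(a.gaze.t, b.gaze.t, atol=tol)
    np.testing.assert_allclose(a.gaze.origin, b.gaze.origin, atol=tol)
    np.testing.assert_allclose(a.gaze.direction, b.gaze.direction, atol=tol)
    assert a.gaze.hit == b.gaze.hit
    assert set(a.hands) == set(b.hands)
    for src in a.hands:
        ha, hb = a.hands[src], b.hands[src]
        np.testing.assert_allclose(ha.t, hb.t, atol=tol)
        np.testing.assert_array_equal(ha.valid, hb.valid)
        np.testing.assert_allclose(ha.position[ha.valid], hb.position[hb.valid], atol=tol)
    np.testing.assert_allclose(a.head.position, b.head.position, atol=tol)
    np.testing.assert_allclose(a.body.t, b.body.t, atol=tol)
    assert set(a.body.joints) == set(b.body.joints)
    for j in a.body.joints:
        va, vb = a.body.valid[j], b.body.valid[j]
        np.testing.assert_array_equal(va, vb)
        np.testing.assert_allclose(a.body.joints[j][va], b.body.joints[j][vb], atol=tol)
    assert [(e.t, e.kind, e.episode_index) for e in a.events] == [
        (e.t, e.kind, e.episode_index) for e in b.events
    ]
    assert len(a.schedule.episodes) == len(b.schedule.episodes)
    for ea, eb in zip(a.schedule.episodes, b.schedule.episodes):
        assert ea == eb


class TestRoundTrip:
    def test_small_recording_round_trips(self, schedule, tmp_path):
        rec = _small_recording(schedule)
        path = tmp_path / "rec.jsonl"
        write_recording(rec, path)
        _assert_recordings_equal(read_recording(path), rec)

    def test_empty_streams_round_trip(self, tmp_path):
        rec = SessionRecording(
            schedule=SessionSchedule(episodes=[], seed=-1),
            gaze=GazeStream.empty(),
            hands={},
            head=HeadStream.empty(),
            body=BodyStream.empty(),
            events=[],
            metadata={"k": 1},
        )
        path = tmp_path / "empty.jsonl"
        write_recording(rec, path)
        back = read_recording(path)
        assert len(back.gaze) == 0 and len(back.events) == 0
        assert back.metadata == {"k": 1}

    def test_simulated_recording_round_trips(self, layout, mini_schedule, tmp_path):
        truth = simulate_truth(mini_schedule, layout, BehaviorParams(), seed=5)
        rec = render_sensors(truth, SensorParams(), seed=5)
        path = tmp_path / "sim.jsonl"
        write_recording(rec, path)
        _assert_recordings_equal(read_recording(path), rec)


class TestValidation:
    def test_non_monotonic_timestamps_rejected(self, schedule, tmp_path):
        rec = _small_recording(schedule)
        rec.gaze.t[5] = rec.gaze.t[4] - 0.01
        with pytest.raises(ValidationError, match="increasing"):
            write_recording(rec, tmp_path / "bad.jsonl")

    def test_non_unit_gaze_direction_rejected(self, schedule, tmp_path):
        rec = _small_recording(schedule)
        rec.gaze.direction[2] *= 1.5
        with pytest.raises(ValidationError, match="unit"):
            write_recording(rec, tmp_path / "bad.jsonl")

    def test_truncated_final_line_reports_line_number(self, schedule, tmp_path):
        rec = _small_recording(schedule)
        path = tmp_path / "rec.jsonl"
        write_recording(rec, path)
        text = path.read_text()
        n_lines = text.count("\n")
        path.write_text(text[:-20])  # chop the final record mid-JSON
        with pytest.raises(ParseError) as exc:
            read_recording(path)
        assert exc.value.line_number == n_lines

    def test_unknown_stream_tag_named(self, schedule, tmp_path):
        rec = _small_recording(schedule)
        path = tmp_path / "rec.jsonl"
        write_recording(rec, path)
        with path.open("a") as fh:
            fh.write(json.dumps({"type": "sonar", "t": 1.0}) + "\n")
        with pytest.raises(FormatError, match="sonar"):
            read_recording(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "rec.jsonl"
        path.write_text(json.dumps({"type": "event", "t": 0.0, "kind": "stamp", "episode": 0}) + "\n")
        with pytest.raises(FormatError, match="header"):
            read_recording(path)


class TestTableFrame:
    def test_identity_transform_is_noop(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        out = to_table_frame(pts, RigidTransform.identity())
        np.testing.assert_allclose(out, pts)

    def test_pure_translation_shifts_every_point(self):
        pts = np.random.default_rng(2).normal(size=(20, 3))
        tr = RigidTransform(np.eye(3), np.array([0.02, 0.0, 0.0]))
        np.testing.assert_allclose(to_table_frame(pts, tr) - pts, np.tile([0.02, 0, 0], (20, 1)))

    def test_random_rigid_transform_preserves_distances(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        tr = RigidTransform(Q, rng.normal(size=3))
        pts = rng.normal(size=(30, 3))
        out = to_table_frame(pts, tr)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d_out, d_in, atol=1e-9)

    def test_non_rigid_matrix_rejected(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # det -1


class TestYawConvention:
    def test_rightward_rotation_from_forward_is_positive(self):
        d = rotate_yaw(np.array([0.0, 1.0, 0.0]), 10.0)
        assert yaw_of(d) == pytest.approx(10.0, abs=1e-9)

    def test_vertical_direction_has_no_yaw(self):
        assert yaw_of([0.0, 0.0, -1.0]) is None

    def test_cardinal_yaws(self):
        assert yaw_of([0.0, 1.0, 0.0]) == pytest.approx(0.0)
        assert yaw_of([1.0, 0.0, 0.0]) == pytest.approx(90.0)
        assert yaw_of([-1.0, 0.0, 0.0]) == pytest.approx(-90.0)
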