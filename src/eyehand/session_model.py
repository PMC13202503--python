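"""Domain types, coordinate conventions and the JSON-Lines recording format.

All streams share a single table coordinate frame: origin at the table
center, +x toward the seated user's right, +y away from the user along the
table, +z up.  Horizontal (yaw) angles are measured about +z in degrees with
positive = rightward (ipsilesional for a right-hemisphere lesion); a
direction rotated +10 deg from +y therefore has yaw +10.

Timestamps are seconds (float64) on a per-session clock starting near zero.
The two devices keep separate clocks; the residual offset between them is
estimated and removed by :mod:`eyehand.temporal_sync`.

A recording is one JSON-Lines file: a metadata header line followed by typed
stream records (``schedule``, ``gaze``, ``hand``, ``head``, ``body``,
``event``).  Floats round-trip bit-exactly through the standard json
encoder.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .task_schedule import Episode, SessionSchedule

__all__ = [
    "ValidationError",
    "FormatError",
    "ParseError",
    "yaw_of",
    "rotate_yaw",
    "RigidTransform",
    "to_table_frame",
    "GazeStream",
    "HandStream",
    "HeadStream",
    "BodyStream",
    "InteractionEvent",
    "SessionRecording",
    "write_recording",
    "read_recording",
]

BODY_JOINTS = ("chest", "shoulder_left", "shoulder_right", "head", "hand_left", "hand_right")
EVENT_KINDS = (
    "paper_appear",
    "paper_fixated",
    "ink_entered",
    "ink_exited",
    "stamp",
    "timeout_advance",
)


class ValidationError(ValueError):
    """A stream or record violates a type invariant."""


class FormatError(ValueError):
    """The file is not in the recording dialect."""


class ParseError(ValueError):
    """A line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


# ---------------------------------------------------------------------------
# angles and rigid transforms


def yaw_of(direction: Sequence[float]) -> Optional[float]:
    """Signed horizontal angle of a direction in degrees, positive rightward.

    Measured between the horizontal projection of ``direction`` and +y.
    Returns None for (near-)vertical directions.
    """
    d = np.asarray(direction, dtype=float)
    if math.hypot(d[0], d[1]) < 1e-9:
        return None
    return math.degrees(math.atan2(d[0], d[1]))


def rotate_yaw(v: Sequence[float], degrees: float) -> np.ndarray:
    """Rotate a vector about +z in the yaw-positive (rightward) sense.

    ``rotate_yaw((0, 1, 0), +10)`` has yaw +10.
    """
    v = np.asarray(v, dtype=float)
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    out = v.copy()
    out[..., 0] = c * v[..., 0] + s * v[..., 1]
    out[..., 1] = -s * v[..., 0] + c * v[..., 1]
    return out


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform y = R x + t."""

    rotation: np.ndarray      # (3, 3), det +1
    translation: np.ndarray   # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rigid transform needs a 3x3 rotation and 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValidationError("rotation must be orthonormal with det +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def to_table_frame(points: np.ndarray, calibration: RigidTransform) -> np.ndarray:
    """Map points into the table frame with a pre-computed rigid calibration."""
    return calibration.apply(points)


# ---------------------------------------------------------------------------
# stream containers (columnar; one row per sample)


def _check_monotonic(t: np.ndarray, name: str) -> None:
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError(f"{name}: timestamps must be strictly increasing")


@dataclass
class GazeStream:
    t: np.ndarray                      # (n,)
    origin: np.ndarray                 # (n, 3), m
    direction: np.ndarray              # (n, 3), unit
    hit: List[Optional[str]]           # per-sample intersected object id

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(-1, 3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(-1, 3)
        self.hit = list(self.hit)

    def __len__(self):
        return len(self.t)

    def validate(self) -> None:
        _check_monotonic(self.t, "gaze")
        if not (len(self.t) == len(self.origin) == len(self.direction) == len(self.hit)):
            raise ValidationError("gaze: field lengths differ")
        if len(self.t):
            norms = np.linalg.norm(self.direction, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValidationError("gaze: direction must be a unit vector")

    @classmethod
    def empty(cls) -> "GazeStream":
        return cls(np.empty(0), np.empty((0, 3)), np.empty((0, 3)), [])


@dataclass
class HandStream:
    t: np.ndarray            # (n,) receiver-clock timestamps
    position: np.ndarray     # (n, 3); NaN where invalid
    valid: np.ndarray        # (n,) bool
    source: str              # headset | external
    t_send: Optional[np.ndarray] = None   # sender-clock timestamps (external)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.t_send is not None:
            self.t_send = np.asarray(self.t_send, dtype=float)

    def __len__(self):
        return len(self.t)

    def validate(self) -> None:
        _check_monotonic(self.t, f"hand[{self.source}]")
        if self.source not in ("headset", "external"):
            raise ValidationError(f"hand: unknown source {self.source!r}")
        if not (len(self.t) == len(self.position) == len(self.valid)):
            raise ValidationError("hand: field lengths differ")
        if np.any(np.isfinite(self.position[~self.valid]).all(axis=1)):
            raise ValidationError("hand: invalid samples must carry no position")
        if np.any(~np.isfinite(self.position[self.valid])):
            raise ValidationError("hand: valid samples must be finite")

    @classmethod
    def empty(cls, source: str) -> "HandStream":
        return cls(np.empty(0), np.empty((0, 3)), np.empty(0, dtype=bool), source)


@dataclass
class HeadStream:
    """Headset pose stream: head position and horizontal forward vector."""

    t: np.ndarray
    position: np.ndarray      # (n, 3)
    forward: np.ndarray       # (n, 3), unit

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float).reshape(-1, 3)
        self.forward = np.asarray(self.forward, dtype=float).reshape(-1, 3)

    def __len__(self):
        return len(self.t)

    def validate(self) -> None:
        _check_monotonic(self.t, "head")
        if not (len(self.t) == len(self.position) == len(self.forward)):
            raise ValidationError("head: field lengths differ")

    @classmethod
    def empty(cls) -> "HeadStream":
        return cls(np.empty(0), np.empty((0, 3)), np.empty((0, 3)))


@dataclass
class BodyStream:
    """External body-tracking stream: a map of joints to positions.

    ``joints[name]`` is an (n, 3) array; ``valid[name]`` flags per-sample
    joint validity (positions are NaN where invalid).
    """

    t: np.ndarray
    joints: Dict[str, np.ndarray]
    valid: Dict[str, np.ndarray]
    t_send: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.joints = {k: np.asarray(v, dtype=float).reshape(-1, 3) for k, v in self.joints.items()}
        self.valid = {k: np.asarray(v, dtype=bool) for k, v in self.valid.items()}
        if self.t_send is not None:
            self.t_send = np.asarray(self.t_send, dtype=float)

    def __len__(self):
        return len(self.t)

    def validate(self) -> None:
        _check_monotonic(self.t, "body")
        for name, pos in self.joints.items():
            if name not in BODY_JOINTS:
                raise ValidationError(f"body: unknown joint {name!r}")
            v = self.valid.get(name)
            if v is None or len(v) != len(self.t) or len(pos) != len(self.t):
                raise ValidationError(f"body: joint {name!r} lengths differ")
            if np.any(~np.isfinite(pos[v])):
                raise ValidationError(f"body: joint {name!r} has non-finite valid samples")

    @classmethod
    def empty(cls) -> "BodyStream":
        return cls(np.empty(0), {}, {})


@dataclass(frozen=True)
class InteractionEvent:
    t: float
    kind: str
    episode_index: int

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"event: unknown kind {self.kind!r}")


@dataclass
class SessionRecording:
    schedule: SessionSchedule
    gaze: GazeStream
    hands: Dict[str, HandStream]
    head: HeadStream
    body: BodyStream
    events: List[InteractionEvent]
    metadata: Dict[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        self.gaze.validate()
        for src, stream in self.hands.items():
            if src != stream.source:
                raise ValidationError(f"hand stream keyed {src!r} has source {stream.source!r}")
            stream.validate()
        self.head.validate()
        self.body.validate()
        by_episode: Dict[int, List[InteractionEvent]] = {}
        for ev in self.events:
            by_episode.setdefault(ev.episode_index, []).append(ev)
        for idx, evs in by_episode.items():
            times = [e.t for e in evs]
            if times != sorted(times):
                raise ValidationError(f"events of episode {idx} are not time-ordered")
            kinds = [e.kind for e in evs]
            if "paper_appear" not in kinds:
                raise ValidationError(f"episode {idx} lacks a paper_appear event")
            n_close = kinds.count("stamp") + kinds.count("timeout_advance")
            if n_close != 1:
                raise ValidationError(
                    f"episode {idx} must end with exactly one stamp or timeout_advance"
                )


# ---------------------------------------------------------------------------
# JSON-Lines serialization


def _vec(a: np.ndarray) -> list:
    return [float(x) for x in a]


def _episode_to_json(e: Episode) -> dict:
    return {
        "round": e.round,
        "location_id": e.location_id,
        "color": e.color,
        "hand": e.hand,
        "post_stamp_delay": e.post_stamp_delay,
    }


def write_recording(recording: SessionRecording, path: Union[str, Path]) -> None:
    """Write a validated recording as one JSON-Lines file."""
    recording.validate()
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "type": "header",
            "format": "eyehand-recording",
            "version": 1,
            "metadata": recording.metadata,
        }
        fh.write(json.dumps(header) + "\n")
        sched = recording.schedule
        fh.write(
            json.dumps(
                {
                    "type": "schedule",
                    "seed": sched.seed,
                    "timeout": sched.timeout,
                    "episodes": [_episode_to_json(e) for e in sched.episodes],
                }
            )
            + "\n"
        )
        g = recording.gaze
        for i in range(len(g)):
            fh.write(
                json.dumps(
                    {
                        "type": "gaze",
                        "t": float(g.t[i]),
                        "origin": _vec(g.origin[i]),
                        "direction": _vec(g.direction[i]),
                        "hit": g.hit[i],
                    }
                )
                + "\n"
            )
        hd = recording.head
        for i in range(len(hd)):
            fh.write(
                json.dumps(
                    {
                        "type": "head",
                        "t": float(hd.t[i]),
                        "position": _vec(hd.position[i]),
                        "forward": _vec(hd.forward[i]),
                    }
                )
                + "\n"
            )
        for src in sorted(recording.hands):
            h = recording.hands[src]
            for i in range(len(h)):
                rec = {
                    "type": "hand",
                    "t": float(h.t[i]),
                    "source": src,
                    "valid": bool(h.valid[i]),
                }
                if h.valid[i]:
                    rec["position"] = _vec(h.position[i])
                if h.t_send is not None:
                    rec["t_send"] = float(h.t_send[i])
                fh.write(json.dumps(rec) + "\n")
        b = recording.body
        for i in range(len(b)):
            joints = {
                name: _vec(b.joints[name][i])
                for name in b.joints
                if b.valid[name][i]
            }
            rec = {"type": "body", "t": float(b.t[i]), "joints": joints}
            if b.t_send is not None:
                rec["t_send"] = float(b.t_send[i])
            fh.write(json.dumps(rec) + "\n")
        for ev in recording.events:
            fh.write(
                json.dumps(
                    {
                        "type": "event",
                        "t": ev.t,
                        "kind": ev.kind,
                        "episode": ev.episode_index,
                    }
                )
                + "\n"
            )


_KNOWN_TAGS = {"header", "schedule", "gaze", "head", "hand", "body", "event"}


def read_recording(path: Union[str, Path]) -> SessionRecording:
    """Read and fully validate a JSON-Lines recording."""
    path = Path(path)
    raw: List[tuple] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(lineno, f"malformed JSON ({exc.msg})") from exc
            raw.append((lineno, obj))

    if not raw or raw[0][1].get("type") != "header":
        raise FormatError("missing header line")
    header = raw[0][1]
    if header.get("format") != "eyehand-recording":
        raise FormatError(f"not an eyehand recording: {header.get('format')!r}")
    metadata = header.get("metadata", {})

    schedule: Optional[SessionSchedule] = None
    gaze_rows, head_rows, body_rows, events = [], [], [], []
    hand_rows: Dict[str, list] = {}
    for lineno, obj in raw[1:]:
        tag = obj.get("type")
        if tag not in _KNOWN_TAGS:
            raise FormatError(f"line {lineno}: unknown stream tag {tag!r}")
        try:
            if tag == "schedule":
                schedule = SessionSchedule(
                    episodes=[Episode(**e) for e in obj["episodes"]],
                    seed=obj["seed"],
                    timeout=obj["timeout"],
                )
            elif tag == "gaze":
                gaze_rows.append((obj["t"], obj["origin"], obj["direction"], obj.get("hit")))
            elif tag == "head":
                head_rows.append((obj["t"], obj["position"], obj["forward"]))
            elif tag == "hand":
                hand_rows.setdefault(obj["source"], []).append(
                    (obj["t"], obj.get("position"), obj["valid"], obj.get("t_send"))
                )
            elif tag == "body":
                body_rows.append((obj["t"], obj["joints"], obj.get("t_send")))
            elif tag == "event":
                events.append(InteractionEvent(obj["t"], obj["kind"], obj["episode"]))
        except (KeyError, TypeError) as exc:
            raise ParseError(lineno, f"bad {tag} record: {exc}") from exc

    if schedule is None:
        schedule = SessionSchedule(episodes=[], seed=-1)

    if gaze_rows:
        gaze = GazeStream(
            np.array([r[0] for r in gaze_rows]),
            np.array([r[1] for r in gaze_rows]),
            np.array([r[2] for r in gaze_rows]),
            [r[3] for r in gaze_rows],
        )
    else:
        gaze = GazeStream.empty()

    if head_rows:
        head = HeadStream(
            np.array([r[0] for r in head_rows]),
            np.array([r[1] for r in head_rows]),
            np.array([r[2] for r in head_rows]),
        )
    else:
        head = HeadStream.empty()

    hands: Dict[str, HandStream] = {}
    for src, rows in hand_rows.items():
        pos = np.full((len(rows), 3), np.nan)
        valid = np.zeros(len(rows), dtype=bool)
        for i, (_, p, v, _) in enumerate(rows):
            valid[i] = v
            if p is not None:
                pos[i] = p
        has_send = all(r[3] is not None for r in rows)
        hands[src] = HandStream(
            np.array([r[0] for r in rows]),
            pos,
            valid,
            src,
            t_send=np.array([r[3] for r in rows]) if has_send else None,
        )

    if body_rows:
        t = np.array([r[0] for r in body_rows])
        joints = {
            name: np.full((len(body_rows), 3), np.nan) for name in BODY_JOINTS
        }
        valid = {name: np.zeros(len(body_rows), dtype=bool) for name in BODY_JOINTS}
        for i, (_, jmap, _) in enumerate(body_rows):
            for name, p in jmap.items():
                if name not in joints:
                    raise FormatError(f"unknown body joint {name!r}")
                joints[name][i] = p
                valid[name][i] = True
        present = {n for n in BODY_JOINTS if valid[n].any()}
        body = BodyStream(
            t,
            {n: joints[n] for n in present},
            {n: valid[n] for n in present},
            t_send=(
                np.array([r[2] for r in body_rows])
                if all(r[2] is not None for r in body_rows)
                else None
            ),
        )
    else:
        body = BodyStream.empty()

    recording = SessionRecording(
        schedule=schedule,
        gaze=gaze,
        hands=hands,
        head=head,
        body=body,
        events=events,
        metadata=metadata,
    )
    recording.validate()
    return recording
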