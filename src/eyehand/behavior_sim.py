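"""Ground-truth behavior simulation and noisy sensor rendering.

This module generates what the acquisition hardware would have seen: a user
playing the stamping game per a session schedule.  Behavior is scripted per
episode (search scanpath, target fixation, ink-pad dip, minimum-jerk reach,
stamp) with injectable lateral asymmetries of the kind unilateral spatial
neglect produces: an ipsilesional (rightward) bias of search gaze, longer
times to find contralesional (left) targets, target omissions, and earlier
gaze anchoring for contralesional reach targets.

The renderer then degrades the ground truth into the three recorded streams:
a 40 Hz headset stream (gaze ray + hand position, with bursty hand-tracking
dropout of about 25%), and a 30 Hz external body-tracking stream (joints and
a second hand-position source with ~2 cm noise, a constant 3D frame offset
left over from imperfect camera-to-headset calibration, and ~92 ms network
latency on its receiver timestamps).

Ground truth is kept on a dense 200 Hz grid, the rate of the optical
motion-capture reference the accuracy benchmark emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .gaze_pipeline import compute_hits
from .session_model import (
    BodyStream,
    GazeStream,
    HandStream,
    HeadStream,
    InteractionEvent,
    SessionRecording,
    rotate_yaw,
)
from .task_schedule import Layout, SessionSchedule

__all__ = [
    "BehaviorParams",
    "SensorParams",
    "EpisodeTruth",
    "GroundTruthSession",
    "minimum_jerk",
    "simulate_truth",
    "render_sensors",
    "simulate_session",
]

TRUTH_RATE_HZ = 200.0

# fixed posture geometry (table frame, meters)
HEAD_BASE = np.array([0.0, -0.55, 0.55])
CHEST_BASE = np.array([0.0, -0.55, 0.40])
SHOULDER_HALF_WIDTH = 0.19
SHOULDER_Z = 0.50
HAND_REST = np.array([0.0, -0.30, 0.02])


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioral generator parameters.

    Angles in degrees (positive = rightward), times in seconds.  The
    ``usn`` preset carries the asymmetry magnitudes of a mild-to-moderate
    right-hemisphere-lesion profile; ``control`` has no asymmetries.
    """

    gaze_bias_deg: float = 0.0          # mean search-gaze yaw
    head_gain: float = 0.6              # fraction of gaze yaw expressed as head yaw
    torso_yaw_deg: float = 0.0
    base_find_time_s: float = 1.8
    left_find_penalty_s: float = 0.0    # added for left-side targets
    find_time_sd_s: float = 0.5
    reach_duration_s: float = 0.7
    anchor_lead_left_s: float = 0.0     # motion onset -> target fixation, left
    anchor_lead_right_s: float = 0.0    # same, right (negative = fixation first)
    fixation_noise_deg: float = 15.0    # spread of search-scanpath yaw
    omission_prob_left: float = 0.0
    omission_prob_right: float = 0.0
    ink_dwell_s: float = 0.5
    reaction_time_s: float = 0.12

    def validate(self) -> None:
        for name in ("base_find_time_s", "reach_duration_s", "ink_dwell_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("omission_prob_left", "omission_prob_right"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def control(cls) -> "BehaviorParams":
        return cls()

    @classmethod
    def usn(cls) -> "BehaviorParams":
        """Right-brain-lesion neglect profile: rightward search bias, slower
        contralesional finds with occasional omissions, earlier anchoring on
        left reach targets."""
        return cls(
            gaze_bias_deg=7.5,
            left_find_penalty_s=1.0,
            anchor_lead_left_s=-0.112,
            anchor_lead_right_s=0.0,
            torso_yaw_deg=-3.8,
            omission_prob_left=0.09,
            omission_prob_right=0.03,
        )


@dataclass(frozen=True)
class SensorParams:
    """Acquisition model: rates, noise, dropout, latency, frame offset."""

    headset_rate_hz: float = 40.0
    external_rate_hz: float = 30.0
    noise_sd_headset_m: float = 0.01        # hand, per axis
    noise_sd_external_m: float = 0.02       # hand + joints, per axis
    dropout_rate_headset: float = 0.25      # bursty loss on the headset hand
    dropout_rate_external: float = 0.03     # i.i.d. loss on external samples
    dropout_burst_mean_s: float = 0.40
    latency_s: float = 0.092                # external receiver delay
    latency_jitter_sd_s: float = 0.003
    frame_offset_m: Tuple[float, float, float] = (0.02, 0.0, 0.0)
    gaze_noise_deg: float = 1.5
    head_noise_m: float = 0.002

    def validate(self) -> None:
        if self.headset_rate_hz <= 0 or self.external_rate_hz <= 0:
            raise ValueError("rates must be > 0")
        for name in ("dropout_rate_headset", "dropout_rate_external"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class EpisodeTruth:
    index: int
    location_id: str
    side: str                    # left | right | center (sector-based)
    hand: str
    color: str
    t_appear: float
    omitted: bool
    t_first_fix: Optional[float] = None
    t_ink_enter: Optional[float] = None
    t_ink_exit: Optional[float] = None   # = true motion onset
    t_anchor: Optional[float] = None
    t_stamp: Optional[float] = None


@dataclass
class GroundTruthSession:
    t: np.ndarray                       # dense 200 Hz grid
    hand: np.ndarray                    # (n, 3) acting-hand trajectory
    gaze_origin: np.ndarray
    gaze_direction: np.ndarray
    gaze_target: List[Optional[str]]    # intended fixation target per sample
    head_yaw_deg: np.ndarray
    joints: Dict[str, np.ndarray]
    events: List[InteractionEvent]
    episodes: List[EpisodeTruth]
    schedule: SessionSchedule
    layout: Layout
    behavior: BehaviorParams
    seed: int


def minimum_jerk(p0, p1, T: float, t) -> np.ndarray:
    """Minimum-jerk point-to-point trajectory, evaluated at time(s) t.

    p(t) = p0 + (p1 - p0) (10 tau^3 - 15 tau^4 + 6 tau^5) with tau = t/T;
    velocity and acceleration vanish at both endpoints.
    """
    if T <= 0:
        raise ValueError(f"duration must be > 0, got {T}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > T + 1e-12):
        raise ValueError("t must lie in [0, T]")
    tau = np.clip(t_arr / T, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if t_arr.ndim == 0:
        return p0 + (p1 - p0) * float(s)
    return p0[None, :] + (p1 - p0)[None, :] * s[:, None]


def _side_of_sector(sector: int, n_sectors: int) -> str:
    if sector <= 2:
        return "left"
    if sector > n_sectors - 2:
        return "right"
    return "center"


class _Timeline:
    """Piecewise segment recorder for one dense stream."""

    def __init__(self):
        self.hand_segments: List[Tuple[float, float, str, np.ndarray, np.ndarray, float]] = []
        self.gaze_segments: List[Tuple[float, float, np.ndarray, Optional[str]]] = []

    def hold_hand(self, t0: float, t1: float, p: np.ndarray) -> None:
        self.hand_segments.append((t0, t1, "hold", p, p, 0.0))

    def move_hand(self, t0: float, p0: np.ndarray, p1: np.ndarray, T: float) -> None:
        self.hand_segments.append((t0, t0 + T, "jerk", p0, p1, T))

    def look_at(self, t0: float, t1: float, point: np.ndarray, target: Optional[str]) -> None:
        if t1 > t0:
            self.gaze_segments.append((t0, t1, point, target))


def simulate_truth(
    schedule: SessionSchedule,
    layout: Layout,
    behavior: BehaviorParams = BehaviorParams(),
    seed: int = 0,
) -> GroundTruthSession:
    """Script the user's behavior for a schedule and densely sample it.

    Per episode: a search scanpath whose yaw distribution is centered at
    ``gaze_bias_deg``; first target fixation at appear + base find time
    (+ left penalty for left-sector targets) + noise, truncated by an
    omission draw or the session timeout; an ink-pad dip; a minimum-jerk
    reach; target re-fixation at onset + the side's anchor lead; a stamp at
    reach end.  Fully reproducible for a given seed.
    """
    behavior.validate()
    rng = np.random.default_rng(seed)
    spec = layout.spec
    tl = _Timeline()
    events: List[InteractionEvent] = []
    episodes: List[EpisodeTruth] = []

    pad_by_color = {
        "violet": np.asarray(spec.ink_pad_positions[0], dtype=float),
        "orange": np.asarray(spec.ink_pad_positions[1], dtype=float),
    }
    paper_margin = 0.08
    move_to_pad_s = 0.45
    return_home_s = 0.5

    def scanpath(t0: float, t1: float, avoid_center: Optional[np.ndarray]) -> None:
        """Fill [t0, t1) with search fixations; rays avoid the active paper."""
        t = t0
        hw = spec.paper_size[0] / 2.0 + paper_margin
        hh = spec.paper_size[1] / 2.0 + paper_margin
        while t < t1:
            dur = rng.uniform(0.18, 0.35)
            dur = min(dur, t1 - t) if t1 - t > 0.08 else t1 - t
            for _ in range(30):
                yaw = rng.normal(behavior.gaze_bias_deg, behavior.fixation_noise_deg)
                yaw = float(np.clip(yaw, -55.0, 55.0))
                dist = rng.uniform(0.25, 0.75)
                u = rotate_yaw(np.array([0.0, 1.0, 0.0]), yaw)
                point = np.array(
                    [HEAD_BASE[0] + dist * u[0], HEAD_BASE[1] + dist * u[1], 0.0]
                )
                if avoid_center is None:
                    break
                if (
                    abs(point[0] - avoid_center[0]) > hw
                    or abs(point[1] - avoid_center[1]) > hh
                ):
                    break
            tl.look_at(t, t + dur, point, None)
            t += dur

    t_cursor = 1.0
    hand_pos = HAND_REST.copy()
    tl.hold_hand(0.0, t_cursor, hand_pos)
    tl.look_at(0.0, t_cursor, np.array([0.0, 0.0, 0.0]), None)

    for idx, ep in enumerate(schedule.episodes):
        loc = layout.locations[ep.location_id]
        side = _side_of_sector(loc.sector, spec.n_sectors)
        paper_center = layout.position(ep.location_id)
        t_appear = t_cursor
        events.append(InteractionEvent(t_appear, "paper_appear", idx))

        find = behavior.base_find_time_s + rng.normal(0.0, behavior.find_time_sd_s)
        if side == "left":
            find += behavior.left_find_penalty_s
        find = max(0.35, find)
        omission_p = {
            "left": behavior.omission_prob_left,
            "right": behavior.omission_prob_right,
            "center": 0.0,
        }[side]
        omitted = bool(rng.random() < omission_p) or (find >= schedule.timeout - 0.05)

        truth = EpisodeTruth(
            index=idx,
            location_id=ep.location_id,
            side=side,
            hand=ep.hand,
            color=ep.color,
            t_appear=t_appear,
            omitted=omitted,
        )

        if omitted:
            t_end = t_appear + schedule.timeout
            scanpath(t_appear, t_end, paper_center)
            tl.hold_hand(t_appear, t_end, hand_pos)
            events.append(InteractionEvent(t_end, "timeout_advance", idx))
        else:
            t_fix = t_appear + find
            scanpath(t_appear, t_fix, paper_center)
            truth.t_first_fix = t_fix
            events.append(InteractionEvent(t_fix, "paper_fixated", idx))

            pad = pad_by_color[ep.color]
            t_move = t_fix + behavior.reaction_time_s
            t_enter = t_move + move_to_pad_s
            t_exit = t_enter + behavior.ink_dwell_s
            t_stamp = t_exit + behavior.reach_duration_s
            lead = (
                behavior.anchor_lead_left_s
                if side == "left"
                else behavior.anchor_lead_right_s
            )
            t_anchor = t_exit + lead

            # gaze: paper until the hand heads for the pad, pad until anchor,
            # paper again from anchor through the stamp
            tl.look_at(t_fix, t_move + 0.1, paper_center, ep.location_id)
            pad_id = "pad_violet" if ep.color == "violet" else "pad_orange"
            tl.look_at(t_move + 0.1, t_anchor, pad, pad_id)
            tl.look_at(t_anchor, t_stamp + 0.3, paper_center, ep.location_id)

            # hand: rest -> pad -> dwell -> reach -> hold on paper -> home
            tl.hold_hand(t_appear, t_move, hand_pos)
            tl.move_hand(t_move, hand_pos, pad, move_to_pad_s)
            tl.hold_hand(t_enter, t_exit, pad)
            tl.move_hand(t_exit, pad, paper_center, behavior.reach_duration_s)
            t_hold_end = t_stamp + 0.2
            tl.hold_hand(t_stamp, t_hold_end, paper_center)
            tl.move_hand(t_hold_end, paper_center, HAND_REST, return_home_s)
            hand_pos = HAND_REST.copy()

            events.append(InteractionEvent(t_enter, "ink_entered", idx))
            events.append(InteractionEvent(t_exit, "ink_exited", idx))
            events.append(InteractionEvent(t_stamp, "stamp", idx))
            truth.t_ink_enter = t_enter
            truth.t_ink_exit = t_exit
            truth.t_anchor = t_anchor
            truth.t_stamp = t_stamp
            t_end = t_hold_end + return_home_s

        episodes.append(truth)
        t_next = (
            (t_appear + schedule.timeout if omitted else truth.t_stamp)
            + ep.post_stamp_delay
        )
        t_cursor = max(t_next, t_end)
        gap_start = tl.gaze_segments[-1][1] if tl.gaze_segments else 0.0
        if t_cursor > gap_start:
            scanpath(gap_start, t_cursor, None)
        if not omitted:
            tl.hold_hand(t_end, t_cursor, hand_pos)
        else:
            tl.hold_hand(t_appear + schedule.timeout, t_cursor, hand_pos)

    # --- densify onto the 200 Hz grid
    duration = t_cursor + 0.5
    n = int(math.ceil(duration * TRUTH_RATE_HZ)) + 1
    t = np.arange(n) / TRUTH_RATE_HZ

    hand = np.tile(HAND_REST, (n, 1))
    for t0, t1, kind, p0, p1, T in tl.hand_segments:
        i0, i1 = np.searchsorted(t, [t0, t1])
        if i1 <= i0:
            continue
        if kind == "hold":
            hand[i0:i1] = p0
        else:
            hand[i0:i1] = minimum_jerk(p0, p1, T, np.clip(t[i0:i1] - t0, 0.0, T))
    # everything after the last segment holds the final position
    if tl.hand_segments:
        t1_last = max(seg[1] for seg in tl.hand_segments)
        i_last = np.searchsorted(t, t1_last)
        if i_last < n and i_last > 0:
            hand[i_last:] = hand[i_last - 1]

    gaze_origin = np.tile(HEAD_BASE, (n, 1))
    gaze_point = np.tile(np.array([0.0, 0.1, 0.0]), (n, 1))
    gaze_target: List[Optional[str]] = [None] * n
    for t0, t1, point, target in tl.gaze_segments:
        i0, i1 = np.searchsorted(t, [t0, t1])
        gaze_point[i0:i1] = point
        if target is not None:
            for i in range(i0, min(i1, n)):
                gaze_target[i] = target
    gaze_direction = gaze_point - gaze_origin
    gaze_direction /= np.linalg.norm(gaze_direction, axis=1, keepdims=True)

    head_yaw = np.array(
        [behavior.head_gain * math.degrees(math.atan2(d[0], d[1])) for d in gaze_direction]
    )

    shoulder_axis = rotate_yaw(np.array([1.0, 0.0, 0.0]), behavior.torso_yaw_deg)
    sl = CHEST_BASE - SHOULDER_HALF_WIDTH * shoulder_axis
    sr = CHEST_BASE + SHOULDER_HALF_WIDTH * shoulder_axis
    sl = np.array([sl[0], sl[1], SHOULDER_Z])
    sr = np.array([sr[0], sr[1], SHOULDER_Z])
    joints = {
        "chest": np.tile(CHEST_BASE, (n, 1)),
        "shoulder_left": np.tile(sl, (n, 1)),
        "shoulder_right": np.tile(sr, (n, 1)),
        "head": np.tile(HEAD_BASE, (n, 1)),
        "hand_left": np.tile(HAND_REST + np.array([-0.15, 0.0, 0.0]), (n, 1)),
        "hand_right": np.tile(HAND_REST + np.array([0.15, 0.0, 0.0]), (n, 1)),
    }
    # the acting hand follows the hand trajectory
    for ep_truth, ep in zip(episodes, schedule.episodes):
        t_end = (
            ep_truth.t_appear + schedule.timeout
            if ep_truth.omitted
            else ep_truth.t_stamp + 0.2 + return_home_s
        )
        i0, i1 = np.searchsorted(t, [ep_truth.t_appear, t_end])
        key = "hand_right" if ep.hand == "right" else "hand_left"
        joints[key][i0:i1] = hand[i0:i1]

    return GroundTruthSession(
        t=t,
        hand=hand,
        gaze_origin=gaze_origin,
        gaze_direction=gaze_direction,
        gaze_target=gaze_target,
        head_yaw_deg=head_yaw,
        joints=joints,
        events=events,
        episodes=episodes,
        schedule=schedule,
        layout=layout,
        behavior=behavior,
        seed=seed,
    )


def _interp3(t_src: np.ndarray, x_src: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    out = np.empty((len(t_new), 3))
    for k in range(3):
        out[:, k] = np.interp(t_new, t_src, x_src[:, k])
    return out


def _burst_dropout_mask(
    t: np.ndarray, rate: float, burst_mean_s: float, rng: np.random.Generator
) -> np.ndarray:
    """True where the sample is LOST.  Alternating renewal process with
    exponential burst lengths; long-run loss fraction = rate."""
    if rate <= 0:
        return np.zeros(len(t), dtype=bool)
    lost = np.zeros(len(t), dtype=bool)
    mean_up = burst_mean_s * (1.0 - rate) / rate
    t_end = t[-1] if len(t) else 0.0
    cursor = 0.0
    state_lost = rng.random() < rate
    while cursor < t_end:
        dur = rng.exponential(burst_mean_s if state_lost else mean_up)
        if state_lost:
            i0, i1 = np.searchsorted(t, [cursor, cursor + dur])
            lost[i0:i1] = True
        cursor += dur
        state_lost = not state_lost
    return lost


def render_sensors(
    truth: GroundTruthSession, sensors: SensorParams = SensorParams(), seed: int = 0
) -> SessionRecording:
    """Render the noisy sensor streams a session recording would contain."""
    sensors.validate()
    rng = np.random.default_rng(seed)
    layout = truth.layout
    t_end = truth.t[-1]

    # ---- headset streams (40 Hz, headset clock == truth clock)
    th = np.arange(0.0, t_end, 1.0 / sensors.headset_rate_hz)

    origin = _interp3(truth.t, truth.gaze_origin, th)
    direction = _interp3(truth.t, truth.gaze_direction, th)
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    if sensors.gaze_noise_deg > 0:
        yaw_noise = rng.normal(0.0, sensors.gaze_noise_deg, len(th))
        pitch_noise = rng.normal(0.0, sensors.gaze_noise_deg, len(th))
        for i in range(len(th)):
            d = rotate_yaw(direction[i], yaw_noise[i])
            # small-angle pitch perturbation about the horizontal axis
            pr = math.radians(pitch_noise[i])
            horiz = math.hypot(d[0], d[1])
            ang = math.atan2(d[2], horiz) + pr
            scale = math.cos(ang) / horiz if horiz > 1e-9 else 0.0
            direction[i] = np.array([d[0] * scale, d[1] * scale, math.sin(ang)])
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    origin = origin + rng.normal(0.0, sensors.head_noise_m, origin.shape)

    active_paper = []
    appear_t: Dict[int, float] = {}
    for ev in truth.events:
        if ev.kind == "paper_appear":
            appear_t[ev.episode_index] = ev.t
        elif ev.kind in ("stamp", "timeout_advance"):
            lid = truth.episodes[ev.episode_index].location_id
            active_paper.append((appear_t[ev.episode_index], ev.t, lid))
    gaze = GazeStream(t=th, origin=origin, direction=direction, hit=[None] * len(th))
    gaze.hit = compute_hits(gaze, layout, active_paper)

    head_fwd = np.stack(
        [
            rotate_yaw(np.array([0.0, 1.0, 0.0]), y + rng.normal(0.0, 0.5))
            for y in np.interp(th, truth.t, truth.head_yaw_deg)
        ]
    )
    head = HeadStream(
        t=th,
        position=_interp3(truth.t, truth.joints["head"], th)
        + rng.normal(0.0, sensors.head_noise_m, (len(th), 3)),
        forward=head_fwd,
    )

    hand_true_h = _interp3(truth.t, truth.hand, th)
    hand_h = hand_true_h + rng.normal(0.0, sensors.noise_sd_headset_m, hand_true_h.shape)
    lost = _burst_dropout_mask(
        th, sensors.dropout_rate_headset, sensors.dropout_burst_mean_s, rng
    )
    hand_h[lost] = np.nan
    headset_hand = HandStream(
        t=th, position=hand_h, valid=~lost, source="headset"
    )

    # ---- external streams (30 Hz, receiver clock = sender + latency)
    ts = np.arange(0.0, t_end, 1.0 / sensors.external_rate_hz)
    jitter = rng.normal(0.0, sensors.latency_jitter_sd_s, len(ts))
    tr = ts + sensors.latency_s + jitter
    # receiver order preserved; bump only actual ties/inversions so the
    # zero-jitter case stays exact
    for i in range(1, len(tr)):
        if tr[i] <= tr[i - 1]:
            tr[i] = tr[i - 1] + 1e-9

    offset = np.asarray(sensors.frame_offset_m, dtype=float)

    hand_true_e = _interp3(truth.t, truth.hand, ts)
    hand_e = (
        hand_true_e
        + offset
        + rng.normal(0.0, sensors.noise_sd_external_m, hand_true_e.shape)
    )
    lost_e = rng.random(len(ts)) < sensors.dropout_rate_external
    hand_e[lost_e] = np.nan
    external_hand = HandStream(
        t=tr, position=hand_e, valid=~lost_e, source="external", t_send=ts
    )

    joints: Dict[str, np.ndarray] = {}
    valid: Dict[str, np.ndarray] = {}
    for name, series in truth.joints.items():
        j = (
            _interp3(truth.t, series, ts)
            + offset
            + rng.normal(0.0, sensors.noise_sd_external_m, (len(ts), 3))
        )
        v = rng.random(len(ts)) >= sensors.dropout_rate_external
        j[~v] = np.nan
        joints[name] = j
        valid[name] = v
    body = BodyStream(t=tr, joints=joints, valid=valid, t_send=ts)

    metadata = {
        "seed": int(seed),
        "behavior_seed": int(truth.seed),
        "headset_rate_hz": sensors.headset_rate_hz,
        "external_rate_hz": sensors.external_rate_hz,
        "spacing_m": layout.spec.spacing,
    }
    return SessionRecording(
        schedule=truth.schedule,
        gaze=gaze,
        hands={"headset": headset_hand, "external": external_hand},
        head=head,
        body=body,
        events=list(truth.events),
        metadata=metadata,
    )


def simulate_session(
    schedule: SessionSchedule,
    layout: Layout,
    behavior: BehaviorParams = BehaviorParams(),
    sensors: SensorParams = SensorParams(),
    seed: int = 0,
) -> Tuple[GroundTruthSession, SessionRecording]:
    """Convenience: simulate truth and render its sensor streams.

    The behavior and sensor random streams are derived independently from
    ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_beh, s_sen = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    truth = simulate_truth(schedule, layout, behavior, seed=s_beh)
    recording = render_sensors(truth, sensors, seed=s_sen)
    return truth, recording
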