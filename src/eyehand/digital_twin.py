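"""Deterministic top-down 2D replay of a processed session.

The digital twin re-draws the table scene at any time point: table outline,
the 21 location marks, the active paper, ink pads, head and hand markers, a
torso wedge, the current fixation mark, the current motion start-end line,
and 3-second fading trails of the hand path and the gaze target path.  It
exists for qualitative review: episodes flagged by the IQR screen are
replayed, and a reviewer records keep/exclude decisions that feed back into
the metric analysis.  Frames contain only abstract geometry (no identifying
information) and are rendered byte-deterministically so replays are
scriptable and diffable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .gaze_pipeline import FixationSeries
from .hand_fusion import FusedTrajectory
from .body_pose import TorsoSeries
from .session_model import SessionRecording, rotate_yaw
from .task_schedule import Layout

__all__ = [
    "FrameSpec",
    "ReviewDecision",
    "ReplaySession",
    "frame_at",
    "render_frame",
    "export_replay",
    "review_episodes",
    "apply_exclusions",
]

TRAIL_SECONDS = 3.0
REVIEW_REASONS = (
    "tracking_loss",
    "missed_fixation_registration",
    "missed_interaction",
    "behavioral",
    "other",
)


@dataclass
class FrameSpec:
    t: float
    active_paper: Optional[str]
    paper_center: Optional[np.ndarray]
    head: Optional[np.ndarray]
    torso_yaw_deg: Optional[float]
    hand: Optional[np.ndarray]
    fixation_point: Optional[np.ndarray]
    motion_line: Optional[Tuple[np.ndarray, np.ndarray]]
    hand_trail: np.ndarray        # (k, 3) positions in [t-3, t]
    hand_trail_t: np.ndarray
    gaze_trail: np.ndarray        # (k, 2) table points in [t-3, t]
    gaze_trail_t: np.ndarray


@dataclass(frozen=True)
class ReviewDecision:
    episode_index: int
    verdict: str                  # keep | exclude
    reason: Optional[str] = None
    note: str = ""

    def __post_init__(self):
        if self.verdict not in ("keep", "exclude"):
            raise ValueError(f"verdict must be keep or exclude, got {self.verdict!r}")
        if self.verdict == "exclude" and self.reason not in REVIEW_REASONS:
            raise ValueError(
                f"excluded episodes need a reason from {REVIEW_REASONS}"
            )


@dataclass
class ReplaySession:
    """Precomputed drawing data for a processed session."""

    layout: Layout
    t_start: float
    t_end: float
    episode_windows: List[Tuple[float, float, str]]     # (appear, end, location)
    motion_windows: List[Tuple[float, float, str, str]]  # (onset~ink_exit, stamp, loc, color)
    hand_t: np.ndarray
    hand_p: np.ndarray
    head_t: np.ndarray
    head_p: np.ndarray
    torso: Optional[TorsoSeries]
    fixations: FixationSeries
    gaze_point_t: np.ndarray
    gaze_point_xy: np.ndarray

    @classmethod
    def from_processed(
        cls,
        recording: SessionRecording,
        layout: Layout,
        fused: FusedTrajectory,
        fixations: FixationSeries,
        torso: Optional[TorsoSeries] = None,
    ) -> "ReplaySession":
        appear: Dict[int, float] = {}
        ink_exit: Dict[int, float] = {}
        windows, motions = [], []
        for ev in recording.events:
            if ev.kind == "paper_appear":
                appear[ev.episode_index] = ev.t
            elif ev.kind == "ink_exited":
                ink_exit[ev.episode_index] = ev.t
            elif ev.kind in ("stamp", "timeout_advance"):
                ep = recording.schedule.episodes[ev.episode_index]
                windows.append((appear[ev.episode_index], ev.t, ep.location_id))
                if ev.kind == "stamp" and ev.episode_index in ink_exit:
                    motions.append(
                        (ink_exit[ev.episode_index], ev.t, ep.location_id, ep.color)
                    )

        # gaze-target trail: intersection of the gaze ray with the table plane
        g = recording.gaze
        dz = g.direction[:, 2]
        ok = np.abs(dz) > 1e-9
        s = np.where(ok, -g.origin[:, 2] / np.where(ok, dz, 1.0), -1.0)
        ok &= s > 0
        pts = g.origin[:, :2] + s[:, None] * g.direction[:, :2]

        return cls(
            layout=layout,
            t_start=float(min(fused.grid[0], g.t[0])) if len(g) else float(fused.grid[0]),
            t_end=float(max(fused.grid[-1], g.t[-1])) if len(g) else float(fused.grid[-1]),
            episode_windows=windows,
            motion_windows=motions,
            hand_t=fused.grid,
            hand_p=fused.position,
            head_t=recording.head.t,
            head_p=recording.head.position,
            torso=torso,
            fixations=fixations,
            gaze_point_t=g.t[ok],
            gaze_point_xy=pts[ok],
        )


def frame_at(session: ReplaySession, t: float) -> FrameSpec:
    """Assemble all drawables for time t (raises outside the session span)."""
    if not session.t_start <= t <= session.t_end:
        raise ValueError(f"t={t} outside session span "
                         f"[{session.t_start}, {session.t_end}]")
    active, center = None, None
    for t0, t1, lid in session.episode_windows:
        if t0 <= t <= t1:
            active, center = lid, session.layout.position(lid)
            break

    motion_line = None
    spec = session.layout.spec
    for t0, t1, lid, color in session.motion_windows:
        if t0 <= t <= t1:
            pad = np.asarray(
                spec.ink_pad_positions[0 if color == "violet" else 1], dtype=float
            )
            motion_line = (pad, session.layout.position(lid))
            break

    def interp(ts: np.ndarray, ps: np.ndarray) -> Optional[np.ndarray]:
        if len(ts) == 0 or t < ts[0] or t > ts[-1]:
            return None
        return np.array([np.interp(t, ts, ps[:, k]) for k in range(ps.shape[1])])

    fixation_point = None
    for iv in session.fixations.intervals:
        if iv.onset_t <= t <= iv.offset_t:
            if iv.target in session.layout.locations:
                fixation_point = session.layout.position(iv.target)
            elif iv.target == "pad_violet":
                fixation_point = np.asarray(spec.ink_pad_positions[0], dtype=float)
            elif iv.target == "pad_orange":
                fixation_point = np.asarray(spec.ink_pad_positions[1], dtype=float)
            break

    torso_yaw = None
    if session.torso is not None and len(session.torso.t):
        m = session.torso.valid & (session.torso.t <= t)
        if m.any():
            torso_yaw = float(session.torso.yaw_deg[np.nonzero(m)[0][-1]])

    hm = (session.hand_t >= t - TRAIL_SECONDS) & (session.hand_t <= t)
    gm = (session.gaze_point_t >= t - TRAIL_SECONDS) & (session.gaze_point_t <= t)
    return FrameSpec(
        t=t,
        active_paper=active,
        paper_center=center,
        head=interp(session.head_t, session.head_p),
        torso_yaw_deg=torso_yaw,
        hand=interp(session.hand_t, session.hand_p),
        fixation_point=fixation_point,
        motion_line=motion_line,
        hand_trail=session.hand_p[hm],
        hand_trail_t=session.hand_t[hm],
        gaze_trail=session.gaze_point_xy[gm],
        gaze_trail_t=session.gaze_point_t[gm],
    )


# ---------------------------------------------------------------------------
# rendering


def _to_px(xy, size: Tuple[int, int], extent: Tuple[float, float]) -> Tuple[int, int]:
    w, h = size
    ex, ey = extent
    x = (xy[0] / ex + 0.5) * (w - 1)
    y = (1.0 - (xy[1] / ey + 0.75)) * (h - 1)  # user edge near the bottom
    return int(round(x)), int(round(y))


def render_frame(
    session: ReplaySession, frame: FrameSpec, size: Tuple[int, int] = (480, 360)
) -> Image.Image:
    """Draw one frame.  Trail alpha fades linearly over the 3 s window."""
    spec = session.layout.spec
    extent = (spec.table_extent[0] * 1.3, spec.table_extent[1] * 2.0)
    img = Image.new("RGB", size, (255, 255, 255))
    draw = ImageDraw.Draw(img)

    tw, td = spec.table_extent[0] / 2.0, spec.table_extent[1] / 2.0
    corners = [(-tw, -td), (tw, -td), (tw, td), (-tw, td)]
    draw.polygon([_to_px(c, size, extent) for c in corners], outline=(120, 120, 120))

    for lid in session.layout.locations:
        px, py = _to_px(session.layout.position(lid), size, extent)
        draw.line([(px - 3, py - 3), (px + 3, py + 3)], fill=(200, 200, 200))
        draw.line([(px - 3, py + 3), (px + 3, py - 3)], fill=(200, 200, 200))

    for pad, col in zip(spec.ink_pad_positions, ((150, 60, 200), (240, 140, 40))):
        px, py = _to_px(pad, size, extent)
        r = int(spec.ink_pad_radius / extent[0] * size[0])
        draw.ellipse([px - r, py - r, px + r, py + r], outline=col)

    if frame.paper_center is not None:
        hw = spec.paper_size[0] / 2.0
        hh = spec.paper_size[1] / 2.0
        c = frame.paper_center
        p0 = _to_px((c[0] - hw, c[1] + hh), size, extent)
        p1 = _to_px((c[0] + hw, c[1] - hh), size, extent)
        draw.rectangle([p0, p1], outline=(0, 0, 0))

    def fading_trail(ts, pts, base):
        for tt, p in zip(ts, pts):
            age = (frame.t - tt) / TRAIL_SECONDS
            alpha = max(0.0, 1.0 - age)  # linear fade
            col = tuple(int(255 - (255 - b) * alpha) for b in base)
            px, py = _to_px(p, size, extent)
            draw.point((px, py), fill=col)

    fading_trail(frame.hand_trail_t, frame.hand_trail, (220, 30, 30))
    fading_trail(frame.gaze_trail_t, frame.gaze_trail, (0, 0, 0))

    if frame.motion_line is not None:
        a = _to_px(frame.motion_line[0], size, extent)
        b = _to_px(frame.motion_line[1], size, extent)
        draw.line([a, b], fill=(230, 0, 230), width=2)

    if frame.torso_yaw_deg is not None and frame.head is not None:
        hx, hy = frame.head[0], frame.head[1]
        f = rotate_yaw(np.array([0.0, 1.0, 0.0]), frame.torso_yaw_deg) * 0.18
        a = _to_px((hx - f[0] * 0.5, hy - f[1] * 0.5), size, extent)
        b = _to_px((hx + f[0], hy + f[1]), size, extent)
        draw.line([a, b], fill=(150, 90, 40), width=3)

    if frame.head is not None:
        px, py = _to_px(frame.head, size, extent)
        draw.ellipse([px - 5, py - 5, px + 5, py + 5], outline=(150, 90, 40))

    if frame.hand is not None:
        px, py = _to_px(frame.hand, size, extent)
        draw.ellipse([px - 4, py - 4, px + 4, py + 4], fill=(220, 30, 30))

    if frame.fixation_point is not None:
        px, py = _to_px(frame.fixation_point, size, extent)
        draw.line([(px - 5, py - 5), (px + 5, py + 5)], fill=(0, 0, 0), width=2)
        draw.line([(px - 5, py + 5), (px + 5, py - 5)], fill=(0, 0, 0), width=2)

    return img


def export_replay(
    session: ReplaySession,
    out_dir,
    fps: float = 10.0,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
    size: Tuple[int, int] = (480, 360),
) -> List[Path]:
    """Export a deterministic PNG frame sequence at ``fps``.

    Frame count is ceil(duration * fps); identical inputs produce
    byte-identical frames.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = session.t_start if t_start is None else t_start
    t1 = session.t_end if t_end is None else t_end
    n = int(math.ceil((t1 - t0) * fps))
    paths = []
    for i in range(n):
        t = min(t0 + i / fps, session.t_end)
        img = render_frame(session, frame_at(session, t), size=size)
        p = out_dir / f"frame_{i:05d}.png"
        img.save(p, format="PNG")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# review workflow


def review_episodes(
    flagged: Sequence[int], decisions: Sequence[ReviewDecision]
) -> Tuple[pd.DataFrame, List[str]]:
    """Fold reviewer decisions into an exclusion table.

    Undecided flagged episodes stay included.  Decisions referencing
    unflagged episodes are kept in the audit log (with a warning entry) but
    still honored only if they exclude a flagged episode.
    """
    flagged_set = set(int(i) for i in flagged)
    audit: List[str] = []
    rows = []
    for d in decisions:
        if d.episode_index not in flagged_set:
            audit.append(
                f"decision for unflagged episode {d.episode_index} ignored "
                f"({d.verdict}, {d.reason})"
            )
            continue
        if d.verdict == "exclude":
            rows.append(
                {
                    "episode_index": d.episode_index,
                    "excluded": True,
                    "reason": d.reason,
                    "note": d.note,
                }
            )
    return pd.DataFrame(rows, columns=["episode_index", "excluded", "reason", "note"]), audit


def apply_exclusions(frame: pd.DataFrame, exclusions: pd.DataFrame) -> pd.DataFrame:
    """Mark excluded episodes in an episode-metrics table (returns a copy)."""
    out = frame.copy()
    for _, row in exclusions.iterrows():
        m = out["episode_index"] == row["episode_index"]
        out.loc[m, "excluded"] = True
        out.loc[m, "exclusion_reason"] = row["reason"]
    return out
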