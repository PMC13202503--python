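"""Torso yaw reconstruction from external body tracking, and head yaw.

Torso rotation is rebuilt from the shoulder joints: the horizontal shoulder
axis (right minus left shoulder), rotated -90 deg in the yaw sense, gives
the torso forward direction, whose signed yaw (positive rightward) is the
torso rotation.  A plausibility check — the head must project between the
two shoulders along the shoulder axis — masks implausible body-tracking
frames before the yaw is trusted.  Head yaw is taken directly from the
headset pose stream, which needs no filtering thanks to the device's robust
self-localization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .session_model import BodyStream, HeadStream, rotate_yaw, yaw_of

__all__ = ["TorsoSeries", "torso_yaw", "head_between_shoulders", "torso_series", "head_yaw_series"]

MIN_SHOULDER_AXIS_M = 0.05


@dataclass
class TorsoSeries:
    t: np.ndarray
    yaw_deg: np.ndarray      # NaN where invalid
    valid: np.ndarray
    availability: float

    def mean_in(self, t0: float, t1: float) -> float:
        m = (self.t >= t0) & (self.t <= t1) & self.valid
        return float(np.mean(self.yaw_deg[m])) if m.any() else np.nan


def torso_yaw(
    shoulder_left: np.ndarray, shoulder_right: np.ndarray
) -> Optional[float]:
    """Signed torso yaw (degrees, + rightward) from the two shoulder joints.

    Returns None when either joint is missing or the horizontal shoulder
    axis is degenerate (< 5 cm).
    """
    sl = np.asarray(shoulder_left, dtype=float)
    sr = np.asarray(shoulder_right, dtype=float)
    if not (np.all(np.isfinite(sl)) and np.all(np.isfinite(sr))):
        return None
    s = sr - sl
    if np.hypot(s[0], s[1]) < MIN_SHOULDER_AXIS_M:
        return None
    forward = rotate_yaw(np.array([s[0], s[1], 0.0]), -90.0)
    return yaw_of(forward)


def head_between_shoulders(
    head: np.ndarray,
    shoulder_left: np.ndarray,
    shoulder_right: np.ndarray,
    margin: float = 0.15,
) -> bool:
    """Plausibility check: head projects onto the shoulder segment.

    The scalar projection of (head - left shoulder) onto the shoulder axis,
    normalized by the axis length, must lie in [-margin, 1 + margin].
    """
    h = np.asarray(head, dtype=float)
    sl = np.asarray(shoulder_left, dtype=float)
    sr = np.asarray(shoulder_right, dtype=float)
    if not all(np.all(np.isfinite(a)) for a in (h, sl, sr)):
        return False
    axis = sr - sl
    norm2 = float(axis @ axis)
    if norm2 < MIN_SHOULDER_AXIS_M**2:
        return False
    proj = float((h - sl) @ axis) / norm2
    return -margin <= proj <= 1.0 + margin


def torso_series(body: BodyStream, margin: float = 0.15) -> TorsoSeries:
    """Per-sample torso yaw with sanity-check masking.

    Samples fail when a shoulder is missing, the shoulder axis is
    degenerate, or the head does not sit between the shoulders.
    """
    n = len(body)
    yaw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    sl = body.joints.get("shoulder_left")
    sr = body.joints.get("shoulder_right")
    hd = body.joints.get("head")
    if sl is not None and sr is not None:
        vl, vr = body.valid["shoulder_left"], body.valid["shoulder_right"]
        vh = body.valid["head"] if hd is not None else np.zeros(n, dtype=bool)
        for i in range(n):
            if not (vl[i] and vr[i]):
                continue
            # the head check can only veto frames where the head is tracked
            if vh[i] and not head_between_shoulders(hd[i], sl[i], sr[i], margin):
                continue
            y = torso_yaw(sl[i], sr[i])
            if y is not None:
                yaw[i] = y
                valid[i] = True
    return TorsoSeries(
        t=body.t.copy(),
        yaw_deg=yaw,
        valid=valid,
        availability=float(valid.mean()) if n else 0.0,
    )


def head_yaw_series(head: HeadStream) -> Tuple[np.ndarray, np.ndarray]:
    """Signed head yaw per sample from the headset forward vectors."""
    n = len(head)
    yaw = np.full(n, np.nan)
    for i in range(n):
        y = yaw_of(head.forward[i])
        if y is not None:
            yaw[i] = y
    return head.t.copy(), yaw
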