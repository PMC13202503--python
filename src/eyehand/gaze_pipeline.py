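"""Gaze-ray intersection, fixation filtering and signed gaze angles.

The headset logs both the raw gaze ray (origin + direction) and the object
the ray intersects at each update.  Downstream analysis needs two filtered
views of this signal:

* a categorical target series, cleaned with a majority filter over a
  7-sample window so that a target counts as fixated when first intersected
  provided the gaze then stays on it for at least half of the window
  (~0.085 s at 40 Hz); only papers and ink pads are targets of interest;
* the continuous gaze origin/direction vectors, cleaned with a 0.35 s
  running median (the headset's gaze estimate carries 1.5-3 deg of noise).

Yaw angles are signed per the table-frame convention (positive rightward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .session_model import GazeStream, yaw_of
from .task_schedule import Layout

__all__ = [
    "SceneGeometry",
    "FixationInterval",
    "FixationSeries",
    "intersect_gaze",
    "compute_hits",
    "filter_targets",
    "filter_gaze_vectors",
    "horizontal_gaze_angle",
]

BACKGROUND = None
PAD_IDS = ("pad_violet", "pad_orange")
TABLE_ID = "table"


@dataclass
class SceneGeometry:
    """Instantaneous scene: at most one active paper, two ink pads, the table.

    All objects lie in the table plane (z = 0); papers are axis-aligned
    rectangles around their location center.
    """

    table_extent: Tuple[float, float]                 # width x depth, m
    pad_centers: Tuple[np.ndarray, np.ndarray]
    pad_radius: float
    paper_id: Optional[str] = None
    paper_center: Optional[np.ndarray] = None
    paper_size: Tuple[float, float] = (0.148, 0.210)

    @classmethod
    def from_layout(cls, layout: Layout, paper_id: Optional[str] = None) -> "SceneGeometry":
        spec = layout.spec
        return cls(
            table_extent=spec.table_extent,
            pad_centers=(
                np.asarray(spec.ink_pad_positions[0], dtype=float),
                np.asarray(spec.ink_pad_positions[1], dtype=float),
            ),
            pad_radius=spec.ink_pad_radius,
            paper_id=paper_id,
            paper_center=(layout.position(paper_id) if paper_id else None),
            paper_size=spec.paper_size,
        )


def intersect_gaze(
    origin: Sequence[float], direction: Sequence[float], scene: SceneGeometry
) -> Optional[str]:
    """Nearest forward intersection of a gaze ray with the scene.

    All scene objects are coplanar (the table plane), so the priority order
    paper > ink pad > table resolves coincident hits.  Returns None if the
    ray misses everything or never reaches the plane.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("gaze direction must be non-zero")
    d = d / n
    if abs(d[2]) < 1e-12:
        return None
    s = -o[2] / d[2]
    if s <= 1e-9:
        return None
    p = o + s * d
    return _classify_plane_point(p[0], p[1], scene)


def _classify_plane_point(x: float, y: float, scene: SceneGeometry) -> Optional[str]:
    if scene.paper_center is not None:
        hw, hh = scene.paper_size[0] / 2.0, scene.paper_size[1] / 2.0
        cx, cy = scene.paper_center[0], scene.paper_center[1]
        if abs(x - cx) <= hw and abs(y - cy) <= hh:
            return scene.paper_id
    for pad_id, c in zip(PAD_IDS, scene.pad_centers):
        if (x - c[0]) ** 2 + (y - c[1]) ** 2 <= scene.pad_radius**2:
            return pad_id
    tw, td = scene.table_extent[0] / 2.0, scene.table_extent[1] / 2.0
    if abs(x) <= tw and abs(y) <= td:
        return TABLE_ID
    return None


def compute_hits(
    gaze: GazeStream,
    layout: Layout,
    active_paper: List[Tuple[float, float, str]],
) -> List[Optional[str]]:
    """Vectorized hit recomputation for a whole stream.

    ``active_paper`` lists (t_start, t_end, location_id) intervals during
    which a paper is shown at that location.
    """
    n = len(gaze)
    if n == 0:
        return []
    o, d = gaze.origin, gaze.direction
    hits: List[Optional[str]] = [None] * n
    dz = d[:, 2]
    ok = np.abs(dz) > 1e-12
    s = np.where(ok, -o[:, 2] / np.where(ok, dz, 1.0), -1.0)
    reach = ok & (s > 1e-9)
    px = o[:, 0] + s * d[:, 0]
    py = o[:, 1] + s * d[:, 1]

    scene = SceneGeometry.from_layout(layout)
    tw, td = scene.table_extent[0] / 2.0, scene.table_extent[1] / 2.0
    on_table = reach & (np.abs(px) <= tw) & (np.abs(py) <= td)
    for i in np.nonzero(on_table)[0]:
        hits[i] = TABLE_ID
    for pad_id, c in zip(PAD_IDS, scene.pad_centers):
        in_pad = reach & ((px - c[0]) ** 2 + (py - c[1]) ** 2 <= scene.pad_radius**2)
        for i in np.nonzero(in_pad)[0]:
            hits[i] = pad_id
    hw, hh = scene.paper_size[0] / 2.0, scene.paper_size[1] / 2.0
    for t0, t1, lid in active_paper:
        c = layout.position(lid)
        i0, i1 = np.searchsorted(gaze.t, [t0, t1])
        seg = slice(i0, i1)
        in_paper = (
            reach[seg]
            & (np.abs(px[seg] - c[0]) <= hw)
            & (np.abs(py[seg] - c[1]) <= hh)
        )
        for i in np.nonzero(in_paper)[0]:
            hits[i0 + i] = lid
    return hits


# ---------------------------------------------------------------------------
# fixation filtering


@dataclass(frozen=True)
class FixationInterval:
    target: str
    onset_t: float      # back-dated to the first raw intersection
    offset_t: float
    accepted_t: float   # time the majority filter first accepted the target


@dataclass
class FixationSeries:
    t: np.ndarray
    filtered: List[Optional[str]]       # per-sample interest target or None
    intervals: List[FixationInterval]
    window: int

    def first_on(self, target: str, t_min: float) -> Optional[FixationInterval]:
        """Earliest fixation interval on ``target`` beginning at/after t_min."""
        for iv in self.intervals:
            if iv.target == target and iv.onset_t >= t_min:
                return iv
        return None


def _is_interest(label: Optional[str]) -> bool:
    return label is not None and label != TABLE_ID


def filter_targets(
    t: np.ndarray, hits: Sequence[Optional[str]], window: int = 7
) -> FixationSeries:
    """Majority-filter the categorical gaze-target series into fixations.

    Only interest targets (papers, ink pads) survive; table and misses are
    background.  A sample is labeled with a target when that target covers at
    least 50% of the centered window (ties between two targets go to the one
    intersected earlier).  Each fixation interval's onset is back-dated to
    the first raw intersection of its target within one window before the
    filtered acceptance.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    t = np.asarray(t, dtype=float)
    n = len(t)
    hits = list(hits)
    half = window // 2
    need = (window + 1) // 2  # >= 50% of the window

    first_seen: Dict[str, int] = {}
    for i, h in enumerate(hits):
        if _is_interest(h) and h not in first_seen:
            first_seen[h] = i

    filtered: List[Optional[str]] = [None] * n
    counts: Dict[str, int] = {}
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        counts.clear()
        for j in range(lo, hi):
            h = hits[j]
            if _is_interest(h):
                counts[h] = counts.get(h, 0) + 1
        best, best_c = None, 0
        for lab, c in counts.items():
            if c > best_c or (c == best_c and best is not None and first_seen[lab] < first_seen[best]):
                best, best_c = lab, c
        if best is not None and best_c >= need:
            filtered[i] = best

    # maximal same-label runs; runs of one target separated by less than
    # half a window of background belong to the same fixation
    runs: List[Tuple[int, int, str]] = []
    i = 0
    while i < n:
        lab = filtered[i]
        if lab is None:
            i += 1
            continue
        j = i
        while j + 1 < n and filtered[j + 1] == lab:
            j += 1
        if runs and runs[-1][2] == lab and i - runs[-1][1] <= half:
            runs[-1] = (runs[-1][0], j, lab)
        else:
            runs.append((i, j, lab))
        i = j + 1

    intervals: List[FixationInterval] = []
    for i, j, lab in runs:
        onset_idx = i
        for k in range(i, max(-1, i - window - 1), -1):
            if hits[k] == lab:
                onset_idx = k
        intervals.append(
            FixationInterval(
                target=lab,
                onset_t=float(t[onset_idx]),
                offset_t=float(t[j]),
                accepted_t=float(t[i]),
            )
        )

    return FixationSeries(t=t, filtered=filtered, intervals=intervals, window=window)


def filter_gaze_vectors(gaze: GazeStream, window_s: float = 0.35) -> GazeStream:
    """Running time-window median of gaze origin and direction.

    The window is time-based (robust to frame drops); filtered directions
    are renormalized to unit length.
    """
    n = len(gaze)
    if n == 0:
        return gaze
    t = gaze.t
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    origin = np.empty_like(gaze.origin)
    direction = np.empty_like(gaze.direction)
    for i in range(n):
        sl = slice(lo[i], hi[i])
        origin[i] = np.median(gaze.origin[sl], axis=0)
        direction[i] = np.median(gaze.direction[sl], axis=0)
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    direction = direction / norms
    return GazeStream(t=t.copy(), origin=origin, direction=direction, hit=list(gaze.hit))


def horizontal_gaze_angle(direction: Sequence[float]) -> Optional[float]:
    """Signed yaw of the horizontal gaze projection, degrees, + rightward.

    None for (near-)vertical rays.
    """
    return yaw_of(direction)
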