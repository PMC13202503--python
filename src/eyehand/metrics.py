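"""Episode metrics and lateral statistics for the stamping task.

Per episode the pipeline extracts: the search phase (paper appearance to
first registered fixation on it), time-to-find, omissions at the session
timeout, search-phase orientation averages (gaze / head / torso yaw,
positive rightward), the hand-motion onset refined from velocity minima,
the gaze-anchoring offset (target fixation time minus motion onset), and
motion duration.  Group analysis mirrors the study protocol: each location
in the two leftmost sectors is paired with its right mirror; per-user
lateral differences (left minus right pair means, averaged over pairs) are
tested against zero with a two-sided Wilcoxon signed-rank test at
alpha = 0.05.  Episodes whose motion duration or time-to-find falls outside
1.5 IQR fences of the user's own distribution are flagged for review, not
automatically excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .gaze_pipeline import FixationSeries, horizontal_gaze_angle
from .hand_fusion import FusedTrajectory
from .body_pose import TorsoSeries
from .session_model import GazeStream, SessionRecording
from .task_schedule import Layout, leftmost_sector_ids

__all__ = [
    "EpisodeMetrics",
    "LateralDifferenceReport",
    "StatsConfig",
    "segment_episodes",
    "episodes_to_frame",
    "detect_motion_onset",
    "gaze_anchoring_offset",
    "pairwise_lateral",
    "iqr_flags",
    "wilcoxon_signed_rank",
    "pearson_r",
    "summarize_group",
    "format_summary",
]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    iqr_multiplier: float = 1.5
    k_sectors: int = 2

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class EpisodeMetrics:
    episode_index: int
    location_id: str
    side: str                      # left | right | center
    hand: str
    t_appear: float
    t_first_fix: Optional[float] = None
    time_to_find_s: Optional[float] = None
    omitted: bool = False
    mean_gaze_yaw_deg: float = np.nan
    mean_head_yaw_deg: float = np.nan
    mean_torso_yaw_deg: float = np.nan
    t_onset: Optional[float] = None
    t_anchor: Optional[float] = None
    anchor_offset_s: Optional[float] = None
    motion_duration_s: Optional[float] = None
    flagged_for_review: bool = False
    excluded: bool = False
    exclusion_reason: Optional[str] = None


def episodes_to_frame(episodes: Sequence[EpisodeMetrics]) -> pd.DataFrame:
    rows = []
    for e in episodes:
        rows.append(
            {
                "episode_index": e.episode_index,
                "location_id": e.location_id,
                "side": e.side,
                "hand": e.hand,
                "t_appear": e.t_appear,
                "t_first_fix": np.nan if e.t_first_fix is None else e.t_first_fix,
                "time_to_find_s": np.nan if e.time_to_find_s is None else e.time_to_find_s,
                "omitted": e.omitted,
                "mean_gaze_yaw_deg": e.mean_gaze_yaw_deg,
                "mean_head_yaw_deg": e.mean_head_yaw_deg,
                "mean_torso_yaw_deg": e.mean_torso_yaw_deg,
                "t_onset": np.nan if e.t_onset is None else e.t_onset,
                "t_anchor": np.nan if e.t_anchor is None else e.t_anchor,
                "anchor_offset_s": np.nan if e.anchor_offset_s is None else e.anchor_offset_s,
                "motion_duration_s": np.nan if e.motion_duration_s is None else e.motion_duration_s,
                "flagged_for_review": e.flagged_for_review,
                "excluded": e.excluded,
                "exclusion_reason": e.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motion onset


def detect_motion_onset(
    fused: FusedTrajectory,
    ink_pad: np.ndarray,
    target: np.ndarray,
    t_ink_exit: float,
    t_stamp: float,
    reference_duration: Optional[float] = None,
    pre_window_s: float = 0.5,
    align_horizon_s: float = 0.15,
) -> float:
    """Refine the motion onset from velocity minima in the movement window.

    Candidates are the local minima of the smoothed hand speed in
    [t_ink_exit - pre_window_s, t_stamp]; each is scored by the unweighted
    mean of four components normalized to their physical scales: distance
    to the ink pad (per movement length), speed magnitude (per window peak
    speed), misalignment of the subsequent displacement over
    ``align_horizon_s`` with the pad-to-target vector (per full reversal),
    and deviation of the implied reach duration from a reference (the
    user's running median of recorded pad-exit-to-stamp durations; fallback
    t_stamp - t_ink_exit), per window length.  The physical scales keep the
    score meaningful when many near-stationary candidates cluster at
    near-zero speed and distance.  Lowest combined score wins, earliest on
    ties; without any candidate the ink-exit time is returned.
    """
    if t_ink_exit >= t_stamp:
        raise ValueError("t_ink_exit must precede t_stamp")
    t = fused.grid
    m = (t >= t_ink_exit - pre_window_s) & (t <= t_stamp)
    idx = np.nonzero(m)[0]
    if len(idx) == 0:
        raise ValueError("empty movement window")
    speed = fused.speed()
    s = speed[idx]
    cand = [
        i
        for i in range(1, len(s) - 1)
        if s[i] <= s[i - 1] and s[i] <= s[i + 1] and (s[i] < s[i - 1] or s[i] < s[i + 1])
    ]
    if not cand:
        return float(t_ink_exit)

    ink_pad = np.asarray(ink_pad, dtype=float)
    target = np.asarray(target, dtype=float)
    move_vec = target - ink_pad
    move_norm = np.linalg.norm(move_vec)
    if move_norm < 1e-9:
        return float(t_ink_exit)
    ref = reference_duration if reference_duration is not None else t_stamp - t_ink_exit
    peak = float(s.max())
    window_len = float(t[idx[-1]] - t[idx[0]])

    scores, times = [], []
    for i in cand:
        gi = idx[i]
        tc = float(t[gi])
        p = fused.position[gi]
        disp = fused.position_at(tc + align_horizon_s)[0] - p
        dn = np.linalg.norm(disp)
        # sub-millimeter displacements are tracking noise, not movement:
        # give them no directional credit instead of a chance alignment
        cosang = float(disp @ move_vec) / (dn * move_norm) if dn > 1e-3 else 0.0
        f_dist = float(np.linalg.norm(p - ink_pad)) / move_norm
        f_speed = float(s[i]) / peak if peak > 1e-12 else 0.0
        f_align = (1.0 - cosang) / 2.0
        f_time = abs(t_stamp - tc - ref) / window_len if window_len > 1e-12 else 0.0
        scores.append((f_dist + f_speed + f_align + f_time) / 4.0)
        times.append(tc)

    best = int(np.lexsort((times, scores))[0])
    return times[best]


def gaze_anchoring_offset(
    paper_id: str,
    fixations: FixationSeries,
    t_ink_selection: float,
    t_onset: float,
) -> Optional[float]:
    """Target re-fixation time relative to motion onset, seconds.

    First fixation interval on the episode's paper beginning at or after
    the ink selection, minus the motion onset; negative values mean the
    target was fixated before the hand started moving.  None when no
    re-fixation was registered.
    """
    iv = fixations.first_on(paper_id, t_ink_selection)
    if iv is None:
        return None
    return float(iv.onset_t - t_onset)


# ---------------------------------------------------------------------------
# episode segmentation


def segment_episodes(
    recording: SessionRecording,
    layout: Layout,
    fused: FusedTrajectory,
    fixations: FixationSeries,
    gaze_filtered: GazeStream,
    torso: TorsoSeries,
    head_yaw: Tuple[np.ndarray, np.ndarray],
    stats_config: StatsConfig = StatsConfig(),
) -> List[EpisodeMetrics]:
    """Extract per-episode metrics from the processed streams.

    Streams must already be synchronized and fused.  The search phase is
    [t_appear, t_first_fix], or the full timeout when the target was never
    fixated (omission).  Motion metrics need the recorded ink-pad and stamp
    events; the onset reference duration is the running median of this
    user's accepted reach durations.
    """
    timeout = recording.schedule.timeout
    events_by_ep: Dict[int, Dict[str, float]] = {}
    for ev in recording.events:
        events_by_ep.setdefault(ev.episode_index, {})[ev.kind] = ev.t

    gaze_yaw = np.full(len(gaze_filtered), np.nan)
    for i in range(len(gaze_filtered)):
        y = horizontal_gaze_angle(gaze_filtered.direction[i])
        if y is not None:
            gaze_yaw[i] = y
    head_t, head_y = head_yaw

    spec = layout.spec
    pad_by_color = {
        "violet": np.asarray(spec.ink_pad_positions[0], dtype=float),
        "orange": np.asarray(spec.ink_pad_positions[1], dtype=float),
    }

    out: List[EpisodeMetrics] = []
    reach_durations: List[float] = []
    for idx, ep in enumerate(recording.schedule.episodes):
        evs = events_by_ep.get(idx)
        if evs is None or "paper_appear" not in evs:
            raise ValueError(f"episode {idx} has no paper_appear event")
        t_appear = evs["paper_appear"]
        side = layout.side_of(ep.location_id, stats_config.k_sectors)
        em = EpisodeMetrics(
            episode_index=idx,
            location_id=ep.location_id,
            side=side,
            hand=ep.hand,
            t_appear=t_appear,
        )

        iv = fixations.first_on(ep.location_id, t_appear - 0.1)
        if iv is not None and iv.onset_t <= t_appear + timeout:
            em.t_first_fix = max(iv.onset_t, t_appear)
            em.time_to_find_s = em.t_first_fix - t_appear
            search_end = em.t_first_fix
        else:
            em.omitted = True
            search_end = t_appear + timeout

        gm = (gaze_filtered.t >= t_appear) & (gaze_filtered.t <= search_end)
        if gm.any():
            em.mean_gaze_yaw_deg = float(np.nanmean(gaze_yaw[gm]))
        hm = (head_t >= t_appear) & (head_t <= search_end)
        if hm.any():
            em.mean_head_yaw_deg = float(np.nanmean(head_y[hm]))
        em.mean_torso_yaw_deg = torso.mean_in(t_appear, search_end)

        if not em.omitted and "ink_exited" in evs and "stamp" in evs:
            ref = float(np.median(reach_durations)) if reach_durations else None
            t_onset = detect_motion_onset(
                fused,
                pad_by_color[ep.color],
                layout.position(ep.location_id),
                evs["ink_exited"],
                evs["stamp"],
                reference_duration=ref,
            )
            em.t_onset = t_onset
            em.motion_duration_s = evs["stamp"] - t_onset
            # reference for the next episode's temporal-consistency factor:
            # the recorded pad-exit-to-stamp duration (stable, event-based)
            reach_durations.append(evs["stamp"] - evs["ink_exited"])
            if "ink_entered" in evs:
                off = gaze_anchoring_offset(
                    ep.location_id, fixations, evs["ink_entered"], t_onset
                )
                if off is not None:
                    em.anchor_offset_s = off
                    em.t_anchor = t_onset + off
        out.append(em)

    # IQR review flags per user, over motion duration and time-to-find
    for attr in ("motion_duration_s", "time_to_find_s"):
        vals = np.array(
            [getattr(e, attr) if getattr(e, attr) is not None else np.nan for e in out]
        )
        flags = iqr_flags(vals, stats_config.iqr_multiplier)
        for e, f in zip(out, flags):
            if f:
                e.flagged_for_review = True
    return out


# ---------------------------------------------------------------------------
# group statistics


def iqr_flags(values: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Flag values beyond quartile +/- multiplier * IQR (linear-interpolated
    quartiles).  Fewer than 4 finite values: no flags, with a warning."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 finite values; no IQR flags computed")
        return np.zeros(len(v), dtype=bool)
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    flags = np.zeros(len(v), dtype=bool)
    flags[finite] = (v[finite] < lo) | (v[finite] > hi)
    return flags


def wilcoxon_signed_rank(values: Sequence[float]) -> Tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against zero median.

    Zeros are discarded; absolute values are ranked with midranks for ties.
    The null distribution is exact (full enumeration via subset-sum
    counting) for n <= 25 and a tie-corrected normal approximation beyond.
    Returns (W = sum of positive ranks, two-sided p).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    v = v[v != 0.0]
    n = len(v)
    if n == 0:
        raise ValueError("all values are zero; the test is undefined")
    ranks = stats.rankdata(np.abs(v))
    w_pos = float(np.sum(ranks[v > 0]))

    if n <= 25:
        # integer subset-sum DP over doubled ranks (midranks are halves)
        weights = np.rint(2 * ranks).astype(int)
        total = int(weights.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for w in weights:
            counts[w:] += counts[:-w].copy() if w > 0 else counts
        counts /= 2.0**n
        w2 = int(round(2 * w_pos))
        cdf_le = float(counts[: w2 + 1].sum())
        cdf_ge = float(counts[w2:].sum())
        p = min(1.0, 2.0 * min(cdf_le, cdf_ge))
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w_pos - mu) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return w_pos, p


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length sequences with n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx < 1e-300 or sy < 1e-300:
        raise ValueError("zero variance in an input")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, p


def summarize_group(values: Sequence[float]) -> Dict[str, float]:
    """Median and linear-interpolated quartiles, study reporting style."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(len(v))}


def format_summary(summary: Dict[str, float], unit: str = "") -> str:
    u = f" {unit}" if unit else ""
    return (
        f"median {summary['median']:.3g} "
        f"[{summary['q1']:.3g}-{summary['q3']:.3g}]{u} (n={summary['n']})"
    )


@dataclass
class LateralDifferenceReport:
    """Mirrored-pair lateral differences, per user and pooled.

    ``per_user`` holds each user's mean pair difference (left minus right
    for time-like metrics: positive time-to-find difference = right found
    sooner; negative anchoring difference = left fixated earlier).
    """

    metric: str
    per_user: np.ndarray
    pairs_per_user: List[Dict[str, float]]
    excluded_users: List[int]
    summary: Dict[str, float] = field(default_factory=dict)
    statistic: float = np.nan
    p_value: float = np.nan

    @property
    def n(self) -> int:
        return len(self.per_user)


def pairwise_lateral(
    user_tables: Sequence[pd.DataFrame],
    layout: Layout,
    metric: str,
    k_sectors: int = 2,
    hand: Optional[str] = None,
    min_users_for_test: int = 5,
) -> LateralDifferenceReport:
    """Per-user mirrored-pair lateral differences of an episode metric.

    For every location in the ``k_sectors`` leftmost sectors, the per-user
    mean of the metric (over included episodes) is differenced against its
    right-mirror counterpart (left minus right); pairs missing either side
    are dropped, users with no usable pair are excluded.  The per-user pair
    averages are tested against zero with the exact Wilcoxon signed-rank
    test when enough users remain.
    """
    left_ids = sorted(leftmost_sector_ids(layout, k_sectors))
    per_user: List[float] = []
    details: List[Dict[str, float]] = []
    excluded_users: List[int] = []
    for uid, table in enumerate(user_tables):
        df = table[~table["excluded"]]
        if hand is not None:
            df = df[df["hand"] == hand]
        means = df.groupby("location_id")[metric].mean()
        pair_diffs: Dict[str, float] = {}
        for lid in left_ids:
            rid = layout.mirror[lid]
            lv = means.get(lid, np.nan)
            rv = means.get(rid, np.nan)
            if np.isfinite(lv) and np.isfinite(rv):
                pair_diffs[lid] = float(lv - rv)
        if not pair_diffs:
            excluded_users.append(uid)
            continue
        per_user.append(float(np.mean(list(pair_diffs.values()))))
        details.append(pair_diffs)

    report = LateralDifferenceReport(
        metric=metric,
        per_user=np.asarray(per_user),
        pairs_per_user=details,
        excluded_users=excluded_users,
    )
    if len(per_user):
        report.summary = summarize_group(report.per_user)
    if len(per_user) >= min_users_for_test and np.any(report.per_user != 0):
        report.statistic, report.p_value = wilcoxon_signed_rank(report.per_user)
    return report
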