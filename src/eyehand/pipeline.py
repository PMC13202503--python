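"""End-to-end processing: recording in, episode metrics and group stats out.

Single-session path: synchronize the external stream onto the headset
clock, fuse the two hand streams, filter the gaze vectors and the
gaze-target series, reconstruct torso yaw, then segment episodes into
metrics.  Cohort path: collect per-user episode tables and run the lateral
(mirrored-pair) analyses and orientation-bias tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .body_pose import TorsoSeries, head_yaw_series, torso_series
from .gaze_pipeline import FixationSeries, filter_gaze_vectors, filter_targets
from .hand_fusion import FusedTrajectory, KalmanParams, fuse_streams
from .metrics import (
    EpisodeMetrics,
    LateralDifferenceReport,
    StatsConfig,
    episodes_to_frame,
    pairwise_lateral,
    segment_episodes,
    summarize_group,
    wilcoxon_signed_rank,
)
from .session_model import GazeStream, SessionRecording
from .task_schedule import Layout, LayoutSpec, generate_layout
from .temporal_sync import SyncResult, synchronize_recording

__all__ = [
    "ProcessedSession",
    "OrientationBiasReport",
    "CohortReport",
    "process_recording",
    "analyze_cohort",
    "run_cohort",
]


@dataclass
class ProcessedSession:
    recording: SessionRecording
    layout: Layout
    sync: SyncResult
    fused: FusedTrajectory
    gaze_filtered: GazeStream
    fixations: FixationSeries
    torso: TorsoSeries
    head_yaw: Tuple[np.ndarray, np.ndarray]
    episodes: List[EpisodeMetrics]
    frame: pd.DataFrame


def process_recording(
    recording: SessionRecording,
    layout: Optional[Layout] = None,
    kalman: KalmanParams = KalmanParams(),
    stats_config: StatsConfig = StatsConfig(),
    grid_rate_hz: float = 40.0,
    target_window: int = 7,
    gaze_median_window_s: float = 0.35,
) -> ProcessedSession:
    """Run the full single-session pipeline on a recording."""
    if layout is None:
        layout = generate_layout(LayoutSpec())
    recording, sync = synchronize_recording(recording, grid_rate_hz=grid_rate_hz)
    fused = fuse_streams(
        recording.hands.get("headset"),
        recording.hands.get("external"),
        kalman,
        grid_rate_hz=grid_rate_hz,
    )
    gaze_filtered = filter_gaze_vectors(recording.gaze, gaze_median_window_s)
    fixations = filter_targets(recording.gaze.t, recording.gaze.hit, target_window)
    torso = torso_series(recording.body)
    head_yaw = head_yaw_series(recording.head)
    episodes = segment_episodes(
        recording, layout, fused, fixations, gaze_filtered, torso, head_yaw, stats_config
    )
    return ProcessedSession(
        recording=recording,
        layout=layout,
        sync=sync,
        fused=fused,
        gaze_filtered=gaze_filtered,
        fixations=fixations,
        torso=torso,
        head_yaw=head_yaw,
        episodes=episodes,
        frame=episodes_to_frame(episodes),
    )


def run_cohort(
    n_users: int,
    behavior,
    layout: Optional[Layout] = None,
    sensors=None,
    seed: int = 0,
    kalman: KalmanParams = KalmanParams(),
) -> List[pd.DataFrame]:
    """Simulate and process a cohort; returns per-user episode tables.

    Each simulated user gets their own schedule and sensor-noise seeds
    (derived deterministically from ``seed``), mirroring the study's
    per-participant randomization with fixed seeds.
    """
    from .behavior_sim import SensorParams, simulate_session
    from .task_schedule import generate_schedule

    if layout is None:
        layout = generate_layout(LayoutSpec())
    if sensors is None:
        sensors = SensorParams()
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_users) % (2**31)
    frames = []
    for u in range(n_users):
        schedule = generate_schedule(layout, int(seeds[2 * u]))
        _, recording = simulate_session(
            schedule, layout, behavior, sensors, seed=int(seeds[2 * u + 1])
        )
        frames.append(process_recording(recording, layout, kalman=kalman).frame)
    return frames


@dataclass
class OrientationBiasReport:
    """Per-user search-phase orientation means, tested against zero."""

    metric: str
    per_user: np.ndarray
    summary: Dict[str, float]
    statistic: float
    p_value: float


@dataclass
class CohortReport:
    gaze_bias: OrientationBiasReport
    head_bias: OrientationBiasReport
    torso_bias: OrientationBiasReport
    time_to_find: LateralDifferenceReport
    anchoring: LateralDifferenceReport
    motion_duration: LateralDifferenceReport
    omission_rate_left: float
    omission_rate_right: float


def _orientation_bias(
    frames: Sequence[pd.DataFrame], column: str
) -> OrientationBiasReport:
    per_user = []
    for df in frames:
        vals = df.loc[~df["excluded"], column]
        per_user.append(float(np.nanmean(vals)))
    per_user = np.asarray(per_user)
    stat, p = (np.nan, np.nan)
    if len(per_user) >= 5 and np.any(per_user != 0):
        stat, p = wilcoxon_signed_rank(per_user)
    return OrientationBiasReport(
        metric=column,
        per_user=per_user,
        summary=summarize_group(per_user),
        statistic=stat,
        p_value=p,
    )


def analyze_cohort(
    user_frames: Sequence[pd.DataFrame],
    layout: Layout,
    stats_config: StatsConfig = StatsConfig(),
    auto_exclude_flagged: bool = False,
) -> CohortReport:
    """Group-level analysis over per-user episode tables.

    Perception metrics (orientation means, time-to-find) use all episodes;
    motion metrics (gaze anchoring, motion duration) use right-hand episodes
    only, mirroring the study's analysis population.  With
    ``auto_exclude_flagged`` set, review-flagged episodes are excluded
    without the interactive replay step (headless mode).
    """
    frames = []
    for df in user_frames:
        df = df.copy()
        if auto_exclude_flagged:
            df.loc[df["flagged_for_review"], "excluded"] = True
        frames.append(df)

    k = stats_config.k_sectors
    n_left = sum(int(((f["side"] == "left")).sum()) for f in frames)
    n_right = sum(int(((f["side"] == "right")).sum()) for f in frames)
    om_left = sum(int((f["omitted"] & (f["side"] == "left")).sum()) for f in frames)
    om_right = sum(int((f["omitted"] & (f["side"] == "right")).sum()) for f in frames)

    return CohortReport(
        gaze_bias=_orientation_bias(frames, "mean_gaze_yaw_deg"),
        head_bias=_orientation_bias(frames, "mean_head_yaw_deg"),
        torso_bias=_orientation_bias(frames, "mean_torso_yaw_deg"),
        time_to_find=pairwise_lateral(frames, layout, "time_to_find_s", k),
        anchoring=pairwise_lateral(frames, layout, "anchor_offset_s", k, hand="right"),
        motion_duration=pairwise_lateral(
            frames, layout, "motion_duration_s", k, hand="right"
        ),
        omission_rate_left=om_left / n_left if n_left else np.nan,
        omission_rate_right=om_right / n_right if n_right else np.nan,
    )
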