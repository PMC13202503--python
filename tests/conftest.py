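"""Shared fixtures: layouts, schedules, and simulated sessions.

Heavy simulated sessions are session-scoped so independent test modules
reuse them instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from eyehand.behavior_sim import BehaviorParams, SensorParams, simulate_session
from eyehand.pipeline import process_recording
from eyehand.task_schedule import (
    LayoutSpec,
    SessionSchedule,
    generate_layout,
    generate_schedule,
)


@pytest.fixture(scope="session")
def layout():
    return generate_layout(LayoutSpec())


@pytest.fixture(scope="session")
def schedule(layout):
    return generate_schedule(layout, seed=1)


@pytest.fixture(scope="session")
def mini_schedule(layout):
    """First 8 episodes of a full schedule: fast simulation fixture."""
    full = generate_schedule(layout, seed=3)
    return SessionSchedule(episodes=full.episodes[:8], seed=3, timeout=full.timeout)


@pytest.fixture(scope="session")
def mini_session(layout, mini_schedule):
    """(truth, recording) for a short control session with default sensors."""
    return simulate_session(
        mini_schedule, layout, BehaviorParams.control(), SensorParams(), seed=21
    )


@pytest.fixture(scope="session")
def default_session(layout, schedule):
    """(truth, recording) for a full-length control session, default sensors."""
    return simulate_session(
        schedule, layout, BehaviorParams.control(), SensorParams(), seed=11
    )


@pytest.fixture(scope="session")
def default_processed(layout, default_session):
    """Full pipeline output for the default session."""
    _, recording = default_session
    return process_recording(recording, layout)
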