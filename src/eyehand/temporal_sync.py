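"""Clock-offset estimation between the external and headset streams.

The external tracker streams its poses over the network, so its receiver
timestamps lag the headset clock by transport and processing delay (about
92 ms in the reference acquisition) plus an error from the 30 vs 40 Hz rate
mismatch.  Synchronization is two-step: a robust initial estimate from the
median sender/receiver timestamp difference, then a refinement maximizing
the cross-correlation of the z-scored hand positions from both sources on a
common grid.  Correlation is evaluated at integer grid lags only; the rate
mismatch between the sources does not support sub-sample precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .session_model import BodyStream, HandStream, SessionRecording

__all__ = ["SyncResult", "initial_offset", "resample", "refine_offset", "synchronize_recording"]


@dataclass
class SyncResult:
    initial_offset_s: float
    refined_offset_s: float
    peak_correlation: float
    grid_rate_hz: float
    boundary_warning: bool = False


def initial_offset(send_ts: np.ndarray, recv_ts: np.ndarray) -> float:
    """Median of paired receiver - sender timestamp differences.

    The median is robust to occasional network spikes.
    """
    send_ts = np.asarray(send_ts, dtype=float)
    recv_ts = np.asarray(recv_ts, dtype=float)
    if len(send_ts) == 0 or len(send_ts) != len(recv_ts):
        raise ValueError("need equal-length, non-empty paired timestamp arrays")
    return float(np.median(recv_ts - send_ts))


def resample(
    t: np.ndarray,
    x: np.ndarray,
    grid: np.ndarray,
    max_gap_s: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a grid with a gap-aware validity mask.

    A grid point is valid only if it falls within the source support and its
    bracketing source interval is no longer than ``max_gap_s`` (default: one
    median source sample interval) — source gaps are not bridged by the
    interpolation.  Grid points coinciding with a source sample are always
    valid.  Returns (values, valid_mask).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("source timestamps must be strictly increasing")
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    out = np.empty((len(grid), x.shape[1]))
    if len(t) == 0:
        out[:] = np.nan
        valid = np.zeros(len(grid), dtype=bool)
        return (out[:, 0] if squeeze else out), valid
    for k in range(x.shape[1]):
        out[:, k] = np.interp(grid, t, x[:, k])
    if max_gap_s is None:
        max_gap_s = float(np.median(np.diff(t))) if len(t) > 1 else np.inf
    eps = 1e-9
    in_support = (grid >= t[0] - eps) & (grid <= t[-1] + eps)
    idx = np.clip(np.searchsorted(t, grid), 1, max(len(t) - 1, 1))
    if len(t) > 1:
        gap = t[idx] - t[idx - 1]
        d_prev = np.abs(grid - t[idx - 1])
        d_next = np.abs(t[idx] - grid)
        at_sample = np.minimum(d_prev, d_next) <= eps
        valid = in_support & (at_sample | (gap <= max_gap_s + eps))
    else:
        valid = np.abs(grid - t[0]) <= eps
    return (out[:, 0] if squeeze else out), valid


def _valid_series(stream: HandStream) -> Tuple[np.ndarray, np.ndarray]:
    m = stream.valid
    return stream.t[m], stream.position[m]


def refine_offset(
    t_a: np.ndarray,
    x_a: np.ndarray,
    t_b: np.ndarray,
    x_b: np.ndarray,
    search_range_s: float = 0.5,
    grid_rate_hz: float = 40.0,
    max_gap_s: Optional[float] = None,
) -> SyncResult:
    """Residual lag of series b relative to a by z-scored cross-correlation.

    Both series are resampled to a common grid; each axis is z-scored over
    the jointly valid overlap (making the estimate invariant to constant
    position biases, e.g. an uncorrected frame offset); the per-axis
    normalized correlations are averaged and evaluated at every integer-lag
    shift within +/- ``search_range_s``.  A positive refined lag means b
    still arrives later than a.
    """
    t_a, x_a = np.asarray(t_a, float), np.asarray(x_a, float)
    t_b, x_b = np.asarray(t_b, float), np.asarray(x_b, float)
    lo = max(t_a[0], t_b[0]) if len(t_a) and len(t_b) else np.nan
    hi = min(t_a[-1], t_b[-1]) if len(t_a) and len(t_b) else np.nan
    if not np.isfinite(lo) or hi <= lo:
        raise ValueError("series have no temporal overlap")
    dt = 1.0 / grid_rate_hz
    grid = np.arange(lo, hi, dt)
    a, va = resample(t_a, x_a, grid, max_gap_s)
    b, vb = resample(t_b, x_b, grid, max_gap_s)
    if a.ndim == 1:
        a, b = a[:, None], b[:, None]

    max_lag = int(round(search_range_s * grid_rate_hz))
    best_lag, best_corr = 0, -np.inf
    n = len(grid)
    for lag in range(-max_lag, max_lag + 1):
        # correlate a[i] with b[i + lag]
        if lag >= 0:
            sa, sb = slice(0, n - lag), slice(lag, n)
        else:
            sa, sb = slice(-lag, n), slice(0, n + lag)
        m = va[sa] & vb[sb]
        if m.sum() < 10:
            continue
        corr = 0.0
        for k in range(a.shape[1]):
            aa = a[sa, k][m]
            bb = b[sb, k][m]
            sd_a, sd_b = aa.std(), bb.std()
            if sd_a < 1e-12 or sd_b < 1e-12:
                continue
            corr += float(np.mean((aa - aa.mean()) / sd_a * (bb - bb.mean()) / sd_b))
        corr /= a.shape[1]
        if corr > best_corr:
            best_lag, best_corr = lag, corr
    if not np.isfinite(best_corr):
        raise ValueError("no lag with sufficient valid overlap")
    return SyncResult(
        initial_offset_s=0.0,
        refined_offset_s=best_lag * dt,
        peak_correlation=best_corr,
        grid_rate_hz=grid_rate_hz,
        boundary_warning=abs(best_lag) == max_lag,
    )


def synchronize_recording(
    recording: SessionRecording,
    search_range_s: float = 0.5,
    grid_rate_hz: float = 40.0,
) -> Tuple[SessionRecording, SyncResult]:
    """Estimate and remove the external-stream clock offset.

    Initial estimate from the sender/receiver timestamp pairs of the
    external hand stream; refined against the headset hand stream by
    cross-correlation.  Returns a new recording whose external hand and
    body timestamps are shifted onto the headset clock (the input is left
    untouched), plus the sync result.
    """
    ext = recording.hands.get("external")
    hs = recording.hands.get("headset")
    if ext is None or hs is None:
        raise ValueError("recording needs both a headset and an external hand stream")
    if ext.t_send is not None:
        off0 = initial_offset(ext.t_send, ext.t)
    else:
        off0 = 0.0

    ta, xa = _valid_series(hs)
    tb, xb = _valid_series(ext)
    res = refine_offset(
        ta, xa, tb - off0, xb, search_range_s=search_range_s, grid_rate_hz=grid_rate_hz
    )
    total = off0 + res.refined_offset_s
    result = SyncResult(
        initial_offset_s=off0,
        refined_offset_s=total,
        peak_correlation=res.peak_correlation,
        grid_rate_hz=grid_rate_hz,
        boundary_warning=res.boundary_warning,
    )
    ext_shifted = HandStream(
        t=ext.t - total,
        position=ext.position.copy(),
        valid=ext.valid.copy(),
        source=ext.source,
        t_send=None if ext.t_send is None else ext.t_send.copy(),
    )
    body = recording.body
    if body is not None and len(body):
        body = BodyStream(
            t=body.t - total,
            joints={k: v.copy() for k, v in body.joints.items()},
            valid={k: v.copy() for k, v in body.valid.items()},
            t_send=None if body.t_send is None else body.t_send.copy(),
        )
    shifted = SessionRecording(
        schedule=recording.schedule,
        gaze=recording.gaze,
        hands={**recording.hands, "external": ext_shifted},
        head=recording.head,
        body=body,
        events=recording.events,
        metadata=recording.metadata,
    )
    return shifted, result
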