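"""Fusion of the two asynchronous hand-position streams.

A single constant-acceleration Kalman filter consumes measurements from the
headset (40 Hz, ~1 cm noise, bursty dropout) and the external tracker
(30 Hz, ~2 cm noise) in timestamp order.  The state is 12-dimensional:
position, velocity, acceleration, plus a 3D offset b that models the
residual rigid misalignment between the two coordinate systems; the
external measurement model observes p + b, so the filter estimates the
frame offset online.  Innovation gating rejects measurements outside the
90% chi-square confidence region of their Mahalanobis distance.  A
Rauch-Tung-Striebel backward pass yields zero-phase (lag-free) smoothed
trajectories, which are read out on a uniform grid; grid points are also
carried through the filter as prediction-only steps so that gaps in both
streams show up as inflated predictive uncertainty rather than silent
interpolation.

Process noise follows the discrete Wiener-process acceleration model driven
by the expected hand-acceleration SD (3 m/s^2); the offset state performs a
slow random walk (1e-4 m/sqrt(s)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .session_model import HandStream

try:  # numba accelerates the per-measurement loop; plain Python works too
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=True)(f)

except ImportError:  # pragma: no cover - numba is an optional speed extra

    def _jit(f):
        return f


__all__ = [
    "KalmanParams",
    "FusionState",
    "FusedTrajectory",
    "gate_threshold",
    "predict",
    "update",
    "rts_smooth",
    "fuse_streams",
]

NSTATE = 12
SRC_HEADSET = 0
SRC_EXTERNAL = 1
SRC_NONE = -1


@dataclass(frozen=True)
class KalmanParams:
    """Filter parameters (defaults match the reference acquisition tuning)."""

    sigma_accel: float = 3.0            # m/s^2, expected SD of hand acceleration
    sigma_offset_walk: float = 1e-4     # m/sqrt(s), offset random-walk SD
    r_external: float = 0.02            # m, external measurement noise SD
    r_headset: float = 0.01             # m, headset measurement noise SD
    gate_confidence: float = 0.90       # chi-square confidence for gating
    availability_sd_cap: float = 0.05   # m, predictive SD above which a frame
                                        # counts as unavailable

    def validate(self) -> None:
        for name in ("sigma_accel", "sigma_offset_walk", "r_external", "r_headset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.gate_confidence < 1.0:
            raise ValueError("gate_confidence must be in (0, 1)")


@dataclass
class FusionState:
    """Filter state at time t: x = [p(3), v(3), a(3), b(3)], covariance P."""

    t: float
    x: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).reshape(NSTATE)
        self.P = np.asarray(self.P, dtype=float).reshape(NSTATE, NSTATE)

    @property
    def position(self) -> np.ndarray:
        return self.x[0:3]

    @property
    def offset(self) -> np.ndarray:
        return self.x[9:12]

    @classmethod
    def initial(cls, t: float, position: Sequence[float]) -> "FusionState":
        x = np.zeros(NSTATE)
        x[0:3] = position
        P = np.diag([1.0] * 3 + [10.0] * 3 + [100.0] * 3 + [0.01] * 3)
        return cls(t=t, x=x, P=P)


@dataclass
class FusedTrajectory:
    grid: np.ndarray                 # uniform output times
    position: np.ndarray             # (n, 3) smoothed positions
    velocity: np.ndarray             # (n, 3) smoothed velocities
    position_sd: np.ndarray          # (n,) predictive position SD (forward pass)
    valid: np.ndarray                # (n,) predictive SD <= availability cap
    availability: float
    offset_estimate: np.ndarray      # final smoothed inter-source offset b
    measurement_t: np.ndarray
    measurement_source: np.ndarray   # 0 headset, 1 external
    accepted: np.ndarray             # per-measurement gate decision

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)

    def position_at(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((len(t), 3))
        for k in range(3):
            out[:, k] = np.interp(t, self.grid, self.position[:, k])
        return out


def gate_threshold(confidence: float, dof: int) -> float:
    """Chi-square inverse CDF: squared-Mahalanobis gate for a confidence."""
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if dof < 1:
        raise ValueError(f"dof must be >= 1, got {dof}")
    return float(stats.chi2.ppf(confidence, dof))


# ---------------------------------------------------------------------------
# numeric kernels (jitted when numba is present)


@_jit
def _make_F(dt: float) -> np.ndarray:
    F = np.eye(NSTATE)
    for k in range(3):
        F[k, 3 + k] = dt
        F[k, 6 + k] = 0.5 * dt * dt
        F[3 + k, 6 + k] = dt
    return F


@_jit
def _make_Q(dt: float, sigma_accel: float, sigma_offset_walk: float) -> np.ndarray:
    Q = np.zeros((NSTATE, NSTATE))
    sa2 = sigma_accel * sigma_accel
    g0 = 0.5 * dt * dt
    g1 = dt
    g2 = 1.0
    g = (g0, g1, g2)
    for i in range(3):
        for j in range(3):
            v = sa2 * g[i] * g[j]
            for k in range(3):
                Q[3 * i + k, 3 * j + k] = v
    sb2 = sigma_offset_walk * sigma_offset_walk * dt
    for k in range(3):
        Q[9 + k, 9 + k] = sb2
    return Q


@_jit
def _predict_kernel(
    x: np.ndarray, P: np.ndarray, dt: float, sigma_accel: float, sigma_offset_walk: float
):
    F = _make_F(dt)
    Q = _make_Q(dt, sigma_accel, sigma_offset_walk)
    x2 = F @ x
    P2 = F @ P @ F.T + Q
    P2 = 0.5 * (P2 + P2.T)
    return x2, P2


@_jit
def _make_H(src: int) -> np.ndarray:
    H = np.zeros((3, NSTATE))
    for k in range(3):
        H[k, k] = 1.0
        if src == 1:
            H[k, 9 + k] = 1.0
    return H


@_jit
def _update_kernel(
    x: np.ndarray,
    P: np.ndarray,
    z: np.ndarray,
    src: int,
    r_headset: float,
    r_external: float,
    gate: float,
):
    H = _make_H(src)
    r = r_external if src == 1 else r_headset
    R = (r * r) * np.eye(3)
    nu = z - H @ x
    S = H @ P @ H.T + R
    Sinv = np.linalg.inv(S)
    d2 = float(nu @ (Sinv @ nu))
    if d2 > gate:
        return x, P, False, d2
    K = P @ H.T @ Sinv
    x2 = x + K @ nu
    A = np.eye(NSTATE) - K @ H
    P2 = A @ P @ A.T + K @ R @ K.T
    P2 = 0.5 * (P2 + P2.T)
    return x2, P2, True, d2


@_jit
def _forward_pass(
    ts: np.ndarray,
    zs: np.ndarray,
    srcs: np.ndarray,
    x0: np.ndarray,
    P0: np.ndarray,
    sigma_accel: float,
    sigma_offset_walk: float,
    r_headset: float,
    r_external: float,
    gate: float,
):
    m = len(ts)
    xf = np.empty((m, NSTATE))
    Pf = np.empty((m, NSTATE, NSTATE))
    xp = np.empty((m, NSTATE))
    Pp = np.empty((m, NSTATE, NSTATE))
    accepted = np.zeros(m, dtype=np.int8)
    x = x0.copy()
    P = P0.copy()
    t_prev = ts[0]
    for i in range(m):
        dt = ts[i] - t_prev
        if dt > 0.0:
            x, P = _predict_kernel(x, P, dt, sigma_accel, sigma_offset_walk)
        xp[i] = x
        Pp[i] = P
        if srcs[i] >= 0:
            x, P, ok, _ = _update_kernel(
                x, P, zs[i], srcs[i], r_headset, r_external, gate
            )
            accepted[i] = 1 if ok else 0
        xf[i] = x
        Pf[i] = P
        t_prev = ts[i]
    return xf, Pf, xp, Pp, accepted


@_jit
def _rts_pass(
    ts: np.ndarray,
    xf: np.ndarray,
    Pf: np.ndarray,
    xp: np.ndarray,
    Pp: np.ndarray,
):
    m = len(ts)
    xs = xf.copy()
    Ps = Pf.copy()
    for i in range(m - 2, -1, -1):
        dt = ts[i + 1] - ts[i]
        F = _make_F(dt)
        # C = Pf F' Pp^{-1}; solve on the symmetric prior is better
        # conditioned than forming the inverse
        C = np.linalg.solve(Pp[i + 1], (Pf[i] @ F.T).T).T
        xs[i] = xf[i] + C @ (xs[i + 1] - xp[i + 1])
        Pi = Pf[i] + C @ (Ps[i + 1] - Pp[i + 1]) @ C.T
        Ps[i] = 0.5 * (Pi + Pi.T)
    return xs, Ps


# ---------------------------------------------------------------------------
# public single-step operations


def predict(state: FusionState, dt: float, params: KalmanParams) -> FusionState:
    """Propagate the state by dt under the constant-acceleration model."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    params.validate()
    if dt == 0:
        return FusionState(t=state.t, x=state.x.copy(), P=state.P.copy())
    x2, P2 = _predict_kernel(
        state.x, state.P, dt, params.sigma_accel, params.sigma_offset_walk
    )
    return FusionState(t=state.t + dt, x=x2, P=P2)


def update(
    state: FusionState, z: Sequence[float], source: str, params: KalmanParams
) -> Tuple[FusionState, bool]:
    """Measurement update with innovation gating (Joseph-form covariance).

    Rejected measurements leave the state unchanged and return accepted =
    False.
    """
    z = np.asarray(z, dtype=float).reshape(3)
    if not np.all(np.isfinite(z)):
        raise ValueError("measurement must be finite")
    if source not in ("headset", "external"):
        raise ValueError(f"unknown source {source!r}")
    params.validate()
    gate = gate_threshold(params.gate_confidence, 3)
    src = SRC_EXTERNAL if source == "external" else SRC_HEADSET
    x2, P2, ok, _ = _update_kernel(
        state.x, state.P, z, src, params.r_headset, params.r_external, gate
    )
    return FusionState(t=state.t, x=x2, P=P2), bool(ok)


def rts_smooth(
    ts: np.ndarray,
    filtered_x: np.ndarray,
    filtered_P: np.ndarray,
    predicted_x: np.ndarray,
    predicted_P: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rauch-Tung-Striebel backward smoothing over a stored forward pass.

    Inputs are the per-step posterior (filtered) and prior (predicted)
    moments; returns smoothed means and covariances.  Smoothed covariances
    never exceed the filtered ones (trace-wise).
    """
    ts = np.asarray(ts, dtype=float)
    arrs = [np.asarray(a, dtype=float) for a in (filtered_x, filtered_P, predicted_x, predicted_P)]
    if not all(len(a) == len(ts) for a in arrs):
        raise ValueError("all histories must have the same length")
    if len(ts) == 0:
        raise ValueError("empty history")
    return _rts_pass(ts, arrs[0], arrs[1], arrs[2], arrs[3])


# ---------------------------------------------------------------------------
# end-to-end fusion


def fuse_streams(
    headset: Optional[HandStream],
    external: Optional[HandStream],
    params: KalmanParams = KalmanParams(),
    grid_rate_hz: float = 40.0,
) -> FusedTrajectory:
    """Fuse the time-aligned hand streams into a smoothed grid trajectory.

    Measurements from both sources are processed in timestamp order
    (headset first on ties — it is the lower-noise source); the forward
    filtered sequence is RTS-smoothed, and states at the uniform output grid
    (carried as prediction-only steps) are read out.  Availability is the
    fraction of grid points whose forward predictive position SD stays below
    ``params.availability_sd_cap``.
    """
    params.validate()
    streams = []
    if headset is not None and len(headset):
        m = headset.valid
        streams.append((headset.t[m], headset.position[m], SRC_HEADSET))
    if external is not None and len(external):
        m = external.valid
        streams.append((external.t[m], external.position[m], SRC_EXTERNAL))
    if not streams or all(len(s[0]) == 0 for s in streams):
        raise ValueError("no valid measurements in either stream")

    t_meas = np.concatenate([s[0] for s in streams])
    z_meas = np.concatenate([s[1] for s in streams])
    src_meas = np.concatenate(
        [np.full(len(s[0]), s[2], dtype=np.int64) for s in streams]
    )
    order = np.lexsort((src_meas, t_meas))  # time, then headset before external
    t_meas, z_meas, src_meas = t_meas[order], z_meas[order], src_meas[order]

    t0, t1 = t_meas[0], t_meas[-1]
    grid = t0 + np.arange(int(math.floor((t1 - t0) * grid_rate_hz)) + 1) / grid_rate_hz

    ts = np.concatenate([t_meas, grid])
    zs = np.concatenate([z_meas, np.full((len(grid), 3), np.nan)])
    srcs = np.concatenate([src_meas, np.full(len(grid), SRC_NONE, dtype=np.int64)])
    kinds = np.concatenate(
        [np.zeros(len(t_meas), dtype=np.int64), np.ones(len(grid), dtype=np.int64)]
    )
    # stable merge: at equal times process measurements before grid readouts
    order = np.lexsort((srcs, kinds, ts))
    ts, zs, srcs, kinds = ts[order], zs[order], srcs[order], kinds[order]

    init = FusionState.initial(t=float(t_meas[0]), position=z_meas[0])
    gate = gate_threshold(params.gate_confidence, 3)
    xf, Pf, xp, Pp, accepted = _forward_pass(
        ts,
        zs,
        srcs,
        init.x,
        init.P,
        params.sigma_accel,
        params.sigma_offset_walk,
        params.r_headset,
        params.r_external,
        gate,
    )
    xs, Ps = _rts_pass(ts, xf, Pf, xp, Pp)

    grid_idx = np.nonzero(kinds == 1)[0]
    pos = xs[grid_idx, 0:3]
    vel = xs[grid_idx, 3:6]
    pred_var = np.stack([np.diag(Pp[i])[0:3] for i in grid_idx])
    pred_sd = np.sqrt(pred_var.max(axis=1))
    valid = pred_sd <= params.availability_sd_cap
    meas_idx = np.nonzero(kinds == 0)[0]

    return FusedTrajectory(
        grid=ts[grid_idx],
        position=pos,
        velocity=vel,
        position_sd=pred_sd,
        valid=valid,
        availability=float(valid.mean()) if len(valid) else 0.0,
        offset_estimate=xs[grid_idx[-1] if len(grid_idx) else -1, 9:12].copy(),
        measurement_t=ts[meas_idx],
        measurement_source=srcs[meas_idx],
        accepted=accepted[meas_idx].astype(bool),
    )
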