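"""Trajectory accuracy benchmarking against a dense reference.

Protocol: (1) temporal alignment by maximizing cross-correlation of hand
speed and acceleration magnitudes (invariant to any constant spatial bias);
(2) spatial alignment initialized by the Kabsch least-squares rigid fit,
refined with an ICP-like iteration over nearest-in-time correspondences;
(3) per-sample Euclidean errors on valid frames in the evaluation window
(by default the dynamic reaching phases), reported as RMSE, median absolute
error, 95th-percentile absolute error, and availability (valid frames /
total frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .session_model import RigidTransform
from .temporal_sync import resample

__all__ = [
    "ErrorReport",
    "kabsch",
    "temporal_align_kinematic",
    "icp_refine",
    "trajectory_errors",
    "align_and_evaluate",
]


@dataclass
class ErrorReport:
    rmse_m: float
    median_ae_m: float
    p95_ae_m: float
    availability: float
    n_samples: int
    lag_s: float = 0.0
    transform: Optional[RigidTransform] = None

    def as_cm(self) -> dict:
        """Report in centimeters (availability stays a fraction)."""
        return {
            "rmse_cm": self.rmse_m * 100.0,
            "median_ae_cm": self.median_ae_m * 100.0,
            "p95_ae_cm": self.p95_ae_m * 100.0,
            "availability": self.availability,
            "n_samples": self.n_samples,
        }


def kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping point set P onto Q.

    Minimizes sum ||R p_i + t - q_i||^2 over proper rotations (det +1).
    Requires >= 3 non-collinear pairs.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if len(P) != len(Q) or len(P) < 3:
        raise ValueError("need >= 3 paired points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(R, t)


def _kinematic_magnitudes(t: np.ndarray, p: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    v = np.gradient(p, t, axis=0)
    a = np.gradient(v, t, axis=0)
    return np.linalg.norm(v, axis=1), np.linalg.norm(a, axis=1)


def temporal_align_kinematic(
    ref_t: np.ndarray,
    ref_p: np.ndarray,
    est_t: np.ndarray,
    est_p: np.ndarray,
    range_s: float = 0.5,
    grid_rate_hz: float = 40.0,
) -> float:
    """Lag of est relative to ref maximizing speed + acceleration
    cross-correlation.  Positive lag: est runs late; subtract it from est
    timestamps to align.  Kinematic magnitudes are invariant to constant
    position bias, so no spatial alignment is needed first."""
    ref_t, est_t = np.asarray(ref_t, float), np.asarray(est_t, float)
    lo, hi = max(ref_t[0], est_t[0]), min(ref_t[-1], est_t[-1])
    if hi <= lo:
        raise ValueError("trajectories do not overlap in time")
    dt = 1.0 / grid_rate_hz
    grid = np.arange(lo, hi, dt)
    r, vr = resample(ref_t, np.asarray(ref_p, float), grid)
    e, ve = resample(est_t, np.asarray(est_p, float), grid)
    sr, ar = _kinematic_magnitudes(grid, r)
    se, ae = _kinematic_magnitudes(grid, e)

    max_lag = int(round(range_s * grid_rate_hz))
    n = len(grid)
    best_lag, best_corr = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            s_r, s_e = slice(0, n - lag), slice(lag, n)
        else:
            s_r, s_e = slice(-lag, n), slice(0, n + lag)
        m = vr[s_r] & ve[s_e]
        if m.sum() < 10:
            continue
        corr = 0.0
        for x, y in ((sr[s_r][m], se[s_e][m]), (ar[s_r][m], ae[s_e][m])):
            sx, sy = x.std(), y.std()
            if sx < 1e-12 or sy < 1e-12:
                continue
            corr += float(np.mean((x - x.mean()) / sx * (y - y.mean()) / sy))
        if corr > best_corr:
            best_lag, best_corr = lag, corr
    return best_lag * dt


def icp_refine(
    est_points: np.ndarray,
    ref_points: np.ndarray,
    init: RigidTransform,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> RigidTransform:
    """Refine a rigid alignment over nearest-in-time correspondences.

    The point sets are paired by index (trajectories share a time grid), so
    each iteration re-fits Kabsch on the current residuals; the mean
    residual is monotone non-increasing and the loop stops when its change
    drops below ``tol``.
    """
    est = np.asarray(est_points, dtype=float).reshape(-1, 3)
    ref = np.asarray(ref_points, dtype=float).reshape(-1, 3)
    if len(est) == 0 or len(ref) == 0:
        raise ValueError("empty point set")
    if len(est) != len(ref):
        raise ValueError("point sets must be paired (same length)")
    transform = init
    prev = float(np.mean(np.linalg.norm(transform.apply(est) - ref, axis=1)))
    for _ in range(max_iter):
        moved = transform.apply(est)
        step = kabsch(moved, ref)
        candidate = step.compose(transform)
        resid = float(np.mean(np.linalg.norm(candidate.apply(est) - ref, axis=1)))
        if resid > prev + 1e-15:
            break
        transform = candidate
        if prev - resid < tol:
            prev = resid
            break
        prev = resid
    return transform


def trajectory_errors(
    est_t: np.ndarray,
    est_p: np.ndarray,
    est_valid: Optional[np.ndarray],
    ref_t: np.ndarray,
    ref_p: np.ndarray,
    windows: Optional[Sequence[Tuple[float, float]]] = None,
) -> ErrorReport:
    """Per-sample Euclidean error statistics of an aligned trajectory.

    The dense reference is interpolated at the estimate's timestamps.
    ``windows`` restricts evaluation (e.g. to reaching phases);
    availability = valid frames / total frames within the windows.
    """
    est_t = np.asarray(est_t, dtype=float)
    est_p = np.asarray(est_p, dtype=float).reshape(-1, 3)
    if est_valid is None:
        est_valid = np.ones(len(est_t), dtype=bool)
    est_valid = np.asarray(est_valid, dtype=bool)
    ref_t = np.asarray(ref_t, dtype=float)
    ref_p = np.asarray(ref_p, dtype=float).reshape(-1, 3)

    in_window = np.zeros(len(est_t), dtype=bool)
    if windows is None:
        in_window[:] = True
    else:
        for t0, t1 in windows:
            in_window |= (est_t >= t0) & (est_t <= t1)
    in_support = (est_t >= ref_t[0]) & (est_t <= ref_t[-1])
    in_window &= in_support

    total = int(in_window.sum())
    use = in_window & est_valid & np.all(np.isfinite(est_p), axis=1)
    if not use.any():
        raise ValueError("no valid frames in the evaluation window")
    ref_i = np.stack(
        [np.interp(est_t[use], ref_t, ref_p[:, k]) for k in range(3)], axis=1
    )
    err = np.linalg.norm(est_p[use] - ref_i, axis=1)
    return ErrorReport(
        rmse_m=float(np.sqrt(np.mean(err**2))),
        median_ae_m=float(np.median(err)),
        p95_ae_m=float(np.percentile(err, 95)),
        availability=float(use.sum()) / total if total else 0.0,
        n_samples=int(use.sum()),
    )


def align_and_evaluate(
    est_t: np.ndarray,
    est_p: np.ndarray,
    est_valid: Optional[np.ndarray],
    ref_t: np.ndarray,
    ref_p: np.ndarray,
    windows: Optional[Sequence[Tuple[float, float]]] = None,
    range_s: float = 0.5,
    refine_spatial: bool = True,
) -> ErrorReport:
    """Full protocol: kinematic lag, Kabsch init, ICP refinement, errors.

    With ``refine_spatial`` off, only the temporal alignment is applied
    (for per-source evaluations where residual frame offsets are part of
    the error being measured).
    """
    est_t = np.asarray(est_t, dtype=float)
    est_p = np.asarray(est_p, dtype=float).reshape(-1, 3)
    if est_valid is None:
        est_valid = np.ones(len(est_t), dtype=bool)
    finite = np.all(np.isfinite(est_p), axis=1)
    v = np.asarray(est_valid, dtype=bool) & finite

    lag = temporal_align_kinematic(ref_t, ref_p, est_t[v], est_p[v], range_s=range_s)
    t_aligned = est_t - lag

    transform = RigidTransform.identity()
    if refine_spatial:
        m = v & (t_aligned >= ref_t[0]) & (t_aligned <= ref_t[-1])
        ref_i = np.stack(
            [np.interp(t_aligned[m], ref_t, ref_p[:, k]) for k in range(3)], axis=1
        )
        init = kabsch(est_p[m], ref_i)
        transform = icp_refine(est_p[m], ref_i, init)

    est_aligned = transform.apply(np.nan_to_num(est_p, nan=0.0))
    est_aligned[~finite] = np.nan
    report = trajectory_errors(t_aligned, est_aligned, v, ref_t, ref_p, windows)
    report.lag_s = lag
    report.transform = transform
    return report
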