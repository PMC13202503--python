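"""Independent textbook Kalman filter + RTS smoother (test oracle).

Plain-vanilla update (no Joseph form) and the standard RTS recursion with
explicit inverses; shares nothing with the package kernels except the
state-transition/process-noise definitions under test.
"""

import numpy as np

from eyehand.hand_fusion import FusionState, KalmanParams, predict, rts_smooth, update

def textbook_kf_rts(ts, zs, x0, P0, params, r):
    """Independent plain-vanilla KF + RTS (single source, no gating)."""
    from eyehand.hand_fusion import _make_F, _make_Q

    n = len(ts)
    H = np.zeros((3, 12))
    H[:, :3] = np.eye(3)
    R = r**2 * np.eye(3)
    xf, Pf, xp, Pp, Fs = [], [], [], [], []
    x, P = x0.copy(), P0.copy()
    t_prev = ts[0]
    for i in range(n):
        dt = ts[i] - t_prev
        F = _make_F(dt)
        if dt > 0:
            Q = _make_Q(dt, params.sigma_accel, params.sigma_offset_walk)
            x = F @ x
            P = F @ P @ F.T + Q
            P = 0.5 * (P + P.T)
        xp.append(x.copy())
        Pp.append(P.copy())
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (zs[i] - H @ x)
        P = (np.eye(12) - K @ H) @ P
        P = 0.5 * (P + P.T)
        xf.append(x.copy())
        Pf.append(P.copy())
        t_prev = ts[i]
    xs = [None] * n
    Ps = [None] * n
    xs[-1], Ps[-1] = xf[-1], Pf[-1]
    for i in range(n - 2, -1, -1):
        F = _make_F(ts[i + 1] - ts[i])
        C = Pf[i] @ F.T @ np.linalg.inv(Pp[i + 1])
        xs[i] = xf[i] + C @ (xs[i + 1] - xp[i + 1])
        Ps[i] = Pf[i] + C @ (Ps[i + 1] - Pp[i + 1]) @ C.T
    return np.array(xs), np.array(Ps)


NO_GATE = KalmanParams(gate_confidence=1.0 - 1e-12)


def run_package_filter(ts, zs, params=NO_GATE):
    """Forward pass via the public step API (gating disabled so the filter
    reduces to a plain single-source Kalman smoother), then the package
    smoother."""
    state = FusionState.initial(ts[0], zs[0])
    xf, Pf, xp, Pp = [], [], [], []
    for i in range(len(ts)):
        state = predict(state, ts[i] - (ts[i - 1] if i else ts[0]), params)
        xp.append(state.x.copy())
        Pp.append(state.P.copy())
        state, accepted = update(state, zs[i], "headset", params)
        assert accepted
        xf.append(state.x.copy())
        Pf.append(state.P.copy())
    xs, Ps = rts_smooth(ts, np.array(xf), np.array(Pf), np.array(xp), np.array(Pp))
    return np.array(xf), np.array(Pf), xs, Ps


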