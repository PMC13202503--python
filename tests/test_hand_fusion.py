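"""Kalman fusion: prediction, gating, smoothing, and stream-level fusion.

The independent textbook oracle (plain Kalman update + standard RTS
recursion, no Joseph form, no gating) lives in ``kalman_textbook`` and
pins down the filter numerics.
"""

import numpy as np
import pytest

from kalman_textbook import NO_GATE, run_package_filter, textbook_kf_rts
from eyehand.hand_fusion import (
    FusionState,
    KalmanParams,
    fuse_streams,
    gate_threshold,
    predict,
    rts_smooth,
    update,
)
from eyehand.session_model import HandStream

PARAMS = KalmanParams()


def _state(t=0.0, p=(0.0, 0.0, 0.0)):
    return FusionState.initial(t, np.asarray(p, dtype=float))


class TestPredict:
    def test_zero_dt_is_identity(self):
        s = _state()
        out = predict(s, 0.0, PARAMS)
        np.testing.assert_array_equal(out.x, s.x)
        np.testing.assert_array_equal(out.P, s.P)

    def test_constant_velocity_kinematics(self):
        s = _state()
        s.x[3:6] = [1.0, 0.0, 0.0]
        out = predict(s, 0.1, PARAMS)
        np.testing.assert_allclose(out.position, [0.1, 0.0, 0.0], atol=1e-12)

    def test_uncertainty_grows_strictly(self):
        s = _state()
        out = predict(s, 0.05, PARAMS)
        assert np.trace(out.P) > np.trace(s.P)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            predict(_state(), -0.01, PARAMS)


class TestGateThreshold:
    def test_chi_square_quantiles(self):
        assert gate_threshold(0.90, 3) == pytest.approx(6.2514, abs=1e-3)
        assert gate_threshold(0.90, 1) == pytest.approx(2.7055, abs=1e-3)

    def test_monotone_in_confidence(self):
        grid = [0.5, 0.8, 0.9, 0.95, 0.99]
        vals = [gate_threshold(c, 3) for c in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("conf", [0.0, 1.0, -0.1])
    def test_invalid_confidence_rejected(self, conf):
        with pytest.raises(ValueError):
            gate_threshold(conf, 3)


class TestUpdate:
    def test_zero_innovation_keeps_mean(self):
        s = _state(p=(0.1, 0.2, 0.3))
        out, accepted = update(s, [0.1, 0.2, 0.3], "headset", PARAMS)
        assert accepted
        np.testing.assert_allclose(out.x, s.x, atol=1e-12)

    def test_distant_measurement_gated_out(self):
        s = _state(p=(0.0, 0.0, 0.0))
        s.P = np.diag([1e-4] * 3 + [10.0] * 3 + [100.0] * 3 + [0.01] * 3)
        out, accepted = update(s, [1.0, 0.0, 0.0], "headset", PARAMS)
        assert not accepted
        np.testing.assert_array_equal(out.x, s.x)

    def test_external_offset_state_converges(self):
        """With the headset observing p and the external source observing
        p + b, a constant 2 cm frame offset is absorbed by the offset state
        within 30 simulated seconds."""
        rng = np.random.default_rng(0)
        offset = np.array([0.02, 0.0, 0.0])
        s = _state()
        for _ in range(30 * 30):
            s = predict(s, 1 / 60.0, PARAMS)
            s, _ = update(s, rng.normal(0.0, PARAMS.r_headset, 3), "headset", PARAMS)
            s = predict(s, 1 / 60.0, PARAMS)
            z = offset + rng.normal(0.0, PARAMS.r_external, 3)
            s, _ = update(s, z, "external", PARAMS)
        assert np.linalg.norm(s.offset - offset) < 0.005

    def test_covariance_stays_symmetric_psd(self):
        rng = np.random.default_rng(1)
        s = _state()
        for i in range(200):
            s = predict(s, 0.025, PARAMS)
            src = "headset" if i % 2 else "external"
            s, _ = update(s, rng.normal(0, 0.02, 3), src, PARAMS)
            np.testing.assert_allclose(s.P, s.P.T, atol=1e-10)
            assert np.linalg.eigvalsh(s.P).min() >= -1e-9


class TestRtsSmooth:
    @pytest.fixture(scope="class")
    @staticmethod
    def fixture_100():
        rng = np.random.default_rng(7)
        ts = np.arange(100) * 0.025
        truth = np.stack(
            [0.2 * np.sin(2 * np.pi * 0.8 * ts), 0.1 * ts, np.zeros_like(ts)], axis=1
        )
        zs = truth + rng.normal(0, PARAMS.r_headset, truth.shape)
        return ts, zs, truth

    def test_matches_textbook_implementation(self, fixture_100):
        ts, zs, _ = fixture_100
        xf, Pf, xs, Ps = run_package_filter(ts, zs)
        x0 = FusionState.initial(ts[0], zs[0])
        xs_ref, Ps_ref = textbook_kf_rts(ts, zs, x0.x, x0.P, NO_GATE, NO_GATE.r_headset)
        np.testing.assert_allclose(xs, xs_ref, atol=1e-8)
        np.testing.assert_allclose(Ps, Ps_ref, atol=1e-8)

    def test_smoothing_never_increases_covariance_trace(self, fixture_100):
        ts, zs, _ = fixture_100
        _, Pf, _, Ps = run_package_filter(ts, zs)
        assert all(
            np.trace(Ps[i]) <= np.trace(Pf[i]) + 1e-10 for i in range(len(ts))
        )

    def test_single_step_history_is_unchanged(self):
        ts = np.array([0.0])
        xf = np.zeros((1, 12))
        Pf = np.eye(12)[None]
        xs, Ps = rts_smooth(ts, xf, Pf, xf.copy(), Pf.copy())
        np.testing.assert_array_equal(xs, xf)
        np.testing.assert_array_equal(Ps, Pf)

    def test_zero_phase_on_sinusoid(self):
        """Smoothed estimate of a noisy sinusoid peaks its cross-correlation
        with the truth at lag zero (no filter delay)."""
        rng = np.random.default_rng(11)
        ts = np.arange(600) * 0.025
        truth = np.stack(
            [0.15 * np.sin(2 * np.pi * 1.0 * ts), np.zeros_like(ts), np.zeros_like(ts)],
            axis=1,
        )
        zs = truth + rng.normal(0, 0.01, truth.shape)
        _, _, xs, _ = run_package_filter(ts, zs)
        est = xs[:, 0] - xs[:, 0].mean()
        ref = truth[:, 0] - truth[:, 0].mean()
        lags = range(-8, 9)
        corr = [np.mean(est[max(0, -l): len(est) - max(0, l)]
                        * ref[max(0, l): len(ref) - max(0, -l)]) for l in lags]
        assert list(lags)[int(np.argmax(corr))] == 0


class TestFuseStreams:
    def test_noise_free_coincident_streams_reproduced(self):
        """Noise-free, offset-free coincident streams are reproduced up to
        the initialization transient (wrong velocity prior for the first few
        samples) and the micrometer-scale position/offset ambiguity of the
        augmented state."""
        ts = np.arange(200) * 0.025
        truth = np.stack(
            [0.01 + 0.05 * ts + 0.02 * ts**2, 0.03 * ts, np.zeros_like(ts)], axis=1
        )
        mk = lambda src: HandStream(ts, truth.copy(), np.ones(len(ts), bool), src)
        fused = fuse_streams(mk("headset"), mk("external"), PARAMS, grid_rate_hz=40.0)
        truth_at = np.stack(
            [np.interp(fused.grid, ts, truth[:, k]) for k in range(3)], axis=1
        )
        err = np.abs(fused.position - truth_at).max(axis=1)
        assert err.max() < 1e-5
        assert err[40:].max() < 2e-6
        assert fused.availability == 1.0

    def test_empty_streams_rejected(self):
        with pytest.raises(ValueError):
            fuse_streams(HandStream.empty("headset"), HandStream.empty("external"), PARAMS)

    def test_gap_bridged_by_external_source(self):
        """With the headset lost for 0.5 s mid-reach, the external source and
        smoothing keep the fused trajectory within 3 cm of truth."""
        rng = np.random.default_rng(3)
        t_h = np.arange(0, 4, 0.025)
        t_e = np.arange(0, 4, 1 / 30.0)
        truth = lambda t: np.stack(
            [0.3 * np.sin(1.5 * t), 0.2 * np.cos(1.1 * t), 0.05 * np.sin(2.3 * t)], axis=1
        )
        z_h = truth(t_h) + rng.normal(0, 0.01, (len(t_h), 3))
        z_e = truth(t_e) + rng.normal(0, 0.02, (len(t_e), 3))
        valid_h = ~((t_h >= 2.0) & (t_h < 2.5))
        z_h[~valid_h] = np.nan
        fused = fuse_streams(
            HandStream(t_h, z_h, valid_h, "headset"),
            HandStream(t_e, z_e, np.ones(len(t_e), bool), "external"),
            PARAMS,
        )
        gap = (fused.grid >= 2.0) & (fused.grid < 2.5)
        err = np.linalg.norm(fused.position[gap] - truth(fused.grid[gap]), axis=1)
        assert err.max() < 0.03

    def test_acceptance_log_covers_all_measurements(self, default_processed):
        fused = default_processed.fused
        rec = default_processed.recording
        n_meas = int(rec.hands["headset"].valid.sum() + rec.hands["external"].valid.sum())
        assert len(fused.accepted) == n_meas
        # the 90% gate rejects ~10% of genuine measurements by construction
        assert 0.85 < fused.accepted.mean() < 0.97
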