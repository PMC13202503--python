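"""Statistics, IQR flags, lateral pairing, and motion-onset scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from eyehand.gaze_pipeline import FixationInterval, FixationSeries
from eyehand.hand_fusion import FusedTrajectory
from eyehand.metrics import (
    detect_motion_onset,
    gaze_anchoring_offset,
    iqr_flags,
    pairwise_lateral,
    pearson_r,
    summarize_group,
    wilcoxon_signed_rank,
)
from eyehand.behavior_sim import minimum_jerk


class TestIqrFlags:
    def test_single_outlier_flagged(self):
        flags = iqr_flags(np.array([1.0, 2, 3, 4, 100]))
        np.testing.assert_array_equal(flags, [False, False, False, False, True])

    def test_constant_values_unflagged(self):
        assert not iqr_flags(np.full(10, 3.3)).any()

    def test_symmetric_range_unflagged(self):
        assert not iqr_flags(np.arange(1.0, 11.0)).any()

    def test_too_few_values_warns_and_skips(self):
        with pytest.warns(UserWarning):
            flags = iqr_flags(np.array([1.0, 2.0, np.nan, np.nan]))
        assert not flags.any()

    def test_matches_brute_force_fences_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.normal(size=rng.integers(4, 40))
            flags = iqr_flags(v)
            # independent fence computation: interpolated quartiles by hand
            s = np.sort(v)
            def quart(q):
                pos = q * (len(s) - 1)
                lo = int(np.floor(pos))
                hi = min(lo + 1, len(s) - 1)
                return s[lo] + (pos - lo) * (s[hi] - s[lo])
            q1, q3 = quart(0.25), quart(0.75)
            lo_f, hi_f = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
            np.testing.assert_array_equal(flags, (v < lo_f) | (v > hi_f))


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        # brute force over all 2^5 sign assignments
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        w, p = wilcoxon_signed_rank(values)
        assert w == 15.0
        count_ge = sum(
            1
            for signs in itertools.product([1, -1], repeat=5)
            if sum(r for r, s in zip([1, 2, 3, 4, 5], signs) if s > 0) >= 15
        )
        count_le = sum(
            1
            for signs in itertools.product([1, -1], repeat=5)
            if sum(r for r, s in zip([1, 2, 3, 4, 5], signs) if s > 0) <= 15
        )
        expected = min(1.0, 2 * min(count_ge, count_le) / 2**5)
        assert p == pytest.approx(expected)
        assert p == pytest.approx(0.0625)

    def test_perfectly_symmetric_sample(self):
        _, p = wilcoxon_signed_rank([-1.0, 1.0, -2.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_zeros_discarded(self):
        w1, p1 = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 0.0])
        w2, p2 = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert (w1, p1) == (w2, p2)

    def test_all_zeros_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_matches_scipy_exact_on_random_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(6, 26))
            v = rng.normal(0.2, 1.0, n)
            _, p = wilcoxon_signed_rank(v)
            ref = sstats.wilcoxon(v, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approximation_beyond_exact_range(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0.3, 1.0, 60)
        _, p = wilcoxon_signed_rank(v)
        ref = sstats.wilcoxon(
            v, alternative="two-sided", method="approx", correction=False
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-6)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        x = np.arange(8.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, p = pearson_r(x, y)
        # hand computation: r = cov / (sx sy) on the worked fixture
        assert r == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * np.sqrt(3 / (1 - 0.64))
        assert p == pytest.approx(2 * sstats.t.sf(t, 3), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSummarizeGroup:
    def test_three_values(self):
        s = summarize_group([1.0, 2.0, 3.0])
        assert (s["median"], s["q1"], s["q3"], s["n"]) == (2.0, 1.5, 2.5, 3)

    def test_single_value(self):
        s = summarize_group([4.2])
        assert s["median"] == s["q1"] == s["q3"] == 4.2

    def test_permutation_invariance(self):
        a = summarize_group([3.0, 1.0, 4.0, 1.5, 9.0])
        b = summarize_group([9.0, 1.5, 1.0, 4.0, 3.0])
        assert a == b


def _user_frame(rows):
    df = pd.DataFrame(rows)
    if "excluded" in df:
        df["excluded"] = df["excluded"].map(lambda v: bool(v) if v == v else False)
    else:
        df["excluded"] = False
    if "hand" not in df:
        df["hand"] = "right"
    return df


class TestPairwiseLateral:
    def test_worked_time_to_find_example(self, layout):
        """Left 8 s vs mirrored right 5 s gives +3 s (right found sooner)."""
        lid = "s1r1"
        rid = layout.mirror[lid]
        frame = _user_frame(
            [
                {"location_id": lid, "time_to_find_s": 8.0},
                {"location_id": rid, "time_to_find_s": 5.0},
            ]
        )
        rep = pairwise_lateral([frame], layout, "time_to_find_s")
        assert rep.per_user[0] == pytest.approx(3.0)

    def test_worked_anchoring_example(self, layout):
        """Left 100 ms vs right 300 ms gives -200 ms (left fixated earlier)."""
        lid = "s2r2"
        rid = layout.mirror[lid]
        frame = _user_frame(
            [
                {"location_id": lid, "anchor_offset_s": 0.100},
                {"location_id": rid, "anchor_offset_s": 0.300},
            ]
        )
        rep = pairwise_lateral([frame], layout, "anchor_offset_s")
        assert rep.per_user[0] == pytest.approx(-0.200)

    def test_equal_sides_give_zero(self, layout):
        rows = []
        for lid in ["s1r1", "s2r3"]:
            rows.append({"location_id": lid, "time_to_find_s": 2.0})
            rows.append({"location_id": layout.mirror[lid], "time_to_find_s": 2.0})
        rep = pairwise_lateral([_user_frame(rows)], layout, "time_to_find_s")
        assert rep.per_user[0] == 0.0

    def test_pairs_missing_one_side_dropped(self, layout):
        frame = _user_frame(
            [
                {"location_id": "s1r1", "time_to_find_s": 8.0},
                {"location_id": layout.mirror["s1r1"], "time_to_find_s": 5.0},
                {"location_id": "s2r2", "time_to_find_s": 9.0},  # no mirror data
            ]
        )
        rep = pairwise_lateral([frame], layout, "time_to_find_s")
        assert len(rep.pairs_per_user[0]) == 1
        assert rep.per_user[0] == pytest.approx(3.0)

    def test_user_without_pairs_excluded(self, layout):
        frame = _user_frame([{"location_id": "s4r1", "time_to_find_s": 1.0}])
        rep = pairwise_lateral([frame], layout, "time_to_find_s")
        assert rep.excluded_users == [0]
        assert len(rep.per_user) == 0

    def test_excluded_episodes_ignored(self, layout):
        lid = "s1r1"
        rid = layout.mirror[lid]
        frame = _user_frame(
            [
                {"location_id": lid, "time_to_find_s": 8.0},
                {"location_id": lid, "time_to_find_s": 100.0, "excluded": True},
                {"location_id": rid, "time_to_find_s": 5.0},
            ]
        )
        rep = pairwise_lateral([frame], layout, "time_to_find_s")
        assert rep.per_user[0] == pytest.approx(3.0)


def _fused_from_positions(t, pos):
    v = np.gradient(pos, t, axis=0)
    return FusedTrajectory(
        grid=t,
        position=pos,
        velocity=v,
        position_sd=np.full(len(t), 0.001),
        valid=np.ones(len(t), dtype=bool),
        availability=1.0,
        offset_estimate=np.zeros(3),
        measurement_t=t,
        measurement_source=np.zeros(len(t), dtype=int),
        accepted=np.ones(len(t), dtype=bool),
    )


class TestDetectMotionOnset:
    INK = np.array([0.1, -0.22, 0.0])
    TARGET = np.array([-0.2, 0.2, 0.0])

    def _reach(self, t_exit=2.0, duration=0.7, hesitate=False):
        t = np.arange(0.0, 4.0, 0.025)
        pos = np.tile(self.INK, (len(t), 1))
        m = (t >= t_exit) & (t <= t_exit + duration)
        pos[m] = minimum_jerk(self.INK, self.TARGET, duration, t[m] - t_exit)
        pos[t > t_exit + duration] = self.TARGET
        if hesitate:
            # insert a mid-reach pause: freeze positions briefly
            h = (t >= t_exit + 0.3) & (t <= t_exit + 0.42)
            pos[h] = pos[np.searchsorted(t, t_exit + 0.3)]
        return t, pos

    def test_clean_reach_onset_at_ink_exit(self):
        t, pos = self._reach()
        fused = _fused_from_positions(t, pos)
        onset = detect_motion_onset(fused, self.INK, self.TARGET, 2.0, 2.7)
        assert onset == pytest.approx(2.0, abs=0.026)

    def test_hesitation_does_not_move_onset(self):
        t, pos = self._reach(hesitate=True)
        fused = _fused_from_positions(t, pos)
        onset = detect_motion_onset(fused, self.INK, self.TARGET, 2.0, 2.7)
        assert onset == pytest.approx(2.0, abs=0.026)

    def test_monotone_speed_falls_back_to_ink_exit(self):
        t = np.arange(0.0, 1.0, 0.025)
        pos = np.outer(t**2, [0.1, 0.0, 0.0])  # strictly accelerating
        fused = _fused_from_positions(t, pos)
        onset = detect_motion_onset(fused, self.INK, self.TARGET, 0.1, 0.9)
        assert onset == 0.1

    def test_empty_window_rejected(self):
        t, pos = self._reach()
        fused = _fused_from_positions(t, pos)
        with pytest.raises(ValueError):
            detect_motion_onset(fused, self.INK, self.TARGET, 10.0, 10.5)

    def test_matches_enumerated_candidate_oracle(self):
        """Brute-force re-scoring of every speed minimum reproduces the
        detector's choice on a noisy reach."""
        rng = np.random.default_rng(5)
        t, pos = self._reach()
        pos = pos + rng.normal(0, 0.002, pos.shape)
        fused = _fused_from_positions(t, pos)
        t_exit, t_stamp = 2.0, 2.7
        onset = detect_motion_onset(fused, self.INK, self.TARGET, t_exit, t_stamp)

        speed = fused.speed()
        m = (t >= t_exit - 0.5) & (t <= t_stamp)
        idx = np.nonzero(m)[0]
        s = speed[idx]
        best = None
        move = self.TARGET - self.INK
        mn = np.linalg.norm(move)
        peak = s.max()
        wlen = t[idx[-1]] - t[idx[0]]
        ref = t_stamp - t_exit
        for i in range(1, len(s) - 1):
            if not (s[i] <= s[i - 1] and s[i] <= s[i + 1] and (s[i] < s[i - 1] or s[i] < s[i + 1])):
                continue
            gi = idx[i]
            tc = t[gi]
            disp = fused.position_at(tc + 0.15)[0] - fused.position[gi]
            dn = np.linalg.norm(disp)
            cos = float(disp @ move) / (dn * mn) if dn > 1e-3 else 0.0
            score = (
                np.linalg.norm(fused.position[gi] - self.INK) / mn
                + s[i] / peak
                + (1 - cos) / 2
                + abs(t_stamp - tc - ref) / wlen
            ) / 4
            if best is None or score < best[0] - 1e-15:
                best = (score, tc)
        assert onset == pytest.approx(best[1])


class TestGazeAnchoring:
    def _series(self, intervals):
        return FixationSeries(
            t=np.arange(100) * 0.025,
            filtered=[None] * 100,
            intervals=intervals,
            window=7,
        )

    def test_fixation_after_onset_positive(self):
        fs = self._series([FixationInterval("P", 2.1, 2.8, 2.15)])
        assert gaze_anchoring_offset("P", fs, 1.5, 2.0) == pytest.approx(0.100)

    def test_fixation_before_onset_negative(self):
        fs = self._series([FixationInterval("P", 1.95, 2.8, 2.0)])
        assert gaze_anchoring_offset("P", fs, 1.5, 2.0) == pytest.approx(-0.050)

    def test_pre_selection_fixations_ignored(self):
        fs = self._series(
            [
                FixationInterval("P", 0.5, 1.0, 0.6),   # the initial find
                FixationInterval("P", 2.1, 2.8, 2.15),  # the anchor
            ]
        )
        assert gaze_anchoring_offset("P", fs, 1.5, 2.0) == pytest.approx(0.100)

    def test_no_refixation_gives_none(self):
        fs = self._series([FixationInterval("Q", 2.1, 2.8, 2.15)])
        assert gaze_anchoring_offset("P", fs, 1.5, 2.0) is None
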