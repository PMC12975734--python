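"""The 27 IC features: DTW, gaze episodes, TAMA, turn detection, LSM."""

import functools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadcoord import (
    SignalTrace,
    adaptation_crosscorr,
    dtw_distance,
    gaze_coordination,
    lsm,
    pupil_coordination,
    tama_series,
    windowed_correlation,
)
from dyadcoord.features import FeatureConfig, detect_turns, structural_features
from dyadcoord.types import FUNCTION_WORD_CATEGORIES

from conftest import fixation_df, segments_df

# ==========================================================================
# DTW
# ==========================================================================


def dtw_oracle(a, b):
    """Independent top-down recursion over warping paths (memoized)."""

    @functools.lru_cache(maxsize=None)
    def go(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, go(i - 1, j))
        if j > 0:
            best = min(best, go(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, go(i - 1, j - 1))
        return c + best

    return go(len(a) - 1, len(b) - 1)


def dtw_bruteforce(a, b):
    """Exhaustive enumeration of every monotone warping path (tiny inputs)."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, acc):
        acc += abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDTW:
    def test_identical_series_distance_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        assert dtw_distance(x, x) == 0.0

    def test_constant_offset_diagonal_path(self):
        # A constant 0, B constant c: the diagonal path costs n*c and no
        # detour can do better
        assert dtw_distance(np.zeros(7), np.full(7, 1.5)) == pytest.approx(10.5)

    def test_two_sample_enumeration(self):
        assert dtw_distance(np.array([0.0, 1.0]), np.array([0.0, 2.0])) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 25)
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a), abs=1e-12)

    def test_matches_recursive_oracle_on_random_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n, m = rng.integers(2, 9, 2)
            a, b = rng.normal(0, 2, n), rng.normal(0, 2, m)
            assert dtw_distance(a, b) == pytest.approx(
                dtw_oracle(tuple(a), tuple(b)), abs=1e-10
            )

    def test_oracle_agrees_with_bruteforce_path_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n, m = rng.integers(2, 5, 2)
            a, b = rng.normal(0, 2, n), rng.normal(0, 2, m)
            assert dtw_oracle(tuple(a), tuple(b)) == pytest.approx(
                dtw_bruteforce(a, b), abs=1e-10
            )


class TestPupilCoordination:
    def test_identical_traces_zero_distance(self):
        rng = np.random.default_rng(2)
        x = SignalTrace(np.arange(2400) / 120.0, rng.normal(0, 1, 2400), 120.0)
        d, nw = pupil_coordination(x, x.copy())
        assert d == 0.0
        # (2400 - 720) / 360 + 1 windows at 6 s / 3 s
        assert nw == 5

    def test_single_window_constant_offset(self):
        n = 720
        a = SignalTrace(np.arange(n) / 120.0, np.zeros(n), 120.0)
        b = SignalTrace(np.arange(n) / 120.0, np.full(n, 0.5), 120.0)
        d, nw = pupil_coordination(a, b)
        assert nw == 1
        assert d == pytest.approx(n * 0.5)

    def test_too_short_returns_missing(self):
        a = SignalTrace(np.arange(100) / 120.0, np.zeros(100), 120.0)
        d, nw = pupil_coordination(a, a.copy())
        assert np.isnan(d) and nw == 0


# ==========================================================================
# Gaze coordination
# ==========================================================================


class TestGazeCoordination:
    def test_full_overlap_is_100(self):
        a = fixation_df([(0, 100, "partner_face")])
        assert gaze_coordination(a, a.copy(), 100.0) == pytest.approx(100.0)

    def test_disjoint_aois_zero(self):
        a = fixation_df([(0, 100, "partner_face")])
        b = fixation_df([(0, 100, "tokens_left")])
        assert gaze_coordination(a, b, 100.0) == 0.0

    def test_hand_computed_interval_intersection(self):
        # A: face[0,50] left[50,100]; B: face[25,75] left[75,100]
        a = fixation_df([(0, 50, "partner_face"), (50, 100, "tokens_left")])
        b = fixation_df([(25, 75, "partner_face"), (75, 100, "tokens_left")])
        assert gaze_coordination(a, b, 100.0) == pytest.approx(50.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        from dyadcoord.types import AOIS

        def random_track():
            rows, t = [], 0.0
            while t < 60:
                d = rng.uniform(0.2, 2.0)
                rows.append((t, min(t + d, 60.0), AOIS[rng.integers(0, 6)]))
                t += d + rng.uniform(0.0, 0.1)
            return fixation_df(rows)

        a, b = random_track(), random_track()
        assert gaze_coordination(a, b, 60.0) == pytest.approx(gaze_coordination(b, a, 60.0))

    def test_invalid_fixations_ignored(self):
        a = fixation_df([(0, 50, "partner_face"), (50, 100, "partner_face", False)])
        b = fixation_df([(0, 100, "partner_face")])
        assert gaze_coordination(a, b, 100.0) == pytest.approx(50.0)

    def test_nonpositive_duration_rejected(self):
        a = fixation_df([(0, 1, "partner_face")])
        with pytest.raises(ValueError):
            gaze_coordination(a, a, 0.0)


# ==========================================================================
# TAMA and windowed correlation
# ==========================================================================


class TestTama:
    def test_duration_weighted_mean(self):
        # 10 s at 200 Hz pitch and 5 s at 100 Hz inside one window
        segs = segments_df([("A", 0, 10, 200.0), ("A", 12, 17, 100.0)])
        out = tama_series(segs, "A", "pitch", window=25.0, step=12.5, duration=25.0)
        assert out[0] == pytest.approx((10 * 200 + 5 * 100) / 15)

    def test_silent_window_is_missing(self):
        segs = segments_df([("A", 0, 10, 200.0)])
        out = tama_series(segs, "A", "pitch", window=25.0, step=12.5, duration=50.0)
        assert np.isfinite(out[0]) and np.isnan(out[-1])

    def test_constant_pitch_everywhere(self):
        segs = segments_df([("A", i * 5, i * 5 + 3, 180.0) for i in range(20)])
        out = tama_series(segs, "A", "pitch", duration=100.0)
        np.testing.assert_allclose(out[np.isfinite(out)], 180.0)

    def test_session_shorter_than_window_rejected(self):
        segs = segments_df([("A", 0, 10, 200.0)])
        with pytest.raises(ValueError, match="window"):
            tama_series(segs, "A", "pitch", window=25.0, duration=10.0)


class TestWindowedCorrelation:
    def test_perfect_and_inverse(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        assert windowed_correlation(a, a)[0] == pytest.approx(1.0)
        assert windowed_correlation(a, -a)[0] == pytest.approx(-1.0)

    def test_direct_pearson_value(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 1, 4, 3])
        r, n = windowed_correlation(a, b, min_joint=4)
        assert n == 4
        assert r == pytest.approx(0.6)

    def test_too_few_joint_windows_missing(self):
        a = np.array([1.0, 2, np.nan, np.nan, np.nan, np.nan])
        b = np.array([2.0, 1, 1, 1, 1, np.nan])
        r, n = windowed_correlation(a, b, min_joint=5)
        assert np.isnan(r) and n == 2

    @given(
        st.floats(0.1, 10),
        st.floats(-5, 5),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_positive_affine_rescaling(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        r1, _ = windowed_correlation(a, b)
        r2, _ = windowed_correlation(scale * a + shift, scale * b + shift)
        assert r1 == pytest.approx(r2, abs=1e-9)


# ==========================================================================
# Turn detection
# ==========================================================================


class TestDetectTurns:
    def test_three_turn_walkthrough(self):
        segs = segments_df([("A", 0, 3), ("B", 3.5, 6), ("A", 6.2, 10)])
        res = detect_turns(segs)
        t = res.turns
        assert list(t["speaker"]) == ["A", "B", "A"]
        np.testing.assert_allclose(t["turn_length"], [3.0, 2.5, 3.8])
        assert np.isnan(t["response_time"].iloc[0])
        np.testing.assert_allclose(t["response_time"].iloc[1:], [0.5, 0.2])
        assert len(res.backchannels) == 0
        assert len(res.interruptions) == 0
        assert t["n_pauses"].sum() == 0

    def test_backchannel_inside_partner_turn(self):
        segs = segments_df([("A", 0, 5), ("B", 2.0, 2.6)])
        res = detect_turns(segs)
        assert list(res.turns["speaker"]) == ["A"]
        assert res.turns["turn_length"].iloc[0] == pytest.approx(5.0)
        assert len(res.backchannels) == 1
        assert res.backchannels["speaker"].iloc[0] == "B"

    def test_interruption_negative_response_time(self):
        segs = segments_df([("A", 0, 5), ("B", 4.3, 8)])
        res = detect_turns(segs)
        t = res.turns
        assert len(res.interruptions) == 1
        assert t["response_time"].iloc[1] == pytest.approx(-0.7)
        assert bool(t["interrupted_partner"].iloc[1])
        # the interrupted speaker loses the floor at the overlap start
        assert t["turn_offset"].iloc[0] == pytest.approx(4.3)
        assert t["turn_length"].iloc[0] == pytest.approx(4.3)

    def test_pause_merges_same_speaker_segments(self):
        segs = segments_df([("A", 0, 2), ("A", 2.3, 5)])
        res = detect_turns(segs)
        t = res.turns
        assert len(t) == 1
        assert t["n_pauses"].iloc[0] == 1
        assert t["pause_time"].iloc[0] == pytest.approx(0.3)
        assert t["turn_length"].iloc[0] == pytest.approx(4.7)

    def test_sub_threshold_gap_is_not_a_pause(self):
        segs = segments_df([("A", 0, 2), ("A", 2.1, 5)])
        t = detect_turns(segs).turns
        assert len(t) == 1 and t["n_pauses"].iloc[0] == 0

    def test_same_speaker_overlap_rejected(self):
        segs = segments_df([("A", 0, 3), ("A", 2.5, 5)])
        with pytest.raises(ValueError, match="overlap"):
            detect_turns(segs)

    def test_turns_never_contain_same_speaker_turns(self, session_zero):
        t = detect_turns(session_zero.segments).turns
        for spk in ("A", "B"):
            sub = t[t["speaker"] == spk]
            on = sub["turn_onset"].to_numpy()
            off = sub["turn_offset"].to_numpy()
            assert np.all(on[1:] >= off[:-1] - 1e-9)


# ==========================================================================
# Adaptation
# ==========================================================================


def interleaved_turns(values_a, values_b):
    rows = []
    for k, (va, vb) in enumerate(zip(values_a, values_b)):
        rows.append({"speaker": "A", "turn_length": va, "response_time": va})
        rows.append({"speaker": "B", "turn_length": vb, "response_time": vb})
    return pd.DataFrame(rows)


class TestAdaptation:
    def test_perfect_echo_gives_r_1(self):
        rng = np.random.default_rng(0)
        a = rng.normal(3, 1, 30)
        turns = interleaved_turns(a, a)  # B copies A's previous value exactly
        mean_r, diff_r, r_ab, r_ba, _ = adaptation_crosscorr(turns, "response_time")
        assert r_ab == pytest.approx(1.0)

    def test_constructed_coefficients_mean_and_difference(self):
        # build sequences with known lag-1 correlations by mixing noise
        rng = np.random.default_rng(1)
        n = 4000
        a = rng.normal(0, 1, n)
        ea, eb = rng.normal(0, 1, n), rng.normal(0, 1, n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * eb  # B follows A with r ~ 0.6
        a2 = np.empty(n)
        a2[0] = a[0]
        a2[1:] = 0.2 * b[:-1] + np.sqrt(1 - 0.04) * ea[1:]  # A follows B with r ~ 0.2
        turns = interleaved_turns(a2, 0.6 * a2 + np.sqrt(1 - 0.36) * eb)
        mean_r, diff_r, r_ab, r_ba, _ = adaptation_crosscorr(turns, "turn_length")
        assert r_ab == pytest.approx(0.6, abs=0.05)
        assert mean_r == pytest.approx((r_ab + r_ba) / 2)
        assert diff_r == pytest.approx(abs(r_ab - r_ba))

    def test_iid_noise_near_zero(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            turns = interleaved_turns(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
            mean_r, *_ = adaptation_crosscorr(turns, "turn_length")
            hits += abs(mean_r) < 0.1
        assert hits >= 95

    def test_too_few_pairs_missing(self):
        turns = interleaved_turns([1.0, 2.0], [2.0, 1.0])
        mean_r, *_ = adaptation_crosscorr(turns, "turn_length", min_pairs=4)
        assert np.isnan(mean_r)


# ==========================================================================
# LSM
# ==========================================================================


def counts_frame(values):
    return pd.DataFrame([dict(zip(FUNCTION_WORD_CATEGORIES, values))], index=[0])


class TestLSM:
    def test_identical_counts_give_1(self):
        c = counts_frame([10] * 8)
        assert lsm(c, c.copy()) == pytest.approx(1.0)

    def test_single_category_formula_value(self):
        a = counts_frame([3, 10, 10, 10, 10, 10, 10, 10])
        b = counts_frame([1, 10, 10, 10, 10, 10, 10, 10])
        cat = 1 - 2 / 4.0001
        assert lsm(a, b) == pytest.approx((7 + cat) / 8)
        assert cat == pytest.approx(0.500012, abs=1e-6)

    def test_double_zero_category_counts_as_match(self):
        a = counts_frame([0, 10, 10, 10, 10, 10, 10, 10])
        assert lsm(a, a.copy()) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = counts_frame(rng.integers(0, 30, 8))
        b = counts_frame(rng.integers(0, 30, 8))
        assert lsm(a, b) == pytest.approx(lsm(b, a))


# ==========================================================================
# Structural features
# ==========================================================================


class TestStructuralFeatures:
    def test_rate_and_time_arithmetic(self):
        # A: 10 turns totalling 120 s of speech, B: 4 turns totalling 60 s,
        # in a 300 s session (turn tables given directly: rate arithmetic)
        from dyadcoord.features import TurnDetectionResult

        rows = []
        for k in range(10):
            rows.append({"speaker": "A", "turn_onset": k * 30.0, "turn_offset": k * 30 + 12.0,
                         "turn_length": 12.0, "response_time": 0.5, "n_pauses": 0,
                         "pause_time": 0.0, "n_syllables": 60, "interrupted_partner": False})
        for k in range(4):
            rows.append({"speaker": "B", "turn_onset": k * 70 + 13.0, "turn_offset": k * 70 + 28.0,
                         "turn_length": 15.0, "response_time": 0.5, "n_pauses": 0,
                         "pause_time": 0.0, "n_syllables": 75, "interrupted_partner": False})
        turns = pd.DataFrame(rows).sort_values("turn_onset").reset_index(drop=True)
        res = TurnDetectionResult(
            turns,
            pd.DataFrame(columns=["speaker", "onset", "offset"]),
            pd.DataFrame(columns=["speaker", "time", "overlap"]),
        )
        segs = segments_df([(r["speaker"], r["turn_onset"], r["turn_offset"]) for r in rows])
        vals, _, _ = structural_features(res, segs, 300.0)
        assert vals["Turn_Rate_Difference"] == pytest.approx(abs(2.0 - 0.8))
        assert vals["Speaking_Time_Difference"] == pytest.approx(abs(0.4 - 0.2))

    def test_identical_statistics_zero_differences(self, session_zero):
        # swap speaker labels: every pair-level |difference| is label-invariant
        segs = session_zero.segments
        swapped = segs.assign(speaker=segs["speaker"].map({"A": "B", "B": "A"}))
        v1, _, _ = structural_features(detect_turns(segs), segs, session_zero.duration)
        v2, _, _ = structural_features(detect_turns(swapped), swapped, session_zero.duration)
        for name, val in v1.items():
            if name.endswith("_Difference") and np.isfinite(val):
                assert val == pytest.approx(v2[name], rel=1e-9), name

    def test_added_silence_scales_only_per_minute_rates(self):
        segs = segments_df([("A", 0, 3), ("B", 3.5, 6), ("A", 6.4, 9), ("B", 9.5, 12),
                            ("A", 12.4, 15), ("B", 15.5, 18)])
        cfg = FeatureConfig(min_joint_windows=10**9)  # TAMA features off
        res = detect_turns(segs)
        v1, _, _ = structural_features(res, segs, 60.0, cfg)
        v2, _, _ = structural_features(res, segs, 120.0, cfg)
        # turn-level features unchanged
        for name in ("Turn_Length_Difference", "Turn_Length_SD_Difference",
                     "Response_Time_Difference", "Pause_per_Turn_Difference",
                     "Pause_per_Speech_Difference", "Speech_Rate_Difference"):
            assert v1[name] == pytest.approx(v2[name], abs=1e-12), name
        # per-minute / per-duration rates scale by old/new duration
        for name in ("Turn_Rate_Difference", "Backchannel_Rate_Difference",
                     "Interrupt_Rate_Difference", "Pause_per_Minute_Difference",
                     "Speaking_Time_Difference"):
            assert v2[name] == pytest.approx(v1[name] / 2, abs=1e-12), name
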