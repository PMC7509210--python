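import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steerlimb.correlation import (
    NOT_STRONG,
    STRONG,
    CorrelationParams,
    amplitude_statistic,
    classify_strength,
    contribution_ratios,
    direction_correlation,
    direction_dependence_test,
    holm_adjust,
)
from steerlimb.errors import (
    CoverageError,
    DegenerateInputError,
    DomainError,
    PairingError,
    SampleSizeError,
)
from steerlimb.preprocess import DirectionSegments, SegmentationParams, segment_directions

FS = 100.0


def _sine_setup(duration_s=60.0, period_s=10.0):
    t = np.arange(int(duration_s * FS)) / FS
    torque = np.sin(2 * np.pi * t / period_s)
    segs = segment_directions(torque, FS, SegmentationParams(theta=0.05, min_dur_s=0.5))
    return torque, segs


class TestDirectionCorrelation:
    def test_self_correlation_is_one(self):
        torque, segs = _sine_setup()
        env = np.abs(torque)
        for direction in ("cw", "ccw"):
            r = direction_correlation(env, torque, segs, direction)
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_shifted_copy_still_one(self):
        # a 200 ms shift lies inside a 500 ms search window, so the
        # max-over-lags definition recovers r = 1 on an interior segment
        torque, _ = _sine_setup()
        y = np.abs(torque)
        shift = int(0.2 * FS)
        env = np.zeros_like(y)
        env[:-shift] = y[shift:]  # env(t) = |torque|(t + 200 ms)
        segs = DirectionSegments(segments=[(1000, 1400, "cw")], fs=FS)
        r = direction_correlation(
            env, torque, segs, "cw", CorrelationParams(max_lag_ms=500.0)
        )
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_null_level(self):
        # Monte-Carlo null: max-over-lags correlation of independent series
        # stays below 0.2 (100 seeds, 60 s at 100 Hz envelope rate)
        torque, segs = _sine_setup()
        for seed in range(100):
            r_gen = np.random.default_rng(seed)
            env = np.abs(r_gen.standard_normal(torque.size))
            r = direction_correlation(env, torque, segs, "cw")
            assert r < 0.2

    def test_affine_invariance(self, rng):
        torque, segs = _sine_setup(duration_s=40.0)
        env = np.abs(torque) + 0.1 * rng.standard_normal(torque.size)
        base = direction_correlation(env, torque, segs, "ccw")
        scaled = direction_correlation(3.0 * env + 5.0, 2.0 * torque, segs, "ccw")
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_missing_direction_is_coverage_error(self):
        torque = np.ones(2000)
        segs = segment_directions(torque, FS, SegmentationParams(theta=0.1))
        with pytest.raises(CoverageError, match="ccw"):
            direction_correlation(np.abs(torque), torque, segs, "ccw")

    def test_insufficient_duration_is_coverage_error(self):
        segs = DirectionSegments(segments=[(0, 50, "cw")], fs=FS)
        env = np.random.default_rng(0).standard_normal(50)
        with pytest.raises(CoverageError):
            direction_correlation(env, env, segs, "cw", CorrelationParams(max_lag_ms=1000.0))


class TestClassifyStrength:
    def test_above_threshold_is_strong(self):
        assert classify_strength(0.76) == STRONG

    def test_exact_threshold_is_not_strong(self):
        # strict inequality: only values larger than the threshold qualify
        assert classify_strength(0.75) == NOT_STRONG

    def test_low_value_not_strong(self):
        assert classify_strength(0.20) == NOT_STRONG

    @pytest.mark.parametrize("r", [-0.01, 1.01])
    def test_domain_error(self, r):
        with pytest.raises(DomainError):
            classify_strength(r)


class TestAmplitude:
    def test_constant_envelope(self):
        torque, segs = _sine_setup(duration_s=20.0)
        assert amplitude_statistic(np.full(torque.size, 0.5), segs, "cw") == pytest.approx(0.5)

    def test_direction_split(self):
        torque, segs = _sine_setup(duration_s=20.0)
        env = np.where(torque < 0, 1.0, 0.0)
        a_cw = amplitude_statistic(env, segs, "cw")
        a_ccw = amplitude_statistic(env, segs, "ccw")
        assert a_cw == pytest.approx(0.0, abs=1e-12)
        assert a_ccw == pytest.approx(1.0, abs=1e-12)

    def test_no_segments_error(self):
        segs = DirectionSegments(segments=[], fs=FS)
        with pytest.raises(CoverageError):
            amplitude_statistic(np.ones(100), segs, "cw")


class TestContribution:
    def test_uniform_inputs_give_exact_tenths(self):
        c = contribution_ratios(np.full(10, 0.8), np.full(10, 0.4))
        np.testing.assert_array_equal(c, np.full(10, 0.1))

    def test_two_muscle_toy(self):
        c = contribution_ratios(np.array([0.8, 0.4]), np.array([0.5, 0.25]))
        np.testing.assert_allclose(c, [0.8, 0.2], atol=1e-12)

    def test_all_zero_products_degenerate(self):
        with pytest.raises(DegenerateInputError):
            contribution_ratios(np.zeros(10), np.ones(10))

    def test_mismatched_lengths(self):
        with pytest.raises(PairingError):
            contribution_ratios(np.ones(10), np.ones(9))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=1.0),
                st.floats(min_value=0.0, max_value=5.0),
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_normalization_property(self, pairs):
        rs = np.array([p[0] for p in pairs])
        amps = np.array([p[1] for p in pairs])
        if (rs * amps).sum() <= 0:
            with pytest.raises(DegenerateInputError):
                contribution_ratios(rs, amps)
            return
        c = contribution_ratios(rs, amps)
        assert np.all(c >= 0)
        assert c.sum() == pytest.approx(1.0, abs=1e-9)


class TestDirectionDependence:
    def test_identical_arrays_p_is_one(self):
        r = np.linspace(0.2, 0.9, 12)
        assert direction_dependence_test(r, r.copy()) == 1.0

    def test_clear_separation_small_p(self):
        rng = np.random.default_rng(42)
        r_cw = 0.8 + 0.05 * rng.standard_normal(20)
        r_ccw = 0.3 + 0.05 * rng.standard_normal(20)
        p = direction_dependence_test(r_cw, r_ccw)
        assert p < 0.001

    def test_matches_bruteforce_enumeration_small_n(self):
        # independent oracle: enumerate all sign patterns directly
        rng = np.random.default_rng(7)
        d = rng.standard_normal(8)
        obs = abs(d.mean())
        count = 0
        for mask in range(1 << 8):
            signs = np.array([1.0 if mask >> k & 1 else -1.0 for k in range(8)])
            if abs((signs * d).mean()) >= obs - 1e-12 * (1 + obs):
                count += 1
        expected = count / (1 << 8)
        p = direction_dependence_test(d + 1.0, np.ones(8))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_n_one_is_error(self):
        with pytest.raises(SampleSizeError):
            direction_dependence_test(np.array([0.5]), np.array([0.4]))

    def test_unequal_lengths_is_pairing_error(self):
        with pytest.raises(PairingError):
            direction_dependence_test(np.ones(5), np.ones(4))

    def test_monte_carlo_branch_valid_p(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=25)
        b = rng.uniform(size=25)
        p = direction_dependence_test(a, b, n_resamples=2000, seed=9)
        assert 0.0 < p <= 1.0


class TestHolm:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.3, 0.04])
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        # smallest raw p gets the largest multiplier
        assert adj[0] == pytest.approx(0.004)
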