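"""Local EDF, Anderson-Darling statistic and the windowed hard decision."""

import numpy as np
import pytest

import gofshrink as gs


class TestLocalEdf:
    def test_simple_fractions(self):
        edf = gs.local_edf([1.0, 2.0, 3.0, 4.0])
        assert edf(2.5) == 0.5
        assert edf(0.0) == 0.0
        assert edf(4.0) == 1.0
        assert edf(99.0) == 1.0

    def test_right_continuity_at_order_statistics(self):
        edf = gs.local_edf([1.0, 1.0, 2.0])
        assert edf(1.0) == pytest.approx(2 / 3)
        assert edf(np.nextafter(1.0, 0.0)) == 0.0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(7)
        values = rng.standard_normal(25)
        edf = gs.local_edf(values)
        for t in rng.uniform(-3, 3, size=100):
            assert edf(t) == np.mean(values <= t)

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError):
            gs.local_edf([1.0])


class TestAdStatistic:
    def test_two_values_at_reference_median(self):
        # closed form: tau = -2 - (1/2)[(1+3)(ln .5 + ln .5)] = -2 + 4 ln 2
        assert gs.ad_statistic([0.0, 0.0]) == pytest.approx(-2 + 4 * np.log(2))

    def test_window_of_zeros_closed_form(self):
        # sum of odd numbers is L^2, so tau = -L + 2L ln 2
        tau = gs.ad_statistic(np.zeros(25))
        assert tau == pytest.approx(-25 + 50 * np.log(2))

    def test_matches_exact_segment_integration(self):
        # independent evaluation of L * integral (F_L - F)^2 / (F(1-F)) dF
        # using the closed-form antiderivative on each EDF step
        rng = np.random.default_rng(1)
        ref = gs.standard_reference_cdf()
        for _ in range(10):
            z = np.sort(rng.standard_normal(25))
            u = np.concatenate([[0.0], ref(z), [1.0]])
            L = z.size
            total = 0.0
            for k in range(L + 1):
                a = k / L
                u1, u2 = u[k], u[k + 1]
                if u2 <= u1:
                    continue
                term = -(u2 - u1)
                if a > 0:
                    term += a**2 * np.log(u2 / u1)
                if a < 1:
                    term -= (1 - a) ** 2 * np.log((1 - u2) / (1 - u1))
                total += term
            assert gs.ad_statistic(z, ref) == pytest.approx(L * total, rel=1e-9)

    def test_depends_only_on_value_multiset(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal(25)
        tau = gs.ad_statistic(values)
        assert gs.ad_statistic(rng.permutation(values)) == pytest.approx(tau)

    def test_far_outlier_sample_is_finite_and_large(self):
        tau = gs.ad_statistic(np.full(25, 50.0))
        assert np.isfinite(tau)
        assert tau > 100.0

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError):
            gs.ad_statistic([np.nan] * 25)


class TestAdStatisticMap:
    def test_agrees_with_scalar_statistic_on_wrapped_windows(self):
        rng = np.random.default_rng(3)
        band = rng.standard_normal((12, 12))
        tau = gs.ad_statistic_map(band, 3)
        padded = np.pad(band, 1, mode="wrap")
        for i in (0, 5, 11):
            for j in (0, 7, 11):
                expected = gs.ad_statistic(padded[i : i + 3, j : j + 3])
                # the map works in float32; tolerance covers that precision
                assert tau[i, j] == pytest.approx(expected, rel=2e-3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            gs.ad_statistic_map(np.zeros((8, 8)), 4)


class TestThresholdSubband:
    def test_retained_coefficients_are_bit_identical(self, rng):
        band = rng.standard_normal((64, 64)) * 3.0
        out, mask = gs.threshold_subband(band, 2.0, 5)
        np.testing.assert_array_equal(out[mask], band[mask])
        assert np.all(out[~mask] == 0.0)

    def test_monotone_in_threshold(self, rng):
        band = rng.standard_normal((64, 64))
        _, loose = gs.threshold_subband(band, 1.0, 5)
        _, tight = gs.threshold_subband(band, 4.0, 5)
        assert np.all(loose[tight])  # tight-retained is a subset of loose-retained

    def test_pure_noise_retained_fraction_matches_pfa(self, dwt_curve):
        # the operational definition of the false-alarm probability; the
        # fraction is measured on a stride-l grid (disjoint windows are
        # independent under H0, making the binomial error model exact)
        pfa = 0.005
        T = gs.threshold_for_pfa(pfa, dwt_curve, "all")
        rng = np.random.default_rng(77)
        hits, n = 0, 0
        for _ in range(3):
            band = rng.standard_normal((256, 256))
            _, mask = gs.threshold_subband(band, T, 5)
            sub = mask[::5, ::5]
            hits += int(sub.sum())
            n += sub.size
        se = np.sqrt(pfa * (1 - pfa) / n)
        assert abs(hits / n - pfa) < 3 * se

    @pytest.mark.parametrize("window_side", [3, 7])
    def test_false_alarm_rate_holds_for_other_window_sizes(self, window_side):
        pfa = 0.01
        curve = gs.estimate_pfa_curve(
            "dwt", levels=3, window_side=window_side, field_size=512,
            realizations=2, seed=42,
        )
        T = gs.threshold_for_pfa(pfa, curve, "all")
        rng = np.random.default_rng(88)
        hits, n = 0, 0
        for _ in range(3):
            band = rng.standard_normal((256, 256))
            _, mask = gs.threshold_subband(band, T, window_side)
            sub = mask[::window_side, ::window_side]
            hits += int(sub.sum())
            n += sub.size
        se = np.sqrt(pfa * (1 - pfa) / n)
        assert abs(hits / n - pfa) < 3 * se

    def test_strong_signal_block_is_retained(self, dwt_curve):
        rng = np.random.default_rng(5)
        band = rng.standard_normal((64, 64))
        band[20:29, 20:29] = 10.0
        T = gs.threshold_for_pfa(0.005, dwt_curve, "all")
        _, mask = gs.threshold_subband(band, T, 5)
        assert np.all(mask[22:27, 22:27])  # block interior sees all-shifted windows

    def test_zero_subband_zeroed_under_reference_threshold(self):
        # an all-zero window has tau = -L + 2L ln 2 ~ 9.66, far below the
        # reference polynomial's threshold scale, so nothing is retained
        T = gs.reference_threshold(0.005)
        out, mask = gs.threshold_subband(np.zeros((32, 32)), T, 5)
        assert not mask.any()
        assert not out.any()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gs.threshold_subband(np.zeros((16, 16)), 0.0, 5)
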