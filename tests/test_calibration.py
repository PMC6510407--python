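"""Threshold calibration: Monte-Carlo curves, polynomial model, lookups."""

import numpy as np
import pytest

import gofshrink as gs
from gofshrink.calibration import REFERENCE_COEFFS


class TestReferencePolynomial:
    def test_value_at_zero_is_constant_term(self):
        assert gs.reference_threshold(0.0) == 81.76

    def test_value_at_one_is_coefficient_sum(self):
        assert gs.reference_threshold(1.0) == pytest.approx(float(REFERENCE_COEFFS.sum()))
        assert gs.reference_threshold(1.0) == pytest.approx(-5.24, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gs.reference_threshold(1.5)


@pytest.fixture(scope="module")
def small_curve():
    return gs.estimate_pfa_curve("dwt", levels=3, field_size=512, realizations=2, seed=11)


class TestEstimatePfaCurve:
    def test_reproducible_bit_for_bit(self, small_curve):
        again = gs.estimate_pfa_curve("dwt", levels=3, field_size=512, realizations=2, seed=11)
        for key in small_curve.keys():
            np.testing.assert_array_equal(small_curve.tables[key][0], again.tables[key][0])
            np.testing.assert_array_equal(small_curve.tables[key][1], again.tables[key][1])

    def test_pfa_monotone_nonincreasing_in_threshold(self, small_curve):
        for key in small_curve.keys():
            _, pfa = small_curve.tables[key]
            assert np.all(np.diff(pfa) <= 0)
            assert np.all((pfa >= 0) & (pfa <= 1))

    def test_low_grid_end_is_upper_tail_median(self, small_curve):
        # the grid starts at the pooled tau median, where pfa ~ 0.5
        _, pfa = small_curve.tables["all"]
        assert 0.4 < pfa[0] <= 0.6

    def test_dwt_scale_curves_agree_within_monte_carlo_error(self, dwt_curve):
        # the orthonormal DWT whitens noise identically at every scale, so
        # per-scale survival curves coincide up to sampling error; compare
        # each scale to the pooled curve at moderate pfa with an effective
        # sample size that discounts the 25x window overlap
        grid, pooled = dwt_curve.tables["all"]
        for j in (1, 2, 3):
            thr, pfa = dwt_curve.tables[f"scale{j}"]
            n_eff = dwt_curve.n_windows[f"scale{j}"] / 25
            for target in (0.05, 0.01, 5e-3):
                i = int(np.argmin(np.abs(pooled - target)))
                se = np.sqrt(pooled[i] * (1 - pooled[i]) / n_eff)
                assert abs(pfa[i] - pooled[i]) < 3 * se

    def test_warns_when_too_few_windows(self):
        with pytest.warns(UserWarning, match="windows at the coarsest"):
            gs.estimate_pfa_curve("dwt", levels=5, field_size=256, realizations=1, seed=1)


class TestFitThresholdPolynomial:
    def test_recovers_exact_polynomial_model(self):
        # points generated from the reference polynomial must refit exactly
        pfa = np.linspace(0.0, 0.5, 40)
        thr = np.polyval(REFERENCE_COEFFS, pfa)
        curve = gs.ThresholdCurve(
            scope={"transform": "dwt"}, seed=0, tables={"all": (thr, pfa)}
        )
        coeffs = gs.fit_threshold_polynomial(curve, degree=8, key="all")
        np.testing.assert_allclose(coeffs, REFERENCE_COEFFS, rtol=1e-6)

    def test_fit_on_empirical_curve_is_monotone_and_tight(self, small_curve):
        coeffs = gs.fit_threshold_polynomial(small_curve, key="all")
        lo, hi = small_curve.poly_domains["all"]
        xs = np.linspace(lo, hi, 200)
        fitted = np.polyval(coeffs, xs)
        assert np.all(np.diff(fitted) <= 1e-9)  # decreasing in pfa
        thr, pfa = small_curve.tables["all"]
        target = np.interp(xs, pfa[::-1], thr[::-1])
        resid = target - fitted
        assert np.sqrt(np.mean(resid**2)) <= 0.02 * (target.max() - target.min())

    def test_too_few_distinct_points_raise(self):
        curve = gs.ThresholdCurve(
            scope={}, seed=0,
            tables={"all": (np.linspace(1, 2, 5), np.linspace(0.5, 0.1, 5))},
        )
        with pytest.raises(ValueError, match="distinct"):
            gs.fit_threshold_polynomial(curve, degree=8, key="all")


class TestThresholdForPfa:
    def test_reference_default_used_without_curve(self):
        assert gs.threshold_for_pfa(0.005) == pytest.approx(
            np.polyval(REFERENCE_COEFFS, 0.005)
        )

    def test_lookup_inverts_the_empirical_table(self, small_curve):
        T = gs.threshold_for_pfa(0.01, small_curve, "all")
        thr, pfa = small_curve.tables["all"]
        # empirical pfa at the returned threshold should bracket the target
        i = int(np.searchsorted(thr, T))
        assert pfa[min(i, pfa.size - 1)] <= 0.011
        assert pfa[max(i - 1, 0)] >= 0.009

    def test_out_of_range_pfa_raises(self, small_curve):
        with pytest.raises(ValueError, match="outside the calibrated range"):
            gs.threshold_for_pfa(1e-9, small_curve, "all")

    def test_scope_mismatch_refused(self, small_curve):
        with pytest.raises(ValueError, match="scope mismatch"):
            gs.threshold_for_pfa(0.01, small_curve, "all", scope={"transform": "dtcwt"})

    def test_held_out_false_alarm_closure(self, dwt_curve):
        # Pfa -> T -> fresh noise -> retained fraction recovers Pfa
        rng = np.random.default_rng(31415)
        noise_bands = [rng.standard_normal((512, 512)) for _ in range(3)]
        for pfa in (1e-3, 5e-3, 1e-2):
            T = gs.threshold_for_pfa(pfa, dwt_curve, "all")
            hits, n = 0, 0
            for band in noise_bands:
                tau = gs.ad_statistic_map(band, 5)
                sub = tau[::5, ::5]
                hits += int((sub > T).sum())
                n += sub.size
            se = np.sqrt(pfa * (1 - pfa) / n)
            assert abs(hits / n - pfa) < 3 * se


class TestCurveSerialization:
    def test_round_trip_preserves_tables_and_lookup(self, small_curve, tmp_path):
        gs.fit_threshold_polynomial(small_curve, key="all")
        path = tmp_path / "curve.csv"
        gs.save_curve(path, small_curve)
        loaded = gs.load_curve(path)
        assert loaded.scope == small_curve.scope
        for key in small_curve.keys():
            np.testing.assert_allclose(
                loaded.tables[key][0], small_curve.tables[key][0], rtol=1e-15
            )
        assert gs.threshold_for_pfa(0.01, loaded, "all") == pytest.approx(
            gs.threshold_for_pfa(0.01, small_curve, "all")
        )
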