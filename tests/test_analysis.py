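"""Peak localization, gradient fits and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imctissue.analysis import (
    PEAK_WINDOWS,
    compare_temperature_groups,
    estimate_shift,
    find_peak,
    fit_band_center,
    fit_gradient,
)
from imctissue.errors import InvalidParameterError


def gaussian_spectrum(center, width=45.0, amplitude=1.0, window=(1350, 1550), step=2.0, baseline=0.1):
    wl = np.arange(window[0], window[1] + 0.5 * step, step)
    vals = baseline + amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return wl, vals


class TestFindPeak:
    def test_gaussian_band_center(self):
        wl, vals = gaussian_spectrum(1441.0)
        pk = find_peak((wl, vals), (1350, 1550))
        assert abs(pk.wavelength - 1441.0) <= 0.5

    def test_symmetric_triplet_is_exact(self):
        pk = find_peak((np.array([1448.0, 1450.0, 1452.0]), np.array([1.0, 2.0, 1.0])), (1448, 1452))
        assert pk.wavelength == pytest.approx(1450.0)
        assert pk.method == "parabolic"

    def test_monotone_ramp_returns_boundary(self):
        wl = np.arange(1400.0, 1421.0, 2.0)
        pk = find_peak((wl, wl * 0.01), (1400, 1420))
        assert pk.wavelength == 1420.0
        assert pk.method == "discrete-argmax"

    def test_flat_spectrum_flags_degeneracy(self):
        wl = np.arange(1400.0, 1421.0, 2.0)
        pk = find_peak((wl, np.ones_like(wl)), (1400, 1420))
        assert pk.wavelength == 1400.0
        assert pk.degenerate

    def test_needs_three_points(self):
        with pytest.raises(InvalidParameterError):
            find_peak((np.array([1.0, 2.0]), np.array([0.0, 1.0])), (0, 3))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        shift=st.floats(-20.0, 20.0),
        scale=st.floats(0.1, 50.0),
    )
    def test_translation_equivariance_and_scale_invariance(self, shift, scale):
        wl, vals = gaussian_spectrum(1441.0)
        ref = find_peak((wl, vals), (1350, 1550))
        moved = find_peak((wl + shift, scale * vals), (1350 + shift, 1550 + shift))
        assert moved.wavelength == pytest.approx(ref.wavelength + shift, abs=1e-9)

    def test_dataframe_input_with_column(self):
        wl, vals = gaussian_spectrum(1441.0)
        df = pd.DataFrame({"wavelength_nm": wl, "mu_a_mm": vals})
        pk = find_peak(df, PEAK_WINDOWS["water_1450"], value_column="mu_a_mm")
        assert abs(pk.wavelength - 1441.0) <= 0.5


class TestFitBandCenter:
    def test_clean_gaussian_recovered(self):
        wl, vals = gaussian_spectrum(1441.0)
        pk = fit_band_center((wl, vals), (1350, 1550))
        assert pk.method == "band-fit"
        assert abs(pk.wavelength - 1441.0) <= 0.5

    def test_noisy_gaussian_beats_argmax(self, rng):
        # with a few percent multiplicative noise the band fit localizes the
        # center far better than the 3-point parabolic argmax
        errs_fit, errs_argmax = [], []
        for _ in range(30):
            wl, vals = gaussian_spectrum(1441.0)
            noisy = vals * (1 + rng.normal(0, 0.03, size=vals.size))
            errs_fit.append(abs(fit_band_center((wl, noisy), (1350, 1550)).wavelength - 1441.0))
            errs_argmax.append(abs(find_peak((wl, noisy), (1350, 1550)).wavelength - 1441.0))
        assert np.median(errs_fit) < 2.0
        assert np.median(errs_fit) < np.median(errs_argmax)

    def test_falls_back_on_ramp(self):
        wl = np.arange(1400.0, 1421.0, 2.0)
        pk = fit_band_center((wl, 0.01 * wl), (1400, 1420))
        assert pk.method == "discrete-argmax"


class TestFitGradient:
    def test_exact_line(self):
        wl = np.arange(400.0, 1501.0, 10.0)
        mu_s = 20.0 - 0.01 * (wl - 400.0)
        est = fit_gradient((wl, mu_s), (400, 1500))
        assert est.slope == pytest.approx(-0.01, abs=1e-12)
        assert est.standard_error == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_normal_equations(self, rng):
        wl = np.arange(500.0, 801.0, 20.0)
        vals = 5.0 - 0.004 * wl + rng.normal(0, 0.1, wl.size)
        est = fit_gradient((wl, vals), (500, 800))
        # closed-form OLS via the normal equations
        X = np.column_stack([np.ones_like(wl), wl])
        beta = np.linalg.solve(X.T @ X, X.T @ vals)
        resid = vals - X @ beta
        sigma2 = resid @ resid / (wl.size - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        assert est.slope == pytest.approx(beta[1], rel=1e-10)
        assert est.standard_error == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-10)

    def test_standard_error_calibration(self, rng):
        # SE matches OLS sampling theory within 20% over 100 simulations
        wl = np.arange(400.0, 1501.0, 25.0)
        sigma = 0.5
        slopes, ses = [], []
        for _ in range(100):
            vals = 10.0 - 0.005 * wl + rng.normal(0, sigma, wl.size)
            est = fit_gradient((wl, vals), (400, 1500))
            slopes.append(est.slope)
            ses.append(est.standard_error)
        assert np.mean(ses) == pytest.approx(np.std(slopes, ddof=1), rel=0.2)

    def test_singular_design_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_gradient((np.array([500.0, 500.0, 500.0]), np.array([1.0, 2.0, 3.0])), (400, 600))


class TestGroupComparisons:
    def test_shift_antisymmetry_and_significance(self, rng):
        a = 1454.0 + rng.normal(0, 1.0, 10)
        b = 1441.0 + rng.normal(0, 1.0, 10)
        ab = estimate_shift(a, b, labels=("25C", "60C"))
        ba = estimate_shift(b, a, labels=("60C", "25C"))
        assert ab.estimate_difference == pytest.approx(-ba.estimate_difference)
        assert abs(ab.estimate_difference - (-13.0)) < 2.0
        assert ab.p_value < 0.01

    def test_identical_groups_null(self, rng):
        vals = 1450.0 + rng.normal(0, 1.0, 10)
        cmp_res = estimate_shift(vals, vals.copy())
        assert cmp_res.estimate_difference == pytest.approx(0.0)
        assert cmp_res.p_value > 0.9

    def test_two_replicates_zero_noise_flagged(self):
        cmp_res = estimate_shift(np.array([1454.0, 1454.0]), np.array([1441.0, 1441.0]))
        assert cmp_res.estimate_difference == pytest.approx(-13.0)
        assert cmp_res.flag == "low-power"

    def test_single_replicate_no_pvalue(self):
        cmp_res = estimate_shift(np.array([1454.0]), np.array([1441.0, 1442.0]))
        assert cmp_res.p_value is None
        assert cmp_res.flag == "insufficient-replicates"

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidParameterError, match="unknown group label"):
            compare_temperature_groups({"25C": np.ones(3)}, ("25C", "60C"))

    def test_injected_slope_difference_power(self, rng):
        # slope summaries differing by 3x the noise SD: detected in >=90% of runs
        detected = 0
        n_runs = 100
        for _ in range(n_runs):
            a = rng.normal(-0.010, 0.001, 12)
            b = rng.normal(-0.013, 0.001, 10)
            cmp_res = compare_temperature_groups({"25C": a, "60C": b}, ("25C", "60C"))
            detected += cmp_res.p_value <= 0.05
        assert detected >= 90

    def test_permutation_matches_welch_roughly(self, rng):
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(1.5, 1.0, 10)
        w = compare_temperature_groups({"a": a, "b": b}, ("a", "b"))
        p = compare_temperature_groups({"a": a, "b": b}, ("a", "b"), permutation=True, seed=3)
        assert p.method == "permutation"
        assert (w.p_value < 0.05) == (p.p_value < 0.05)
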