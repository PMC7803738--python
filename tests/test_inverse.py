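"""Quasi-Newton inversion: initial guess, round trips, bookkeeping contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from imctissue.errors import InvalidMeasurementError
from imctissue.forward import MeasuredQuantities, SimulationConfig, simulate_measurements
from imctissue.inverse import (
    InversionConfig,
    initial_guess,
    invert_optical_properties,
    invert_spectrum,
)
from imctissue.optics import OpticalProperties, sandwich, with_tissue
from conftest import bare_slab


class TestInitialGuess:
    def test_beer_lambert_mu_t_estimate(self, geometry):
        # pure absorber, index-matched: Tc pins mu_t exactly up to MC noise
        stack = bare_slab(1.0, 0.0, 0.0)
        meas = simulate_measurements(stack, geometry, SimulationConfig(n_photons=100_000, seed=21))
        guess = initial_guess(meas, stack, geometry, InversionConfig(seed=1))
        assert guess.mu_a + guess.mu_s == pytest.approx(1.0, rel=0.15)

    def test_total_attenuation_within_factor_three(self, geometry):
        truth = OpticalProperties(0.1, 10.0, 0.9, 1.0)
        stack = bare_slab(0.1, 10.0, 0.9)
        meas = simulate_measurements(stack, geometry, SimulationConfig(n_photons=100_000, seed=22))
        guess = initial_guess(meas, stack, geometry, InversionConfig(seed=2))
        ratio = (guess.mu_a + guess.mu_s) / truth.mu_t
        assert 1 / 3 < ratio < 3

    def test_grid_fallback_when_collimated_dead(self, geometry, ear_stack):
        meas = MeasuredQuantities(Rd=0.05, Tt=0.01, Td=0.01, Tc=0.0)
        cfg = InversionConfig(seed=3)
        guess = initial_guess(meas, ear_stack, geometry, cfg)
        (a_lo, a_hi), (s_lo, s_hi), (g_lo, g_hi) = cfg.bounds
        assert a_lo < guess.mu_a < a_hi
        assert s_lo < guess.mu_s < s_hi
        assert g_lo < guess.g < g_hi


class TestSinglePointInversion:
    def test_fixed_point_converges_immediately(self, geometry, ear_stack):
        # measurement equals the forward evaluation at the starting point
        cfg = InversionConfig(seed=55)
        start = OpticalProperties(0.2, 8.0, 0.88, 1.4)
        meas = simulate_measurements(
            with_tissue(ear_stack, start), geometry,
            SimulationConfig(n_photons=cfg.n_photons_inversion, seed=55),
        )
        res = invert_optical_properties(meas, ear_stack, geometry, cfg, x0=start)
        assert res.converged
        assert res.iterations <= 1
        assert res.residual_norm == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_recovery_midrange(self, geometry, ear_stack):
        truth = OpticalProperties(0.05, 5.0, 0.90, 1.4)
        stack = with_tissue(ear_stack, truth)
        cfg = InversionConfig(seed=17, residual_tolerance=1e-4, max_iterations=200)
        meas = simulate_measurements(stack, geometry, SimulationConfig(n_photons=cfg.n_photons_inversion, seed=17))
        res = invert_optical_properties(meas, ear_stack, geometry, cfg)
        r = res.recovered
        assert abs(r.mu_a - truth.mu_a) / truth.mu_a < 0.05
        assert abs(r.mu_s - truth.mu_s) / truth.mu_s < 0.05
        assert abs(r.g - truth.g) < 0.02

    def test_noisy_round_trips_median_error(self, geometry, ear_stack, rng):
        # 1% multiplicative measurement noise at a weakly absorbing truth
        # (mu_a * d ~ 0.01): scattering is recovered to a few percent, while
        # the absorption error is measurement-noise-limited (the absorbed
        # fraction ~2% is comparable to the noise), so mu_a is only pinned
        # to within a factor ~2.  Bounds below are frozen from empirical
        # noise propagation against the generating truth.
        truth = OpticalProperties(0.03, 8.0, 0.92, 1.4)
        stack = with_tissue(ear_stack, truth)
        base = simulate_measurements(stack, geometry, SimulationConfig(n_photons=100_000, seed=90))
        errs_a, errs_s = [], []
        for k in range(20):
            eps = rng.normal(0.0, 0.01, size=3)
            rd = base.Rd * (1 + eps[0])
            tt = base.Tt * (1 + eps[1])
            td = min(base.Td * (1 + eps[2]), tt)
            meas = MeasuredQuantities(Rd=rd, Tt=tt, Td=td, Tc=tt - td)
            res = invert_optical_properties(
                meas, ear_stack, geometry, InversionConfig(seed=100 + k, residual_tolerance=0.02, max_iterations=80)
            )
            errs_a.append(abs(res.recovered.mu_a - truth.mu_a) / truth.mu_a)
            errs_s.append(abs(res.recovered.mu_s - truth.mu_s) / truth.mu_s)
        assert np.median(errs_s) <= 0.10
        assert np.median(errs_a) <= 1.0

    def test_unattainable_measurement_rejected(self, geometry, ear_stack):
        meas = MeasuredQuantities(Rd=0.6, Tt=0.6, Td=0.5, Tc=0.1)
        with pytest.raises(InvalidMeasurementError):
            invert_optical_properties(meas, ear_stack, geometry, InversionConfig())

    def test_result_inside_bounds_and_call_economy(self, geometry, ear_stack, ear_measurement):
        cfg = InversionConfig(seed=4, max_iterations=30)
        res = invert_optical_properties(ear_measurement, ear_stack, geometry, cfg)
        (a_lo, a_hi), (s_lo, s_hi), (g_lo, g_hi) = cfg.bounds
        assert a_lo < res.recovered.mu_a < a_hi
        assert s_lo < res.recovered.mu_s < s_hi
        assert g_lo < res.recovered.g < g_hi
        # Broyden economy: finite differences only at init/refresh
        assert res.forward_calls <= 3 + cfg.max_iterations + 3 * res.jacobian_refreshes

    def test_reproducible_bit_for_bit(self, geometry, ear_stack, ear_measurement):
        cfg = InversionConfig(seed=12)
        a = invert_optical_properties(ear_measurement, ear_stack, geometry, cfg)
        b = invert_optical_properties(ear_measurement, ear_stack, geometry, cfg)
        assert a.recovered == b.recovered
        assert a.residual_norm == b.residual_norm
        assert a.forward_calls == b.forward_calls


class TestSpectrumInversion:
    def _table(self, geometry, ear_stack, wavelengths, props_per_wl, n_photons=20_000):
        rows = []
        for i, (wl, props) in enumerate(zip(wavelengths, props_per_wl)):
            m = simulate_measurements(
                with_tissue(ear_stack, props), geometry, SimulationConfig(n_photons=n_photons, seed=300 + i)
            )
            rows.append({"wavelength_nm": wl, "Rd": m.Rd, "Tt": m.Tt, "Td": m.Td, "Tc": m.Tc})
        return pd.DataFrame(rows)

    def test_smooth_spectrum_round_trip(self, geometry, ear_stack):
        # bounds frozen from noise propagation at these photon budgets:
        # scattering and anisotropy recover to well under 1%, absorption to
        # ~15% (absorbed fraction ~6% against ~0.5% tally noise)
        wavelengths = np.array([1000.0, 1010.0, 1020.0, 1030.0, 1040.0])
        truths = [
            OpticalProperties(0.2 + 0.01 * k, 6.0 - 0.05 * k, 0.90, 1.4) for k in range(5)
        ]
        table = self._table(geometry, ear_stack, wavelengths, truths, n_photons=200_000)
        out = invert_spectrum(
            table, ear_stack, geometry,
            InversionConfig(seed=31, residual_tolerance=0.03, n_photons_inversion=100_000, max_iterations=40),
        )
        assert bool(out["converged"].all())
        for k, truth in enumerate(truths):
            assert out["mu_a_mm"][k] == pytest.approx(truth.mu_a, rel=0.25)
            assert out["mu_s_mm"][k] == pytest.approx(truth.mu_s, rel=0.05)
            assert out["g"][k] == pytest.approx(truth.g, abs=0.02)
        assert np.allclose(out["mu_s_prime_mm"], out["mu_s_mm"] * (1 - out["g"]))

    def test_single_row_matches_single_inversion_schema(self, geometry, ear_stack, ear_measurement):
        m = ear_measurement
        table = pd.DataFrame([{"wavelength_nm": 800.0, "Rd": m.Rd, "Tt": m.Tt, "Td": m.Td, "Tc": m.Tc}])
        out = invert_spectrum(table, ear_stack, geometry, InversionConfig(seed=5))
        assert len(out) == 1
        assert set(out.columns) >= {
            "wavelength_nm", "mu_a_mm", "mu_s_mm", "g", "mu_s_prime_mm",
            "residual", "iterations", "converged", "seed",
        }

    def test_corrupted_row_is_isolated(self, geometry, ear_stack, ear_measurement):
        m = ear_measurement
        good = {"wavelength_nm": 800.0, "Rd": m.Rd, "Tt": m.Tt, "Td": m.Td, "Tc": m.Tc}
        bad = {"wavelength_nm": 810.0, "Rd": 0.7, "Tt": 0.6, "Td": 0.5, "Tc": 0.1}
        good2 = dict(good, wavelength_nm=820.0)
        out = invert_spectrum(pd.DataFrame([good, bad, good2]), ear_stack, geometry, InversionConfig(seed=6))
        assert out["flag"].str.contains("invalid-measurement").tolist() == [False, True, False]
        assert np.isnan(out["mu_a_mm"][1])
        assert np.isfinite(out["mu_a_mm"][0]) and np.isfinite(out["mu_a_mm"][2])

    def test_wavelengths_must_increase(self, geometry, ear_stack, ear_measurement):
        m = ear_measurement
        row = {"Rd": m.Rd, "Tt": m.Tt, "Td": m.Td, "Tc": m.Tc}
        table = pd.DataFrame([dict(row, wavelength_nm=810.0), dict(row, wavelength_nm=800.0)])
        with pytest.raises(Exception):
            invert_spectrum(table, ear_stack, geometry, InversionConfig(seed=7))
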