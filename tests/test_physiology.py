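"""pH-trace quantification: calibration, buffering, fluxes, assays."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from casurv import (
    BufferingModel,
    Epoch,
    FluorescenceTrace,
    Solution,
    SyntheticConfig,
    bicarbonate_buffering,
    co2_hydration_rate,
    fit_calibration,
    gen_ph_trace,
    gradient,
    intrinsic_buffering,
    microdialysis_interstitial,
    na_dependent_flux,
    net_acid_extrusion,
    qpcr_relative,
)
from casurv.physiology import ammonium_in, ammonium_out


class TestCalibration:
    def test_two_point_line(self):
        cal = fit_calibration([(1.0, 7.0), (2.0, 7.5)])
        assert cal.slope_ == pytest.approx(0.5)
        assert cal.intercept_ == pytest.approx(6.5)

    def test_collinear_points_zero_residual(self):
        cal = fit_calibration([(1.0, 7.0), (2.0, 7.5), (3.0, 8.0)])
        assert cal.residual_sd_ == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_identity(self):
        cal = fit_calibration([(0.8, 6.8), (1.4, 7.2), (2.1, 7.7)])
        ratios = np.linspace(0.5, 2.5, 11)
        assert np.abs(cal.inverse(cal.predict(ratios)) - ratios).max() < 1e-12

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(0)
        true_slope, true_icpt, sigma, n = 0.6, 6.4, 0.02, 6
        ratios = np.linspace(0.8, 2.0, n)
        ph = true_slope * ratios + true_icpt + rng.normal(scale=sigma, size=n)
        cal = fit_calibration(np.column_stack([ratios, ph]))
        se = sigma / np.sqrt(((ratios - ratios.mean()) ** 2).sum())
        assert abs(cal.slope_ - true_slope) < 3 * se

    def test_identical_ratios_error(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 7.0), (1.0, 7.5)])


class TestBuffering:
    def test_henderson_hasselbalch_ammonium(self):
        sol = Solution(pH_o=7.4, NH4Cl_total=20.0, CO2_present=False, HCO3_o=0.0)
        assert ammonium_out(sol, pKa=8.9) == pytest.approx(19.3869, abs=1e-3)

    def test_equilibrium_symmetry(self):
        sol = Solution(pH_o=7.4, NH4Cl_total=20.0, CO2_present=False, HCO3_o=0.0)
        assert ammonium_in(7.4, sol) == pytest.approx(ammonium_out(sol))

    def test_worked_prepulse_numbers(self):
        """20 mM NH4Cl, plateau pH_i 7.1, washout drop 0.4 -> beta ~96.7."""
        sol = Solution(pH_o=7.4, NH4Cl_total=20.0, CO2_present=False, HCO3_o=0.0)
        nh4_i = ammonium_in(7.1, sol, pKa=8.9)
        assert nh4_i == pytest.approx(38.68, abs=0.02)
        assert nh4_i / 0.4 == pytest.approx(96.7, abs=0.1)

    def test_bicarbonate_at_equal_ph(self):
        sol = Solution(pH_o=7.4, HCO3_o=22.0, CO2_present=True)
        assert bicarbonate_buffering(7.4, sol) == pytest.approx(50.6)

    def test_bicarbonate_acid_shifted(self):
        sol = Solution(pH_o=7.4, HCO3_o=22.0, CO2_present=True)
        assert bicarbonate_buffering(7.1, sol) == pytest.approx(2.3 * 11.026, abs=0.01)

    def test_bicarbonate_zero_cases(self):
        assert bicarbonate_buffering(7.2, Solution(HCO3_o=0.0, CO2_present=True)) == 0.0
        assert bicarbonate_buffering(7.2, Solution(CO2_present=False)) == 0.0

    def test_total_additivity(self):
        sol_co2 = Solution(HCO3_o=22.0, CO2_present=True)
        bm = BufferingModel(25.0, sol_co2)
        ph = np.array([6.9, 7.1, 7.4])
        assert np.allclose(bm.total(ph), 25.0 + bicarbonate_buffering(ph, sol_co2))
        bm0 = BufferingModel(25.0, Solution(CO2_present=False))
        assert np.allclose(bm0.total(ph), 25.0)

    def test_intrinsic_from_generated_prepulse(self):
        cfg = SyntheticConfig(seed=2)
        trace, sol = gen_ph_trace(cfg)
        res = intrinsic_buffering(trace, sol)
        assert res["beta_intrinsic"] == pytest.approx(cfg.trace.beta_intrinsic, rel=0.05)

    def test_small_acidification_below_noise_floor_errors(self):
        t = np.arange(0.0, 300.0)
        ph = np.where(t < 200, 7.1, 7.09)  # 0.01 drop only
        trace = FluorescenceTrace(
            time=t, value=ph,
            epochs=[Epoch("baseline", 0), Epoch("NH4_add", 50), Epoch("NH4_washout", 200)],
        )
        sol = Solution(NH4Cl_total=20.0, CO2_present=False, HCO3_o=0.0)
        with pytest.raises(ValueError, match="noise floor"):
            intrinsic_buffering(trace, sol, smooth_s=0)


class TestFlux:
    def test_constant_rate_times_beta(self):
        """dpH/dt = 0.002/s with beta 50 -> J = 6 mM/min in every bin."""
        t = np.arange(0.0, 100.0, 0.5)
        ph = 6.8 + 0.002 * t
        trace = FluorescenceTrace(
            time=t, value=ph, epochs=[Epoch("Na_restored", 0.0)]
        )
        bm = BufferingModel(50.0, Solution(CO2_present=False))
        flux = net_acid_extrusion(trace, bm, smooth_s=0)
        assert flux.J.size >= 2
        assert np.allclose(flux.J, 6.0, rtol=1e-6)

    def test_flat_trace_zero_flux(self):
        t = np.arange(0.0, 60.0, 0.5)
        trace = FluorescenceTrace(
            time=t, value=np.full_like(t, 7.0), epochs=[Epoch("Na_restored", 0.0)]
        )
        flux = net_acid_extrusion(trace, BufferingModel(50.0, Solution(CO2_present=False)), smooth_s=0)
        assert np.allclose(flux.J, 0.0)

    def test_linearity_in_beta_and_rate(self):
        t = np.arange(0.0, 100.0, 0.5)
        trace1 = FluorescenceTrace(time=t, value=6.8 + 0.001 * t, epochs=[Epoch("Na_restored", 0.0)])
        trace2 = FluorescenceTrace(time=t, value=6.8 + 0.002 * t, epochs=[Epoch("Na_restored", 0.0)])
        sol = Solution(CO2_present=False)
        j1 = net_acid_extrusion(trace1, BufferingModel(25.0, sol), smooth_s=0)
        j2 = net_acid_extrusion(trace1, BufferingModel(50.0, sol), smooth_s=0)
        assert np.allclose(2 * j1.J, j2.J)
        j3 = net_acid_extrusion(trace2, BufferingModel(25.0, sol), smooth_s=0)
        common, ia, ib = np.intersect1d(
            np.round(j1.bin_centers, 6), np.round(j3.bin_centers, 6), return_indices=True
        )
        assert common.size > 0
        assert np.allclose(2 * j1.J[ia], j3.J[ib], rtol=1e-6)

    def test_generator_round_trip_within_5pct(self):
        """Flux-vs-pH recovered within 5% per fully traversed bin."""
        cfg = SyntheticConfig(seed=2)
        trace, sol = gen_ph_trace(cfg)
        bm = BufferingModel(cfg.trace.beta_intrinsic, sol)
        flux = net_acid_extrusion(trace, bm)
        true = cfg.trace.true_flux(flux.bin_centers)
        inner = slice(1, -1)  # edge bins are only partially traversed
        rel = np.abs(flux.J[inner] / true[inner] - 1)
        assert rel.max() < 0.05

    def test_na_dependent_component_recovered(self):
        cfg = SyntheticConfig(seed=3)
        bm = BufferingModel(cfg.trace.beta_intrinsic, Solution(CO2_present=False))
        with_na, _ = gen_ph_trace(cfg, kind="prepulse", na_during_recovery=True)
        without_na, _ = gen_ph_trace(cfg, kind="prepulse", na_during_recovery=False)
        f_with = net_acid_extrusion(with_na, bm)
        f_without = net_acid_extrusion(without_na, bm)
        diff = na_dependent_flux(f_with, f_without)
        true = cfg.trace.true_flux(diff.bin_centers) - cfg.trace.true_flux(
            diff.bin_centers, with_na=False
        )
        inner = (diff.bin_centers > diff.bin_centers.min()) & (
            diff.bin_centers < diff.bin_centers.max()
        )
        assert np.abs(diff.J[inner] / true[inner] - 1).max() < 0.10

    def test_na_difference_identities(self):
        f = net_acid_extrusion(
            FluorescenceTrace(
                time=np.arange(0.0, 100.0, 0.5),
                value=6.8 + 0.002 * np.arange(0.0, 100.0, 0.5),
                epochs=[Epoch("Na_restored", 0.0)],
            ),
            BufferingModel(50.0, Solution(CO2_present=False)),
            smooth_s=0,
        )
        zero = na_dependent_flux(f, f)
        assert np.allclose(zero.J, 0.0)
        assert zero.na_dependent

    def test_no_common_bins_errors(self):
        from casurv.physiology import FluxEstimate

        a = FluxEstimate(np.array([6.725]), np.array([6.0]), np.array([10]))
        b = FluxEstimate(np.array([7.225]), np.array([2.0]), np.array([10]))
        with pytest.raises(ValueError, match="no pH bins"):
            na_dependent_flux(a, b)


class TestCO2Hydration:
    def test_linear_segment_slope(self):
        t = np.arange(0.0, 120.0, 0.5)
        ph = np.where(t < 30, 7.4, 7.4 - 0.01 * (t - 30))
        trace = FluorescenceTrace(time=t, value=ph, epochs=[Epoch("baseline", 0), Epoch("CO2_on", 30.0)])
        assert co2_hydration_rate(trace) == pytest.approx(0.01, rel=1e-6)

    def test_flat_trace_zero_rate(self):
        t = np.arange(0.0, 60.0, 0.5)
        trace = FluorescenceTrace(time=t, value=np.full_like(t, 7.4), epochs=[Epoch("CO2_on", 0.0)])
        assert co2_hydration_rate(trace) == pytest.approx(0.0, abs=1e-12)

    def test_missing_epoch_errors(self):
        t = np.arange(0.0, 10.0)
        trace = FluorescenceTrace(time=t, value=np.full_like(t, 7.4))
        with pytest.raises(ValueError, match="CO2_on"):
            co2_hydration_rate(trace)

    def test_generated_assay_recovers_initial_slope(self):
        cfg = SyntheticConfig(seed=4)
        trace, _ = gen_ph_trace(cfg, kind="co2")
        rate = co2_hydration_rate(trace)
        true = cfg.trace.co2_amplitude * cfg.trace.co2_rate_per_s
        assert rate == pytest.approx(true, rel=0.05)


class TestGradient:
    def _trace(self, value, epochs=None):
        t = np.arange(0.0, 60.0)
        return FluorescenceTrace(
            time=t, value=np.full_like(t, value) if np.isscalar(value) else value,
            epochs=epochs or [], region="core",
        )

    def test_constant_offset(self):
        series, means = gradient(self._trace(6.9), self._trace(7.3))
        assert np.allclose(series["delta_pH"], -0.4)
        assert means["all"] == pytest.approx(-0.4)

    def test_identical_traces_zero(self):
        series, _ = gradient(self._trace(7.1), self._trace(7.1))
        assert np.allclose(series["delta_pH"], 0.0)

    def test_core_step_shifts_epoch_mean(self):
        t = np.arange(0.0, 60.0)
        core_vals = np.where(t < 30, 7.0, 6.8)
        epochs = [Epoch("baseline", 0.0), Epoch("CO2_on", 30.0)]
        core = FluorescenceTrace(time=t, value=core_vals, epochs=epochs, region="core")
        _, means = gradient(core, self._trace(7.2))
        assert means["baseline"] == pytest.approx(-0.2)
        assert means["CO2_on"] == pytest.approx(-0.4)


class TestScalarAssays:
    @pytest.mark.parametrize("conc,rec,expected", [(1.0, 0.5, 2.0), (3.3, 1.0, 3.3)])
    def test_microdialysis(self, conc, rec, expected):
        assert microdialysis_interstitial(conc, rec) == pytest.approx(expected)

    @pytest.mark.parametrize("rec", [0.0, -0.1, 1.5])
    def test_microdialysis_invalid_recovery(self, rec):
        with pytest.raises(ValueError):
            microdialysis_interstitial(1.0, rec)

    @given(st.floats(0.01, 1.0), st.floats(0.1, 10.0))
    def test_microdialysis_round_trip(self, rec, true_conc):
        dialysate = true_conc * rec
        assert microdialysis_interstitial(dialysate, rec) == pytest.approx(true_conc)

    @pytest.mark.parametrize(
        "ct,r1,r2,expected",
        [(20.0, 20.0, 20.0, 1.0), (21.0, 20.0, 20.0, 0.5), (16.68, 20.0, 20.0, 9.98)],
    )
    def test_qpcr(self, ct, r1, r2, expected):
        assert qpcr_relative(ct, r1, r2) == pytest.approx(expected, abs=0.01)
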