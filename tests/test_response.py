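"""Compressibility routes, power-law fits and the exclusion scan."""

import numpy as np
import pytest

import fluctuodyn as fd
from fluctuodyn.constants import K_B
from fluctuodyn.datatypes import MixtureComposition, PowerLawFit
from fluctuodyn.errors import InsufficientDataError, InvalidParameterError

GRID = [232.0, 238.0, 244.0, 250.0, 258.0, 268.0, 280.0, 295.0]


class TestComposition:
    def test_dilute_glycerol_weight_fraction(self):
        # 3.2 mol% glycerol corresponds to 14.5 wt%
        w = fd.mole_to_weight_fraction(0.032, 92.09, 18.015)
        assert w == pytest.approx(0.145, abs=5e-4)

    @pytest.mark.parametrize("chi,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_endpoints(self, chi, expected):
        assert fd.mole_to_weight_fraction(chi) == expected

    def test_weight_mole_round_trip(self):
        chi = 0.032
        assert fd.weight_to_mole_fraction(
            fd.mole_to_weight_fraction(chi)) == pytest.approx(chi, rel=1e-12)


class TestNumberDensity:
    def test_pure_water(self):
        comp = MixtureComposition(0.0)
        assert fd.number_density(0.997, comp) == pytest.approx(0.0333, abs=5e-5)

    def test_pure_glycerol(self):
        comp = MixtureComposition(1.0)
        assert fd.number_density(1.261, comp) == pytest.approx(0.00825, abs=5e-5)

    def test_linear_in_density(self):
        comp = MixtureComposition(0.032)
        assert fd.number_density(2.0, comp) == pytest.approx(
            2 * fd.number_density(1.0, comp), rel=1e-12)


class TestCompressibilityFromS0:
    def test_ideal_gas_limit(self):
        n, T = 0.0334, 295.0
        expected = 1.0 / (n * 1e30 * K_B * T)
        assert fd.compressibility_from_S0(1.0, n, T) == pytest.approx(expected, rel=1e-12)

    def test_hand_value_supercooled_solution(self):
        kappa = fd.compressibility_from_S0(0.060, 0.0334, 295.0)
        assert kappa == pytest.approx(4.4e-10, rel=0.02)
        from fluctuodyn.response import kappa_to_micro_bar
        assert kappa_to_micro_bar(kappa) == pytest.approx(44.0, rel=0.02)

    def test_linear_in_s0(self):
        k1 = fd.compressibility_from_S0(0.03, 0.0334, 260.0)
        k2 = fd.compressibility_from_S0(0.06, 0.0334, 260.0)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)


class TestVolumeFluctuationRoute:
    def test_interleaved_copies_same_estimate(self):
        series = fd.generate_volume_series(3e5, 4e-10, 250.0, 1000, 3)
        from fluctuodyn.datatypes import VolumeSeries
        v2 = np.empty(2000)
        v2[0::2] = series.volumes
        v2[1::2] = series.volumes
        doubled = VolumeSeries(np.arange(2000.0), v2, 250.0)
        assert fd.kappa_from_volume_fluctuations(doubled) == pytest.approx(
            fd.kappa_from_volume_fluctuations(series), rel=1e-12)

    def test_scattering_and_fluctuation_routes_agree(self):
        """κ_T = S(0)/(n k_B T) and the NPT volume-fluctuation estimator
        coincide on matched synthetic inputs within sampling error."""
        kappa_true = 4.5e-10  # Pa⁻¹
        n, T = 0.0334, 260.0
        S0 = kappa_true * n * 1e30 * K_B * T
        kappa_s0 = fd.compressibility_from_S0(S0, n, T)
        series = fd.generate_volume_series(3.3e5, kappa_true, T, 100_000, 12)
        kappa_fluct = fd.kappa_from_volume_fluctuations(series)
        assert kappa_s0 == pytest.approx(kappa_true, rel=1e-12)
        assert kappa_fluct == pytest.approx(kappa_true, rel=0.03)


class TestPowerLawFit:
    def test_noiseless_round_trip_to_four_significant_figures(self):
        df = fd.generate_powerlaw_series(20.0, 0.36, 224.0, GRID, 0.0, 0)
        fit = fd.fit_powerlaw(df)
        assert fit.exponent == pytest.approx(0.36, rel=1e-4)
        assert fit.T_s == pytest.approx(224.0, rel=1e-4)
        assert fit.amplitude == pytest.approx(20.0, rel=1e-4)
        assert fit.R_squared == pytest.approx(1.0, abs=1e-9)

    def test_exact_round_trip_property(self):
        # noiseless generator output is an exact fixed point of the fitter
        for amp, expo, ts, seed in [(5.0, 0.26, 221.0, 0), (1.3, 1.2, 200.0, 1)]:
            df = fd.generate_powerlaw_series(amp, expo, ts, GRID, 0.0, seed)
            fit = fd.fit_powerlaw(df)
            assert fit.exponent == pytest.approx(expo, rel=1e-6)
            assert fit.T_s == pytest.approx(ts, rel=1e-6)
            assert fit.amplitude == pytest.approx(amp, rel=1e-6)

    def test_constant_series_flagged_degenerate(self):
        df = fd.generate_powerlaw_series(3.0, 0.0, 224.0, GRID, 0.0, 0)
        fit = fd.fit_powerlaw(df)
        assert fit.degenerate
        assert fit.exponent == 0.0
        assert np.isnan(fit.T_s)

    def test_noisy_mean_exponent_recovery(self):
        exps = [fd.fit_powerlaw(
            fd.generate_powerlaw_series(20.0, 0.36, 224.0, GRID, 0.01, s)).exponent
            for s in range(40)]
        assert abs(np.mean(exps) - 0.36) < 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fd.fit_powerlaw([(240.0, 1.0), (250.0, 0.9), (260.0, 0.8)])


class TestExclusionScan:
    def test_pure_power_law_not_flagged(self):
        df = fd.generate_powerlaw_series(20.0, 0.36, 224.0, GRID, 0.005, 3)
        scan = fd.exclusion_scan(df, 2)
        assert not scan.deviation_flagged

    def test_saturating_bend_flagged(self):
        """A Widom-like bend below the lowest temperatures breaks the
        power law there; excluding the lowest point improves R²."""
        df = fd.generate_powerlaw_series(20.0, 0.36, 224.0, GRID, 0.0, 0)
        df.loc[df["T"] < 236.0, "value"] *= 0.75  # saturate toward a maximum
        scan = fd.exclusion_scan(df, 2)
        assert scan.deviation_flagged
        assert scan.table["R_squared"].iloc[1] > scan.table["R_squared"].iloc[0]

    def test_zero_exclusion_identical_to_plain_fit(self):
        df = fd.generate_powerlaw_series(20.0, 0.36, 224.0, GRID, 0.01, 5)
        scan = fd.exclusion_scan(df, 0)
        fit = fd.fit_powerlaw(df)
        assert scan.table.loc[0, "R_squared"] == pytest.approx(fit.R_squared, rel=1e-12)
        assert scan.table.loc[0, "exponent"] == pytest.approx(fit.exponent, rel=1e-9)

    def test_excluding_too_many_rejected(self):
        df = fd.generate_powerlaw_series(20.0, 0.36, 224.0, GRID[:6], 0.0, 0)
        with pytest.raises(InsufficientDataError):
            fd.exclusion_scan(df, 3)


class TestExponentRatio:
    def test_ising_exponents_give_half(self):
        fit_nu = PowerLawFit(1.0, 0.6, 220.0, 1.0, {"exponent": 0.01}, "xi")
        fit_gamma = PowerLawFit(1.0, 1.2, 220.0, 1.0, {"exponent": 0.01}, "kappa")
        ratio, err = fd.exponent_ratio(fit_nu, fit_gamma)
        assert ratio == pytest.approx(0.5, rel=1e-12)
        assert err > 0

    def test_uncertainty_propagation(self):
        fit_nu = PowerLawFit(1.0, 0.26, 221.0, 1.0, {"exponent": 0.1}, "xi")
        fit_gamma = PowerLawFit(1.0, 0.36, 224.0, 1.0, {"exponent": 0.02}, "kappa")
        ratio, err = fd.exponent_ratio(fit_nu, fit_gamma)
        assert ratio == pytest.approx(0.26 / 0.36, rel=1e-12)
        expected = ratio * np.sqrt((0.1 / 0.26) ** 2 + (0.02 / 0.36) ** 2)
        assert err == pytest.approx(expected, rel=1e-12)
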