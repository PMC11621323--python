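"""g(r), windowed Fourier transform, peak fitting and WAXS observables."""

import numpy as np
import pytest

import fluctuodyn as fd
from fluctuodyn.datatypes import Configuration, RadialDistributionFunction, StructureFactorCurve
from fluctuodyn.errors import (
    FitFailureError,
    IncompatibleGridsError,
    InsufficientDataError,
    InvalidParameterError,
)
from fluctuodyn.structure import window_function


class TestComputeRDF:
    def test_two_particles_single_bin(self):
        cfg = Configuration([100.0] * 3, [[0, 0, 0], [5, 0, 0]], ["O", "O"])
        rdf = fd.compute_rdf(cfg, bin_width=0.1)
        nonzero = np.nonzero(rdf.g_values)[0]
        assert len(nonzero) == 1
        assert rdf.r_centers[nonzero[0]] == pytest.approx(5.0, abs=0.1)

    def test_diamond_lattice_first_peak(self):
        cfg = fd.generate_water_like(512, 1.0, jitter=0.0, seed=0)
        rdf = fd.compute_rdf(cfg)
        first = np.nonzero(rdf.g_values)[0][0]
        assert rdf.r_centers[first] == pytest.approx(2.75, abs=0.02)

    def test_hydrogen_excluded_by_default(self):
        pos = [[0, 0, 0], [5, 0, 0], [1, 0, 0]]
        cfg = Configuration([100.0] * 3, pos, ["O", "O", "H"])
        rdf = fd.compute_rdf(cfg, bin_width=0.1)
        assert np.count_nonzero(rdf.g_values) == 1  # only the O-O pair

    def test_density_and_rmax_recorded(self, ideal_gas_config):
        rdf = fd.compute_rdf(ideal_gas_config)
        assert rdf.r_max == pytest.approx(15.0)
        assert rdf.number_density == pytest.approx(1000 / 30.0 ** 3)

    def test_single_particle_rejected(self):
        cfg = Configuration([10.0] * 3, [[0, 0, 0], [1, 1, 1]], ["O", "H"])
        with pytest.raises(InsufficientDataError):
            fd.compute_rdf(cfg)


class TestWindowFunction:
    def test_boundary_values(self):
        assert window_function(0.0, 10.0) == 1.0
        assert window_function(10.0, 10.0) == 0.0
        assert window_function(12.0, 10.0) == 0.0

    def test_branch_join_value_two_thirds(self):
        r_max = 9.0
        r_join = r_max / 3
        left = 1 - 3 * (r_join / r_max) ** 2
        right = 1.5 * (1 - 2 * r_join / r_max + (r_join / r_max) ** 2)
        assert left == pytest.approx(2 / 3)
        assert right == pytest.approx(2 / 3)
        assert window_function(r_join, r_max) == pytest.approx(2 / 3, abs=1e-12)

    def test_continuity_on_dense_grid(self):
        r_max = 7.3
        r = np.linspace(0, r_max, 200001)
        w = window_function(r, r_max)
        assert np.max(np.abs(np.diff(w))) < 1e-4  # no jumps at branch joins
        jump = np.abs(np.diff(window_function(
            np.array([r_max / 3 - 1e-10, r_max / 3 + 1e-10]), r_max)))
        assert jump < 1e-9

    def test_negative_r_rejected(self):
        with pytest.raises(InvalidParameterError):
            window_function(-0.1, 10.0)


class TestRdfToStructureFactor:
    def test_uniform_g_gives_unity(self):
        r = np.arange(0.01, 15.0, 0.02)
        rdf = RadialDistributionFunction(r, np.ones_like(r), 0.03, 15.0)
        sq = fd.rdf_to_structure_factor(rdf, [0.5, 1.0, 2.0])
        assert np.allclose(sq.S, 1.0, atol=1e-14)

    def test_single_bin_closed_form(self):
        r = np.arange(0.01, 15.0, 0.02)
        g = np.ones_like(r)
        i0 = 200  # interior bin
        g[i0] = 2.0
        rho = 0.03
        rdf = RadialDistributionFunction(r, g, rho, 15.0)
        q = 1.3
        sq = fd.rdf_to_structure_factor(rdf, [q])
        r0, dr = r[i0], 0.02
        expected = 1 + 4 * np.pi * rho * window_function(r0, 15.0) * r0 * dr \
            * np.sin(q * r0) / q
        assert sq.S[0] == pytest.approx(expected, rel=1e-12)

    def test_linear_in_g_minus_one(self):
        r = np.arange(0.01, 10.0, 0.02)
        rng = np.random.default_rng(0)
        h = rng.uniform(0, 0.2, r.size)
        q = np.linspace(0.3, 2.0, 7)
        s1 = fd.rdf_to_structure_factor(
            RadialDistributionFunction(r, 1 + h, 0.03, 10.0), q).S
        s2 = fd.rdf_to_structure_factor(
            RadialDistributionFunction(r, 1 + 2 * h, 0.03, 10.0), q).S
        assert np.allclose(s2 - 1, 2 * (s1 - 1), rtol=1e-10)

    def test_zero_q_rejected(self):
        r = np.arange(0.01, 10.0, 0.02)
        rdf = RadialDistributionFunction(r, np.ones_like(r), 0.03, 10.0)
        with pytest.raises(InvalidParameterError):
            fd.rdf_to_structure_factor(rdf, [0.0, 0.5])

    def test_hard_sphere_small_q_matches_py_compressibility(self, hard_sphere_config):
        """Sampling-limited agreement (15%) of pipeline S(q→0) with the
        closed-form Percus-Yevick value at packing fraction 0.2."""
        curves = []
        for seed in range(8):
            cfg = fd.generate_hard_sphere(229, 30.0, 1.78, seed=seed)
            rdf = fd.compute_rdf(cfg)
            curves.append(fd.rdf_to_structure_factor(rdf, [0.21]).S[0])
        s0_py = fd.percus_yevick_s0(0.2)
        assert np.mean(curves) == pytest.approx(s0_py, rel=0.15)


class TestFirstPeakFit:
    @staticmethod
    def _gaussian_curve(center, noise=0.0, slope=0.0, seed=0):
        q = np.linspace(1.6, 2.1, 120)
        rng = np.random.default_rng(seed)
        S = 1.0 + slope * (q - 1.8) + 1.5 * np.exp(-0.5 * ((q - center) / 0.08) ** 2)
        S = S + noise * rng.standard_normal(q.size)
        return StructureFactorCurve(q, S)

    def test_exact_gaussian_round_trip(self):
        peak = fd.fit_first_peak(self._gaussian_curve(1.80), window=(1.7, 1.9))
        assert peak.q1 == pytest.approx(1.80, abs=1e-6)
        assert peak.q1_stderr < 1e-6

    def test_noisy_peak_with_background_recovered(self):
        errors = []
        for seed in range(30):
            curve = self._gaussian_curve(1.75, noise=0.015, slope=0.3, seed=seed)
            peak = fd.fit_first_peak(curve, window=(1.65, 1.9))
            errors.append(abs(peak.q1 - 1.75))
        assert np.median(errors) < 0.01

    def test_monotone_curve_raises_fit_failure(self):
        q = np.linspace(1.7, 1.9, 40)
        curve = StructureFactorCurve(q, 1.0 + 0.5 * q)
        with pytest.raises(FitFailureError):
            fd.fit_first_peak(curve, window=(1.7, 1.9))

    def test_baseline_shift_invariance(self):
        curve = self._gaussian_curve(1.82, noise=0.005, seed=4)
        shifted = StructureFactorCurve(curve.q, curve.S + 2.5)
        p1 = fd.fit_first_peak(curve, window=(1.7, 1.95))
        p2 = fd.fit_first_peak(shifted, window=(1.7, 1.95))
        assert p1.q1 == pytest.approx(p2.q1, abs=1e-9)


class TestDerivativeMaximum:
    def test_tanh_inflection_located(self):
        T = np.linspace(210, 290, 17)
        T0 = 241.0
        q1 = 1.9 - 0.1 * np.tanh((T - T0) / 12.0)
        # dq1/dT is most negative at T0; the rate of change |dq1/dT| peaks
        # there, so feed -q1 whose derivative has its maximum at T0
        res = fd.q1_derivative_maximum(list(zip(T, -q1)))
        assert res.unique
        assert res.T_max == pytest.approx(T0, abs=1.0)

    def test_linear_series_flagged_non_unique(self):
        T = np.linspace(220, 280, 7)
        with pytest.warns(UserWarning):
            res = fd.q1_derivative_maximum(list(zip(T, 1.7 + 0.001 * T)))
        assert not res.unique

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fd.q1_derivative_maximum([(230, 1.8), (240, 1.81), (250, 1.82)])


class TestIsosbestic:
    @staticmethod
    def _family(q_iso, n=5, noise=0.0, seed=0):
        q = np.arange(0.2, 1.0, 0.01)
        rng = np.random.default_rng(seed)
        curves = []
        for i, T in enumerate(np.linspace(230, 290, n)):
            S = 0.1 + 0.05 * q + (T - 260.0) * 0.002 * (q - q_iso)
            S = S + noise * rng.standard_normal(q.size)
            curves.append(StructureFactorCurve(q, S, temperature=T))
        return curves

    def test_constructed_crossing_found(self):
        res = fd.find_isosbestic(self._family(0.5))
        assert res.unique
        assert res.q_iso == pytest.approx(0.5, abs=0.011)

    def test_identical_curves_flagged(self):
        q = np.arange(0.2, 1.0, 0.01)
        curves = [StructureFactorCurve(q, 0.1 + 0.05 * q) for _ in range(4)]
        with pytest.warns(UserWarning):
            res = fd.find_isosbestic(curves)
        assert not res.unique

    def test_noisy_crossing_within_one_grid_step(self):
        res = fd.find_isosbestic(self._family(0.45, n=9, noise=2e-4, seed=3))
        assert res.q_iso == pytest.approx(0.45, abs=0.011)

    def test_disjoint_ranges_rejected(self):
        q_lo = np.arange(0.2, 0.5, 0.01)
        q_hi = np.arange(0.6, 0.9, 0.01)
        c1 = StructureFactorCurve(q_lo, np.ones_like(q_lo))
        c2 = StructureFactorCurve(q_hi, np.ones_like(q_hi))
        c3 = StructureFactorCurve(q_hi, np.ones_like(q_hi))
        with pytest.raises(IncompatibleGridsError):
            fd.find_isosbestic([c1, c2, c3])


def test_ideal_gas_structure_factor_is_unity(ideal_gas_config):
    """Homogeneous uncorrelated configurations have S(q) = 1 at every q
    within sampling error."""
    frames = [fd.generate_ideal_gas(1000, 30.0, seed=s) for s in range(10)]
    q = np.arange(0.3, 3.0, 0.15)
    stack = np.vstack([
        fd.rdf_to_structure_factor(fd.compute_rdf(c), q).S for c in frames
    ])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    assert np.all(np.abs(mean - 1.0) < 3 * np.maximum(sem, 1e-3))
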