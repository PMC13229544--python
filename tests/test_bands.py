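import numpy as np
import pytest

from doseresp import synthetic as syn
from doseresp.bands import (
    BandConfig,
    _BandSolver,
    band_limits,
    confidence_band,
    estimate_nu,
    fixed_multipliers,
)
from doseresp.rkhs import ExposureScaler, SobolevBasis, padded_scaler
from doseresp.testing import TestConfig, flat_null_test


@pytest.fixture(scope="module")
def cubic_test(sample_cubic_small, oracle_q_cubic, oracle_g):
    return flat_null_test(
        sample_cubic_small, None,
        TestConfig(kappa=syn.oracle_kappa(), M=1000, seed=4),
        qfit=oracle_q_cubic, gfit=oracle_g,
    )


class TestEstimateNu:
    def test_scales_quadratically(self, sample_cubic_small, oracle_q_cubic,
                                  oracle_g, cubic_test):
        # J is quadratically homogeneous in the curve amplitude
        basis = SobolevBasis(D=20)
        s = sample_cubic_small
        a01 = padded_scaler(s.exposure_bounds).transform(s.A)
        nu = estimate_nu(s, oracle_q_cubic, oracle_g, basis, a01,
                         test=cubic_test)
        assert nu > 0

        class ScaledQ:
            df = 0.0
            def predict_matrix(self, W, a):
                return 3.0 * oracle_q_cubic.predict_matrix(W, a)

        s3 = syn.ObservedSample(W=s.W, A=s.A, Y=3.0 * s.Y,
                                exposure_bounds=s.exposure_bounds)
        test3 = flat_null_test(
            s3, None, TestConfig(kappa=syn.oracle_kappa(), M=200, seed=4),
            qfit=ScaledQ(), gfit=oracle_g,
        )
        nu3 = estimate_nu(s3, ScaledQ(), oracle_g, basis, a01, test=test3)
        # CV refits, so allow slack around the exact factor 9
        assert 4.0 < nu3 / nu < 20.0

    def test_large_sample_below_oracle(self, oracle_q_cubic, oracle_g):
        # the adaptive radius undershoots the quadrature value (smoothing
        # bias), which is what degrades adaptive-band coverage
        s = syn.generate_dataset(syn.DgpSpec("cubic_alt", 4000, 55))
        basis = SobolevBasis(D=20)
        a01 = padded_scaler(s.exposure_bounds).transform(s.A)
        res = flat_null_test(
            s, None, TestConfig(kappa=syn.oracle_kappa(), M=200, seed=0),
            qfit=oracle_q_cubic, gfit=oracle_g,
        )
        nu = estimate_nu(s, oracle_q_cubic, oracle_g, basis, a01, test=res)
        assert 10.0 < nu < syn.oracle_nu() * 2


class TestFixedMultipliers:
    def test_order_statistic_convention(self, cubic_test):
        l1, l2, t = fixed_multipliers(cubic_test, alpha=0.05)
        draws = np.sort(cubic_test.draws)
        assert t == draws[int(np.ceil(0.95 * draws.size)) - 1]
        assert l1 > 0 and l2 >= 0

    def test_quantile_monotone_in_alpha(self, cubic_test):
        _, _, t05 = fixed_multipliers(cubic_test, alpha=0.05)
        _, _, t20 = fixed_multipliers(cubic_test, alpha=0.20)
        assert t20 <= t05


class TestBandLimits:
    def _solver(self, cubic_test, nu, t_star):
        l1, l2, _ = fixed_multipliers(cubic_test)
        return _BandSolver(cubic_test.U, cubic_test.V, cubic_test.Gamma,
                           l1, l2, nu, t_star)

    def test_huge_threshold_gives_cauchy_schwarz_box(self, cubic_test):
        # test constraint inactive: limits are the nu-ball extremes
        nu = syn.oracle_nu()
        solver = self._solver(cubic_test, nu, t_star=1e9)
        rng = np.random.default_rng(0)
        b = rng.standard_normal(20)
        (lo, hi), _ = band_limits(b, cubic_test.U, cubic_test.V,
                                  cubic_test.Gamma, 1.0, 0.0, nu, 1e9,
                                  solver=solver)
        gamma = SobolevBasis(D=20).gamma
        box = np.sqrt(nu * np.sum(gamma * b**2))
        assert hi == pytest.approx(box, rel=1e-6)
        assert lo == pytest.approx(-box, rel=1e-6)

    def test_tiny_nu_pins_limits_to_zero(self, cubic_test):
        l1, l2, t = fixed_multipliers(cubic_test)
        solver = self._solver(cubic_test, nu=1e-12, t_star=1e9)
        b = np.ones(20)
        (lo, hi), _ = band_limits(b, cubic_test.U, cubic_test.V,
                                  cubic_test.Gamma, l1, 0.0, 1e-12, 1e9,
                                  solver=solver)
        assert abs(lo) < 1e-4 and abs(hi) < 1e-4

    def test_monotone_in_nu_and_threshold(self, cubic_test):
        l1, l2, t = fixed_multipliers(cubic_test)
        rng = np.random.default_rng(1)
        b = rng.standard_normal(20)
        widths = []
        for nu_mult, t_mult in [(1.0, 1.0), (2.0, 1.0), (2.0, 2.0)]:
            solver = self._solver(cubic_test, syn.oracle_nu() * nu_mult,
                                  t * t_mult)
            (lo, hi), _ = band_limits(b, cubic_test.U, cubic_test.V,
                                      cubic_test.Gamma, l1, l2,
                                      syn.oracle_nu() * nu_mult, t * t_mult,
                                      solver=solver)
            widths.append(hi - lo)
        assert widths[0] <= widths[1] * (1 + 1e-6)
        assert widths[1] <= widths[2] * (1 + 1e-6)

    def test_dual_solution_matches_generic_solver(self, cubic_test):
        # independent check of the KKT solver against SLSQP with analytic
        # gradients from multiple starting points
        from scipy.optimize import minimize

        l1, l2, t = fixed_multipliers(cubic_test)
        nu = syn.oracle_nu()
        solver = self._solver(cubic_test, nu, t)
        rng = np.random.default_rng(2)
        for trial in range(3):
            b = rng.standard_normal(20)
            (lo, hi), _ = band_limits(b, cubic_test.U, cubic_test.V,
                                      cubic_test.Gamma, l1, l2, nu, t,
                                      solver=solver)
            for sense, ours in ((+1, hi), (-1, lo)):
                bb = sense * b
                best = -np.inf
                for x0 in (solver.min_stat_over_ball()[1], np.zeros(20)):
                    res = minimize(
                        lambda c: -bb @ c, x0, jac=lambda c: -bb,
                        method="SLSQP",
                        constraints=[
                            {"type": "ineq",
                             "fun": lambda c: nu - solver.rough_value(c),
                             "jac": lambda c: -2 * solver.gamma_inv * c},
                            {"type": "ineq",
                             "fun": lambda c: solver.s - solver.stat_value(c),
                             "jac": lambda c: -2 * solver.P @ (c - solver.c0)},
                        ],
                        options={"maxiter": 500, "ftol": 1e-12},
                    )
                    if (solver.rough_value(res.x) <= nu * 1.00001
                            and solver.stat_value(res.x) <= solver.s * 1.00001):
                        best = max(best, -res.fun)
                assert sense * ours == pytest.approx(best, rel=1e-5, abs=1e-8)


class TestConfidenceBand:
    def test_end_to_end_and_self_consistency(self, sample_cubic_small,
                                             oracle_q_cubic, oracle_g, cubic_test):
        band = confidence_band(
            sample_cubic_small,
            grid=np.linspace(-1, 1, 20),
            alpha=0.05,
            config=BandConfig(nu=syn.oracle_nu()),
            test=cubic_test,
        )
        assert not np.any(band.failed_points)
        assert np.all(band.lower <= band.upper + 1e-9)
        # the band covers most of the true centered curve at oracle tuning
        truth = syn.true_theta_centered(band.grid, "cubic_alt")
        assert np.mean(band.contains(truth)) > 0.8

    def test_width_shrinks_with_n(self, oracle_q_cubic, oracle_g):
        widths = []
        for n in (200, 800):
            s = syn.generate_dataset(syn.DgpSpec("cubic_alt", n, 67))
            band = confidence_band(
                s, grid=np.linspace(-0.9, 0.9, 10), alpha=0.05,
                config=BandConfig(
                    test=TestConfig(kappa=syn.oracle_kappa(), M=500, seed=1),
                    nu=syn.oracle_nu(),
                ),
                qfit=oracle_q_cubic, gfit=oracle_g,
            )
            widths.append(np.median(band.width))
        assert widths[1] < widths[0]
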