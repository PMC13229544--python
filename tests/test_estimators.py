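import numpy as np
import pytest

from doseresp import synthetic as syn
from doseresp.estimators import (
    DiscreteDistribution,
    EstimatorWorkspace,
    Zn_weights,
    estimate_eif,
    one_step_psi,
    plugin_psi,
    plugin_theta,
    tmle_psi,
    tmle_update,
)
from doseresp.rkhs import (
    padded_scaler,
    ExposureScaler,
    FunctionClass,
    SobolevBasis,
    evaluate_basis,
    gram_matrices,
)
from doseresp.testing import solve_sup


@pytest.fixture(scope="module")
def setup_cubic(sample_cubic_small, oracle_q_cubic, oracle_g):
    s = sample_cubic_small
    basis = SobolevBasis(D=20)
    a01 = padded_scaler(s.exposure_bounds).transform(s.A)
    H = evaluate_basis(basis, a01)
    V, Gamma = gram_matrices(basis, a01)
    ws = EstimatorWorkspace(s, oracle_q_cubic, oracle_g)
    return s, basis, H, V, Gamma, ws


class TestPluginTheta:
    def test_constant_regression(self, sample_flat_small):
        class ConstQ:
            df = 0.0
            def predict_matrix(self, W, a):
                return np.full((np.atleast_2d(W).shape[0], len(np.atleast_1d(a))), 2.5)

        th = plugin_theta(ConstQ(), sample_flat_small)
        np.testing.assert_allclose(th(np.linspace(-1, 1, 5)), 2.5)

    def test_oracle_flat_setting_near_zero(self, sample_flat_small, oracle_q_flat):
        th = plugin_theta(oracle_q_flat, sample_flat_small)
        vals = th(np.linspace(-1, 1, 9))
        # theta_n(a) = -mean(zeta(W_i)) (1 - a^2): bounded by sampling noise
        assert np.max(np.abs(vals)) < 4 * 0.95 / np.sqrt(sample_flat_small.n)


class TestPluginPsi:
    def test_zero_contrast(self, setup_cubic):
        _, _, H, *_ = setup_cubic
        np.testing.assert_allclose(plugin_psi(np.ones(300), np.ones(300), H), 0.0)

    def test_constant_test_function_maps_to_zero(self, setup_cubic, rng):
        s, _, H, *_ = setup_cubic
        Hconst = np.ones((s.n, 1))
        theta = rng.standard_normal(s.n)
        assert plugin_psi(theta, np.zeros(s.n), Hconst)[0] == pytest.approx(0.0)

    def test_matches_population_inner_product(self):
        # oracle curve in place of the plug-in at large n vs quadrature
        s = syn.generate_dataset(syn.DgpSpec("cubic_alt", 60000, 31))
        basis = SobolevBasis(D=6)
        a01 = padded_scaler(s.exposure_bounds).transform(s.A)
        H = evaluate_basis(basis, a01)
        theta = syn.true_theta(s.A, "cubic_alt")
        U = plugin_psi(theta, np.zeros(s.n), H)
        # population value: marginal of A is uniform(−1,1) for this DGP
        x, wq = np.polynomial.legendre.leggauss(300)
        Hq = evaluate_basis(basis, padded_scaler(s.exposure_bounds).transform(x))
        thq = syn.true_theta(x, "cubic_alt")
        thq = thq - np.sum(wq / 2 * thq)
        pop = (wq / 2 * thq) @ Hq
        np.testing.assert_allclose(U, pop, atol=0.02)


class TestZnWeights:
    def test_centered_columns_without_weighting(self, setup_cubic):
        s, _, H, _, _, ws = setup_cubic
        Z = Zn_weights(s, None, H, weights=np.ones(s.n))
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)

    def test_hand_computed_toy(self):
        # direct elementwise evaluation on a 5-row toy sample
        class ToyG:
            floor = 0.0
            def predict_matrix(self, a, W):
                a = np.atleast_1d(a)
                W = np.atleast_2d(W)
                return 0.5 + 0.1 * np.outer(a, W[:, 0])

        s = syn.ObservedSample(
            W=np.arange(10).reshape(5, 2) / 10.0,
            A=np.array([-0.5, -0.25, 0.0, 0.25, 0.5]),
            Y=np.zeros(5),
            exposure_bounds=(-1, 1),
        )
        H = np.column_stack([s.A, s.A**2])
        G = ToyG().predict_matrix(s.A, s.W)
        w_hand = G.mean(axis=1) / np.diag(G)
        Z_hand = w_hand[:, None] * (H - H.mean(axis=0))
        np.testing.assert_allclose(Zn_weights(s, ToyG(), H), Z_hand)


class TestOneStep:
    def test_equals_plugin_when_residuals_vanish(self, setup_cubic):
        s, _, H, _, _, ws = setup_cubic

        class PerfectQ:
            df = 0.0
            def predict_matrix(self, W, a):
                return ws.qfit.predict_matrix(W, a)

        s_perfect = syn.ObservedSample(
            W=s.W, A=s.A, Y=np.diag(ws.Qcross), exposure_bounds=s.exposure_bounds
        )
        ws2 = EstimatorWorkspace(s_perfect, ws.qfit, ws.gfit)
        psi = one_step_psi(s_perfect, ws.qfit, ws.gfit, None, H, workspace=ws2)
        U_plug = plugin_psi(ws2.theta_at_A, np.zeros(s.n), H)
        np.testing.assert_allclose(psi.U, U_plug, atol=1e-12)

    def test_linear_in_h(self, setup_cubic):
        s, _, H, _, _, ws = setup_cubic
        U1 = one_step_psi(s, ws.qfit, ws.gfit, None, H, workspace=ws).U
        U2 = one_step_psi(s, ws.qfit, ws.gfit, None, 2.0 * H, workspace=ws).U
        np.testing.assert_allclose(U2, 2.0 * U1, rtol=1e-10)

    def test_root_n_unbiased_under_null(self, oracle_q_flat, oracle_g):
        # CLT check: sqrt(n) U_d has mean within MC error of 0, per basis fn
        D = 8
        basis = SobolevBasis(D=D)
        reps, n = 150, 500
        Us = np.empty((reps, D))
        for rep in range(reps):
            s = syn.generate_dataset(syn.DgpSpec("flat_null", n, 7000 + rep))
            a01 = padded_scaler(s.exposure_bounds).transform(s.A)
            H = evaluate_basis(basis, a01)
            Us[rep] = one_step_psi(s, oracle_q_flat, oracle_g, None, H).U
        z = np.sqrt(n) * Us.mean(axis=0) / (np.sqrt(n) * Us.std(axis=0) / np.sqrt(reps))
        assert np.max(np.abs(z)) < 4.0


class TestEifEstimate:
    def test_column_means_match_centering_identity(self, setup_cubic):
        # algebraic identity: mean Phi = plugin contrast + E_n[theta_n h]
        s, _, H, _, _, ws = setup_cubic
        Hc = H - H.mean(axis=0)
        Phi = estimate_eif(s, ws.qfit, ws.gfit, None, H,
                           use_theta_hat_for_null=False, workspace=ws)
        expected = plugin_psi(ws.theta_at_A, np.zeros(s.n), H) + (
            ws.theta_at_A @ Hc
        ) / s.n
        np.testing.assert_allclose(Phi.mean(axis=0), expected, atol=1e-10)

    def test_flag_removes_candidate_null(self, setup_cubic):
        s, _, H, _, _, ws = setup_cubic
        Phi1 = estimate_eif(s, ws.qfit, ws.gfit, None, H, True, workspace=ws)
        Phi2 = estimate_eif(s, ws.qfit, ws.gfit,
                            lambda a: np.sin(a), H, True, workspace=ws)
        np.testing.assert_array_equal(Phi1, Phi2)

    def test_gateaux_derivative_oracle(self, rng):
        # finite-difference pathwise derivative vs the analytic influence
        # value on a discrete distribution: resolves the formula's grouping
        w = np.repeat([-0.3, 0.7], 4)
        a = np.tile([-0.6, 0.4], 4)
        y = rng.normal(size=8)
        p = rng.dirichlet(np.ones(8) * 3)
        P = DiscreteDistribution(w, a, y, p)
        h = lambda av: np.cos(2 * av) + 0.5 * av
        tstar = lambda av: 0.2 * av**2
        t = 1e-4
        for idx in range(8):
            fd = (
                P.mix_with_pointmass(idx, t).psi(h, tstar)
                - P.mix_with_pointmass(idx, -t).psi(h, tstar)
            ) / (2 * t)
            an = P.eif(w[idx], a[idx], y[idx], h, tstar)
            assert abs(fd - an) < 1e-4

    def test_discrete_eif_mean_zero(self, rng):
        w = np.repeat([0.0, 1.0], 3)
        a = np.tile([-0.5, 0.0, 0.5], 2)
        y = rng.normal(size=6)
        p = rng.dirichlet(np.ones(6) * 2)
        P = DiscreteDistribution(w, a, y, p)
        h = lambda av: av**3
        mean_eif = sum(
            pi * P.eif(wi, ai, yi, h) for wi, ai, yi, pi in zip(w, a, y, p)
        )
        assert abs(mean_eif) < 1e-12


class TestTmle:
    def test_zero_steps_when_already_orthogonal(self, setup_cubic):
        s, basis, H, V, Gamma, ws = setup_cubic

        class ZeroResidQ:
            df = 0.0
            def predict_matrix(self, W, a):
                return ws.qfit.predict_matrix(W, a)

        s0 = syn.ObservedSample(W=s.W, A=s.A, Y=np.diag(ws.Qcross),
                                exposure_bounds=s.exposure_bounds)
        ws0 = EstimatorWorkspace(s0, ws.qfit, ws.gfit)
        fclass = FunctionClass(basis, syn.oracle_kappa(), V, Gamma)
        state = tmle_update(s0, ws.qfit, ws.gfit, fclass, workspace=ws0)
        assert state.steps_taken == 0
        psi0 = tmle_psi(s0, ws.qfit, ws.gfit, state, None, H, workspace=ws0)
        np.testing.assert_allclose(
            psi0.U, plugin_psi(ws0.theta_at_A, np.zeros(s.n), H), atol=1e-12
        )

    def test_estimating_equation_solved_and_loss_monotone(self, setup_cubic):
        s, basis, H, V, Gamma, ws = setup_cubic
        fclass = FunctionClass(basis, syn.oracle_kappa(), V, Gamma)
        state = tmle_update(s, ws.qfit, ws.gfit, fclass, workspace=ws)
        assert state.steps_taken > 0
        # re-solve the constrained program at the final state
        Hc = H - H.mean(axis=0)
        Z = ws.weights[:, None] * Hc
        sol = solve_sup(Z.T @ state.resid / s.n, V, Gamma, fclass.kappa)
        assert sol.statistic <= state.threshold * (1 + 1e-8)
        assert np.all(np.diff(state.loss_path) <= 1e-12)

    def test_tml_curve_finite_on_grid(self, setup_cubic):
        s, basis, H, V, Gamma, ws = setup_cubic
        fclass = FunctionClass(basis, syn.oracle_kappa(), V, Gamma)
        state = tmle_update(s, ws.qfit, ws.gfit, fclass, workspace=ws)
        psi = tmle_psi(s, ws.qfit, ws.gfit, state, None, H, workspace=ws)
        vals = psi.theta_hat(np.linspace(-1, 1, 21))
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(vals)) < np.max(np.abs(s.Y)) * 2

    def test_one_step_agreement_shrinks_with_n(self, oracle_g):
        # first-order agreement measured over the function class: the TML
        # update solves the estimating equation over H_kappa only, so the
        # sqrt(n)-scaled disagreement sup_{h in H_kappa} |psi_I(h) - psi_II(h)|
        # decreases across n (at the {log n}^{-1/2} stopping-rule rate)
        gaps = []
        q = syn.OracleOutcomeRegression("cubic_alt")
        basis = SobolevBasis(D=20)
        for n in (250, 2000):
            med = []
            for rep in range(12):
                s = syn.generate_dataset(syn.DgpSpec("cubic_alt", n, 900 + rep))
                a01 = padded_scaler(s.exposure_bounds).transform(s.A)
                H = evaluate_basis(basis, a01)
                V, Gamma = gram_matrices(basis, a01)
                ws = EstimatorWorkspace(s, q, oracle_g)
                fclass = FunctionClass(basis, syn.oracle_kappa(), V, Gamma)
                u1 = one_step_psi(s, q, oracle_g, None, H, workspace=ws).U
                state = tmle_update(s, q, oracle_g, fclass, workspace=ws)
                u2 = tmle_psi(s, q, oracle_g, state, None, H, workspace=ws).U
                gap = solve_sup(u1 - u2, V, Gamma, fclass.kappa).statistic
                med.append(np.sqrt(n) * gap)
            gaps.append(np.median(med))
        assert gaps[1] < gaps[0]
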