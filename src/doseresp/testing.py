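"""Supremum statistic over the Sobolev function class, multiplier-bootstrap
calibration, and the end-to-end flat-null test.

The statistic is ``Psi_n = max { U' c : c' V c = 1, c' Gamma c <= kappa }``
where U collects the per-basis-function estimates.  The KKT conditions give
``c = lambda1^{-1} (V + lambda2 Gamma)^{-1} U`` with ``lambda2`` solving a
scalar ratio equation; after simultaneous diagonalization of the pencil
(V, Gamma) the equation involves only scalar sums, so the root-find (and
its vectorization across bootstrap draws) is cheap.

An optional indicator-function class (the step functions ``1(a <= a0)``
over a cutoff grid, in the style of primitive-function tests) shares the
bootstrap machinery; its supremum is a maximum over the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

from .nuisance import LearnerConfig, fit_conditional_density, fit_outcome_regression, select_bandwidth
from .rkhs import (
    DEFAULT_KAPPA_FALLBACK,
    ExposureScaler,
    FunctionClass,
    SobolevBasis,
    estimate_kappa,
    evaluate_basis,
    fit_penalized_projection,
    gram_matrices,
    padded_scaler,
    pseudo_outcome,
)

__all__ = [
    "SupSolution",
    "TestResult",
    "TestConfig",
    "solve_sup",
    "sup_bruteforce",
    "PencilSolver",
    "multiplier_bootstrap",
    "flat_null_test",
]


@dataclass
class SupSolution:
    """Solution of the constrained maximization of U'c."""

    statistic: float
    c: np.ndarray
    lambda1: float
    lambda2: float


@dataclass
class TestConfig:
    """Configuration for the flat-null test pipeline."""

    __test__ = False  # not a pytest class despite the name

    estimator: str = "one_step"  # "one_step" | "tmle"
    kappa: float | str = "adaptive"  # numeric oracle value or "adaptive"
    D: int = 20
    M: int = 1000
    alpha: float = 0.05
    seed: int = 0
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    hclass: str = "sobolev"  # "sobolev" | "indicator"
    indicator_grid: int = 50
    use_theta_hat_for_null: bool = True
    tmle_eps_frac: float = 1e-3
    tmle_max_steps: int = 5000


@dataclass
class TestResult:
    """Outcome of the flat-null (or general candidate-null) test."""

    __test__ = False  # not a pytest class despite the name

    statistic: float
    p_value: float
    M: int
    draws: np.ndarray
    seed: int
    kappa_used: float | None
    estimator_kind: str
    alpha: float
    # pipeline artifacts retained for band construction and diagnostics
    sup: SupSolution | None = None
    U: np.ndarray | None = None
    Phi: np.ndarray | None = None
    V: np.ndarray | None = None
    Gamma: np.ndarray | None = None
    basis: SobolevBasis | None = None
    scaler: ExposureScaler | None = None
    h_matrix: np.ndarray | None = None
    qfit: object = None
    gfit: object = None
    workspace: object = None
    psi: object = None

    def reject(self, alpha: float | None = None) -> bool:
        return self.p_value <= (self.alpha if alpha is None else alpha)


class PencilSolver:
    """Simultaneous diagonalization of (V, Gamma) for fast repeated solves.

    With ``Gamma = diag(1/gamma)`` positive, let ``S = Gamma^{-1/2} V
    Gamma^{-1/2} = Q L Q'``.  For ``u = Q' Gamma^{-1/2} U`` the KKT ratio
    equation becomes ``R(l2) = sum(u^2/(L+l2)^2) / sum(L u^2/(L+l2)^2) =
    kappa``, which is decreasing in ``l2``; everything reduces to scalar
    sums over the eigenvalues.
    """

    def __init__(self, V: np.ndarray, Gamma: np.ndarray, kappa: float):
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        gamma_inv = np.diag(Gamma)
        if np.any(gamma_inv <= 0):
            raise ValueError("Gamma must have positive diagonal")
        self.kappa = float(kappa)
        self.ghalf = 1.0 / np.sqrt(gamma_inv)  # Gamma^{-1/2} diagonal
        S = (self.ghalf[:, None] * V) * self.ghalf[None, :]
        lam, Q = np.linalg.eigh((S + S.T) / 2.0)
        self.lam = np.maximum(lam, 0.0)
        self.Q = Q
        self.lam_max = float(self.lam.max())
        if self.lam_max <= 0:
            raise ValueError("V is zero; degenerate exposure distribution")
        # smallest achievable roughness-to-variance ratio over directions
        self.min_ratio = 1.0 / self.lam_max
        if self.kappa < self.min_ratio * (1.0 - 1e-10):
            raise ValueError(
                f"kappa={kappa:.4g} below the minimal roughness ratio "
                f"{self.min_ratio:.4g}; the function class is empty"
            )

    def _transform(self, U: np.ndarray) -> np.ndarray:
        return self.Q.T @ (self.ghalf * U)

    def _ratio(self, u2: np.ndarray, s) -> np.ndarray:
        """Roughness-to-variance ratio along the stationary path.

        Candidate directions are ``b(s) prop (L + s I)^{-1} u`` in the
        Gamma-whitened eigenbasis; ``s > 0`` is the KKT multiplier ratio of
        the printed solution, ``s < -lam_max`` its continuation where the
        variance multiplier changes sign (needed when kappa is small).
        """
        denom = (self.lam[:, None] + np.atleast_1d(s)[None, :]) ** 2
        u2 = u2[:, None] if u2.ndim == 1 else u2
        N = np.sum(u2 / denom, axis=0)
        D = np.sum(self.lam[:, None] * u2 / denom, axis=0)
        return N / D

    def _solution_at(self, u: np.ndarray, s: float) -> SupSolution:
        denom = self.lam + s
        b = u / denom
        var = float(np.sum(self.lam * b**2))
        b /= np.sqrt(var)
        val = float(u @ b)
        if val < 0:
            b = -b
            val = -val
        c = self.ghalf * (self.Q @ b)
        return SupSolution(val, c, float(np.sqrt(var)), float(s))

    def solve(self, U: np.ndarray) -> SupSolution:
        U = np.asarray(U, float)
        D = U.size
        if not np.any(U):
            return SupSolution(0.0, np.zeros(D), 0.0, 0.0)
        u = self._transform(U)
        u2 = u**2
        lam = self.lam
        pos = lam > 1e-13 * self.lam_max
        # roughness ratio of the variance-only maximizer (s -> 0 limit)
        if np.all(pos) or not np.any(u2[~pos] > 0):
            r0 = float(np.sum(u2[pos] / lam[pos] ** 2) / np.sum(u2[pos] / lam[pos]))
        else:
            r0 = np.inf
        if r0 <= self.kappa:
            # roughness bound inactive: statistic sqrt(U' V^+ U)
            lam1 = float(np.sqrt(np.sum(u2[pos] / lam[pos])))
            b = np.zeros(D)
            b[pos] = u[pos] / lam[pos]
            c = self.ghalf * (self.Q @ b) / lam1
            return SupSolution(lam1, c, lam1, 0.0)

        from scipy.optimize import brentq

        scale = self.lam_max
        r_u = float(np.sum(u2) / np.sum(lam * u2))  # ratio in the u direction
        if self.kappa >= r_u:
            # printed branch: s > 0, ratio decreasing from r0 to r_u
            f = lambda x: float(self._ratio(u2, scale * 10.0**x)[0]) - self.kappa
            lo, hi = -14.0, 14.0
            while f(hi) > 0 and hi < 40:
                hi += 6.0
            x = brentq(f, lo, hi, xtol=1e-13, rtol=1e-15)
            return self._solution_at(u, scale * 10.0**x)
        # continuation branch: s < -lam_max, ratio increasing from the
        # minimal ratio (at s -> -lam_max) to r_u (at s -> -inf)
        g = lambda x: float(self._ratio(u2, -self.lam_max - scale * 10.0**x)[0]) - self.kappa
        lo, hi = -13.0, 13.0
        if g(lo) > 0 or g(hi) < 0:
            raise RuntimeError(
                f"kappa={self.kappa:.6g} not bracketed on the continuation "
                f"branch (limits {g(lo) + self.kappa:.6g}, {g(hi) + self.kappa:.6g})"
            )
        x = brentq(g, lo, hi, xtol=1e-13, rtol=1e-15)
        return self._solution_at(u, -self.lam_max - scale * 10.0**x)

    def statistics(self, U_matrix: np.ndarray, iters: int = 70) -> np.ndarray:
        """Vectorized statistics for many U columns (bootstrap draws).

        Bisection on the stationary-path parameter runs simultaneously for
        all columns, separately on the printed branch and its small-kappa
        continuation; columns whose variance-only solution already
        satisfies the roughness bound use the closed form.
        """
        U_matrix = np.asarray(U_matrix, float)
        u = self.Q.T @ (self.ghalf[:, None] * U_matrix)
        u2 = u**2
        lam = self.lam
        M = u2.shape[1]
        stats = np.zeros(M)
        nonzero = u2.sum(axis=0) > 0
        pos = lam > 1e-13 * self.lam_max
        lam_pos = lam[pos][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            r0 = np.sum(u2[pos] / lam_pos**2, axis=0) / np.sum(
                u2[pos] / lam_pos, axis=0
            )
            if not np.all(pos):
                r0 = np.where(np.any(u2[~pos] > 0, axis=0), np.inf, r0)
        inactive = nonzero & (r0 <= self.kappa)
        if np.any(inactive):
            stats[inactive] = np.sqrt(
                np.sum(u2[np.ix_(pos, inactive)] / lam_pos, axis=0)
            )
        active = nonzero & ~inactive
        if not np.any(active):
            return stats
        r_u = np.sum(u2[:, active], axis=0) / np.sum(lam[:, None] * u2[:, active], axis=0)
        scale = self.lam_max
        for branch, mask_b in (("A", self.kappa >= r_u), ("B", self.kappa < r_u)):
            cols = np.nonzero(active)[0][mask_b]
            if cols.size == 0:
                continue
            ub = u2[:, cols]
            lo = np.full(cols.size, -14.0)
            hi = np.full(cols.size, 30.0 if branch == "A" else 13.0)
            for _ in range(iters):
                mid = (lo + hi) / 2.0
                s = scale * 10.0**mid if branch == "A" else -self.lam_max - scale * 10.0**mid
                ratio = self._ratio(ub, s)
                move_up = ratio > self.kappa if branch == "A" else ratio < self.kappa
                lo = np.where(move_up, mid, lo)
                hi = np.where(move_up, hi, mid)
            mid = (lo + hi) / 2.0
            s = scale * 10.0**mid if branch == "A" else -self.lam_max - scale * 10.0**mid
            denom = lam[:, None] + s[None, :]
            lam1 = np.sqrt(np.sum(lam[:, None] * ub / denom**2, axis=0))
            stats[cols] = np.abs(np.sum(ub / denom, axis=0)) / lam1
        return stats


def solve_sup(U, V, Gamma, kappa) -> SupSolution:
    """Maximize U'c over {c'Vc = 1, c'Gamma c <= kappa} via the KKT form."""
    return PencilSolver(np.asarray(V, float), np.asarray(Gamma, float), kappa).solve(
        np.asarray(U, float)
    )


def sup_bruteforce(U, V, Gamma, kappa, budget: int = 4000, seed: int = 0) -> float:
    """Independent oracle for :func:`solve_sup` (small D only).

    Whitens by V and sweeps the stationary mixture parameter of candidate
    directions ``x(mu) prop (I + mu S)^{-1} u`` over dense grids covering
    both the ``mu >= 0`` range and its sign-flipped continuation, keeping
    the best feasible candidate and refining feasibility crossings; the
    winner is polished with SLSQP restarts.  Deterministic given budget
    and seed.
    """
    from scipy.optimize import minimize

    U = np.asarray(U, float)
    V = np.asarray(V, float)
    Gamma = np.asarray(Gamma, float)
    if U.size > 8:
        raise ValueError("brute force limited to D <= 8")
    if not np.any(U):
        return 0.0
    evals, evecs = np.linalg.eigh((V + V.T) / 2.0)
    if np.any(evals <= 0):
        raise ValueError("V must be positive definite for the brute force")
    Vih = evecs @ np.diag(evals**-0.5) @ evecs.T  # V^{-1/2}
    u = Vih @ U
    S = Vih @ Gamma @ Vih
    Se, SQ = np.linalg.eigh((S + S.T) / 2.0)
    ut = SQ.T @ u
    s_min = float(Se.min())

    def candidate(mu):
        denom = 1.0 + mu * Se
        if np.any(np.abs(denom) < 1e-300):
            return None
        x = ut / denom
        nrm = np.linalg.norm(x)
        if nrm == 0:
            return None
        x = x / nrm
        if float(x @ (Se * x)) <= kappa * (1.0 + 1e-9):
            return abs(float(ut @ x))
        return None

    span = np.geomspace(1e-10, 1e10, budget // 2) / s_min
    mus = np.concatenate([[0.0], span, -1.0 / s_min - span])
    best = -np.inf
    feas = np.zeros(mus.size, bool)
    for i, mu in enumerate(mus):
        val = candidate(mu)
        feas[i] = val is not None
        if val is not None and val > best:
            best = val
    half = 1 + span.size  # refine within each branch separately
    for seg in (slice(0, half), slice(half, None)):
        fm, mm = feas[seg], mus[seg]
        for idx in np.nonzero(fm[1:] != fm[:-1])[0]:
            lo, hi = mm[idx], mm[idx + 1]
            for _ in range(80):
                mid = (lo + hi) / 2.0
                val = candidate(mid)
                if val is None:
                    lo = mid
                else:
                    hi = mid
                    best = max(best, val)

    # SLSQP polish in the whitened sphere coordinates, multiple starts
    rng = np.random.default_rng(seed)
    starts = [ut / np.linalg.norm(ut)]
    kmin = Se.argmin()
    e0 = np.zeros_like(ut)
    e0[kmin] = 1.0
    starts.append(e0)
    starts.extend(rng.standard_normal((6, ut.size)))
    for x0 in starts:
        x0 = x0 / np.linalg.norm(x0)
        if float(x0 @ (Se * x0)) > kappa:
            # shrink toward the smoothest direction until feasible
            for t in np.linspace(0.05, 1.0, 20):
                cand = (1 - t) * x0 + t * np.sign(x0[kmin] or 1.0) * e0
                cand /= np.linalg.norm(cand)
                if float(cand @ (Se * cand)) <= kappa:
                    x0 = cand
                    break
        res = minimize(
            lambda x: -(ut @ x),
            x0,
            jac=lambda x: -ut,
            method="SLSQP",
            constraints=[
                {"type": "eq", "fun": lambda x: x @ x - 1.0, "jac": lambda x: 2 * x},
                {
                    "type": "ineq",
                    "fun": lambda x: kappa - x @ (Se * x),
                    "jac": lambda x: -2 * Se * x,
                },
            ],
            options={"maxiter": 200, "ftol": 1e-14},
        )
        if res.success:
            x = res.x / np.linalg.norm(res.x)
            if float(x @ (Se * x)) <= kappa * (1.0 + 1e-8):
                best = max(best, abs(float(ut @ x)))
    return best


def multiplier_bootstrap(Phi, V, Gamma, kappa, M: int, seed) -> np.ndarray:
    """Multiplier-bootstrap draws of the supremum statistic.

    Draw m uses i.i.d. standard normal multipliers ``xi``, forms
    ``U^(m)_d = n^{-1} sum_i (xi_i - xi-bar) Phi[i, d]`` and solves the same
    constrained maximization as the statistic.
    """
    if M < 100:
        raise ValueError("use at least 100 bootstrap draws")
    Phi = np.asarray(Phi, float)
    n = Phi.shape[0]
    rng = np.random.default_rng(seed)
    solver = PencilSolver(np.asarray(V, float), np.asarray(Gamma, float), kappa)
    draws = np.empty(M)
    # chunked so the multiplier matrix stays small
    done = 0
    while done < M:
        m = min(M - done, 500)
        Xi = rng.standard_normal((n, m))
        Xi -= Xi.mean(axis=0)
        Umat = Phi.T @ Xi / n
        draws[done : done + m] = solver.statistics(Umat)
        done += m
    return draws


def _indicator_matrix(A: np.ndarray, n_cut: int) -> np.ndarray:
    cuts = np.quantile(A, np.linspace(0.0, 1.0, n_cut + 2)[1:-1])
    return (A[:, None] <= cuts[None, :]).astype(float)


def flat_null_test(
    sample,
    theta_star=None,
    config: TestConfig | None = None,
    qfit=None,
    gfit=None,
) -> TestResult:
    """End-to-end test of H0: centered dose-response curve == theta-bar*.

    Fits (or accepts injected) nuisances, builds the basis and the function
    class, estimates the inner products with the configured estimator,
    calibrates by multiplier bootstrap, and returns the statistic with its
    bootstrap p-value ``M^{-1} #{draws > statistic}``.
    """
    from .estimators import EstimatorWorkspace, one_step_psi, tmle_psi, tmle_update

    config = config or TestConfig()
    rng = np.random.default_rng(config.seed)

    if qfit is None:
        qfit = fit_outcome_regression(sample, config.learner)
    if gfit is None:
        r = config.learner.density_bandwidth
        if r is None:
            r = select_bandwidth(sample, folds=config.learner.cv_folds,
                                 seed=config.seed)
        gfit = fit_conditional_density(sample, r, config.learner)

    ws = EstimatorWorkspace(sample, qfit, gfit)
    scaler = padded_scaler(sample.exposure_bounds)
    a01 = scaler.transform(sample.A)

    if config.hclass == "indicator":
        if config.estimator != "one_step":
            raise ValueError("indicator class supports the one-step estimator only")
        H = _indicator_matrix(sample.A, config.indicator_grid)
        psi = one_step_psi(sample, qfit, gfit, theta_star, H,
                           config.use_theta_hat_for_null, workspace=ws)
        stat = float(np.max(np.abs(psi.U)))
        n = sample.n
        draws = np.empty(config.M)
        done = 0
        boot_rng = np.random.default_rng(config.seed + 1)
        while done < config.M:
            m = min(config.M - done, 500)
            Xi = boot_rng.standard_normal((n, m))
            Xi -= Xi.mean(axis=0)
            draws[done : done + m] = np.max(np.abs(psi.Phi.T @ Xi / n), axis=0)
            done += m
        p = float(np.mean(draws > stat))
        return TestResult(
            statistic=stat, p_value=p, M=config.M, draws=draws,
            seed=config.seed, kappa_used=None, estimator_kind="one_step",
            alpha=config.alpha, U=psi.U, Phi=psi.Phi, h_matrix=H,
            scaler=scaler, qfit=qfit, gfit=gfit, workspace=ws, psi=psi,
        )

    basis = SobolevBasis(D=config.D)
    H = evaluate_basis(basis, a01)
    V, Gamma = gram_matrices(basis, a01)

    if config.kappa == "adaptive":
        f = pseudo_outcome(sample, qfit, gfit, theta_star)
        coef, _ = fit_penalized_projection(f, basis, a01, seed=config.seed)
        try:
            kappa, _ = estimate_kappa(coef, basis, V)
        except ValueError:
            kappa = DEFAULT_KAPPA_FALLBACK
        kappa = max(kappa, DEFAULT_KAPPA_FALLBACK)
    else:
        kappa = float(config.kappa)

    fclass = FunctionClass(basis=basis, kappa=kappa, V=V, Gamma=Gamma)

    if config.estimator == "one_step":
        psi = one_step_psi(sample, qfit, gfit, theta_star, H,
                           config.use_theta_hat_for_null, workspace=ws)
    elif config.estimator == "tmle":
        state = tmle_update(sample, qfit, gfit, fclass,
                            eps_frac=config.tmle_eps_frac,
                            max_steps=config.tmle_max_steps, workspace=ws,
                            h_matrix=H)
        psi = tmle_psi(sample, qfit, gfit, state, theta_star, H,
                       config.use_theta_hat_for_null, workspace=ws)
    else:
        raise ValueError(f"unknown estimator {config.estimator!r}")

    sol = solve_sup(psi.U, V, Gamma, kappa)
    draws = multiplier_bootstrap(psi.Phi, V, Gamma, kappa, config.M,
                                 seed=config.seed + 1)
    p = float(np.mean(draws > sol.statistic))
    log.debug(
        "flat_null_test: Q=%s, g bandwidth=%.4g, kappa=%.4g, lambda2=%.4g, "
        "statistic=%.4g, p=%.4g",
        getattr(qfit, "training_meta", "injected"),
        getattr(gfit, "bandwidth", float("nan")), kappa, sol.lambda2,
        sol.statistic, p,
    )
    return TestResult(
        statistic=sol.statistic, p_value=p, M=config.M, draws=draws,
        seed=config.seed, kappa_used=kappa, estimator_kind=config.estimator,
        alpha=config.alpha, sup=sol, U=psi.U, Phi=psi.Phi, V=V, Gamma=Gamma,
        basis=basis, scaler=scaler, h_matrix=H, qfit=qfit, gfit=gfit,
        workspace=ws, psi=psi,
    )
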