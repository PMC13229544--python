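"""Estimation of the inner-product functionals psi(h) = E[(theta-bar -
theta-bar*)(A) h(A)] for a panel of test functions h, together with the
estimated efficient influence function (EIF).

Three estimator kinds are provided:

* plug-in -- evaluates the empirical inner product at the plug-in curve
  ``theta_n(a) = n^{-1} sum_i Q_n(W_i, a)``; retains first-order bias.
* one-step -- plug-in plus the empirical mean of the estimated EIF, which
  removes the first-order bias (doubly robust in (Q, g)).
* TML -- iteratively fluctuates the outcome regression along a universal
  least favorable submodel until the EIF estimating equation is solved to
  within an ``{n log n}^{-1/2}``-scaled threshold, then plugs in.

The per-observation EIF estimates feed the multiplier bootstrap.  All
estimators are linear in h, so estimates for ``h = sum_d c_d eta_d`` are
``U' c`` with ``U`` the vector of per-basis-function estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .nuisance import density_ratio_weights

__all__ = [
    "PsiEstimate",
    "TmleState",
    "EstimatorWorkspace",
    "plugin_theta",
    "plugin_psi",
    "Zn_weights",
    "one_step_psi",
    "estimate_eif",
    "tmle_update",
    "tmle_psi",
    "DiscreteDistribution",
]


@dataclass
class PsiEstimate:
    """Vector of estimated inner products with influence-function matrix.

    ``U[d]`` estimates psi(eta_d); ``Phi[i, d]`` is the estimated influence
    value of observation i on coordinate d; ``theta_hat`` evaluates the
    estimator's dose-response curve (plug-in or TML-updated).
    """

    U: np.ndarray
    kind: Literal["plugin", "one_step", "tmle"]
    Phi: np.ndarray | None = None
    theta_hat: Callable | None = None


@dataclass
class TmleState:
    """State of the targeted update of the outcome regression."""

    coef_sum: np.ndarray  # eps * sum_b c_b; the accumulated fluctuation
    resid: np.ndarray  # Y_i - Q-tilde(W_i, A_i)
    steps_taken: int
    step_size: float
    final_derivative: float
    threshold: float
    loss_path: np.ndarray


class EstimatorWorkspace:
    """Precomputed nuisance evaluations shared by all estimators.

    Builds the cross matrices ``Q(W_i, A_j)`` and ``g(A_i | W_j)`` once;
    everything downstream (plug-in curve, density-ratio weights, EIF terms,
    TML fluctuation geometry) is linear algebra on them.
    """

    def __init__(self, sample, qfit, gfit):
        self.sample = sample
        self.qfit = qfit
        self.gfit = gfit
        n = sample.n
        self.Qcross = qfit.predict_matrix(sample.W, sample.A)  # Q(W_i, A_j)
        self.Qii = np.ascontiguousarray(np.diag(self.Qcross))
        self.G = gfit.predict_matrix(sample.A, sample.W)  # g(A_i | W_j)
        self.num = self.G.mean(axis=1)  # n^{-1} sum_j g(A_i | W_j)
        self.weights = self.num / np.diag(self.G)
        self.theta_at_A = self.Qcross.mean(axis=0)  # theta_n(A_j)
        self.resid = sample.Y - self.Qii
        # rho(A_i) = num_i * n^{-1} sum_j 1 / g(A_i | W_j): the sample-mean
        # factor of Z_n at the sample points, used by the TML plug-in curve
        self.rho = self.num * np.mean(1.0 / self.G, axis=1)
        self.n = n

    def theta_star_at_A(self, theta_star) -> np.ndarray:
        if theta_star is None:
            return np.zeros(self.n)
        return np.asarray(theta_star(self.sample.A), float)


def plugin_theta(qfit, sample) -> Callable:
    """Plug-in dose-response curve ``a -> n^{-1} sum_i Q(W_i, a)``."""

    def theta_n(a):
        return qfit.predict_matrix(sample.W, np.atleast_1d(a)).mean(axis=0)

    return theta_n


def plugin_psi(theta_at_A, theta_star_at_A, h_matrix) -> np.ndarray:
    """Plug-in inner products for each column of ``h_matrix``.

    ``U_d = n^{-1} sum_i [contrast_i - mean(contrast)] h_d(A_i)`` with
    ``contrast = theta_n(A) - theta*(A)``.  Constant test-function columns
    map to zero by the centering.
    """
    contrast = np.asarray(theta_at_A, float) - np.asarray(theta_star_at_A, float)
    contrast = contrast - contrast.mean()
    return contrast @ np.asarray(h_matrix, float) / contrast.size


def Zn_weights(sample, gfit, h_matrix, weights=None) -> np.ndarray:
    """Matrix ``Z[i, d] = w_i (h_d(A_i) - mean_j h_d(A_j))`` of the
    least-favorable-direction evaluations at the sample."""
    if weights is None:
        weights = density_ratio_weights(gfit, sample)
    H = np.asarray(h_matrix, float)
    return weights[:, None] * (H - H.mean(axis=0))


def _eif_matrix(ws: EstimatorWorkspace, theta_at_A, Qcross, Qii, h_matrix,
                theta_star_at_A, use_theta_hat_for_null: bool) -> np.ndarray:
    """Plug-in EIF estimate, one column per test function.

    Follows the estimating-equation form: the bracket [centered curve
    contrast + density-ratio-weighted residual] times the centered test
    function, plus the ``E[Q(w, A)(h(A) - Eh)]`` term, minus the empirical
    centering of the weighted-residual term.  When
    ``use_theta_hat_for_null`` is set the candidate null is replaced by the
    plug-in curve and the contrast term vanishes, making the matrix free of
    theta* (one bootstrap serves every null hypothesis).
    """
    H = np.asarray(h_matrix, float)
    Hc = H - H.mean(axis=0)
    resid = ws.sample.Y - Qii
    # leverage-style rescaling: in-sample residuals of a fit with d
    # effective degrees of freedom are shrunk by about sqrt(1 - d/n);
    # undo it so the bootstrap does not underestimate the influence scale
    df = float(getattr(ws.qfit, "df", 0.0) or 0.0)
    if 0.0 < df < 0.5 * ws.n:
        resid = resid * np.sqrt(ws.n / (ws.n - df))
    Z = ws.weights[:, None] * Hc
    term2 = (ws.weights * resid)[:, None] * Hc
    term3 = (Qcross @ Hc) / ws.n
    term4 = -(resid @ Z) / ws.n
    Phi = term2 + term3 + term4[None, :]
    if not use_theta_hat_for_null:
        contrast = theta_at_A - theta_star_at_A
        contrast = contrast - contrast.mean()
        Phi = Phi + contrast[:, None] * Hc
    return Phi


def estimate_eif(
    sample,
    qfit,
    gfit,
    theta_star,
    h_matrix,
    use_theta_hat_for_null: bool = True,
    workspace: EstimatorWorkspace | None = None,
) -> np.ndarray:
    """Per-observation estimated EIF values at the initial nuisance fit."""
    ws = workspace or EstimatorWorkspace(sample, qfit, gfit)
    return _eif_matrix(
        ws,
        ws.theta_at_A,
        ws.Qcross,
        ws.Qii,
        h_matrix,
        ws.theta_star_at_A(theta_star),
        use_theta_hat_for_null,
    )


def one_step_psi(
    sample,
    qfit,
    gfit,
    theta_star,
    h_matrix,
    use_theta_hat_for_null: bool = True,
    workspace: EstimatorWorkspace | None = None,
) -> PsiEstimate:
    """One-step estimator: plug-in plus the weighted-residual correction."""
    ws = workspace or EstimatorWorkspace(sample, qfit, gfit)
    H = np.asarray(h_matrix, float)
    Hc = H - H.mean(axis=0)
    ts = ws.theta_star_at_A(theta_star)
    U_plug = plugin_psi(ws.theta_at_A, ts, H)
    Z = ws.weights[:, None] * Hc
    U = U_plug + (ws.resid @ Z) / ws.n
    Phi = _eif_matrix(
        ws, ws.theta_at_A, ws.Qcross, ws.Qii, H, ts, use_theta_hat_for_null
    )
    return PsiEstimate(
        U=U, kind="one_step", Phi=Phi, theta_hat=plugin_theta(qfit, sample)
    )


def tmle_update(
    sample,
    qfit,
    gfit,
    fclass,
    eps_frac: float = 1e-3,
    max_steps: int = 5000,
    hn_coef=None,
    workspace: EstimatorWorkspace | None = None,
    h_matrix=None,
) -> TmleState:
    """Fluctuate Q along the universal least favorable submodel.

    Each step adds ``eps * Z(.,.; h*)`` to Q, where ``h*`` maximizes the
    estimating-equation value over the function class (solved in
    coefficient space by the same KKT machinery as the test statistic).
    Iteration stops once the absolute derivative of the squared-error loss
    falls below ``{n log n}^{-1/2} sd_n((Y - Q)(W,A) Z(W,A; h_n))``, with
    ``h_n`` the estimated least-orthogonal direction (the first step's
    maximizer when no adaptive estimate is supplied).  A loss increase
    triggers a retry with ``eps / 10``.
    """
    from .testing import solve_sup

    ws = workspace or EstimatorWorkspace(sample, qfit, gfit)
    basis = fclass.basis
    from .rkhs import evaluate_basis, padded_scaler

    if h_matrix is None:
        a01 = padded_scaler(sample.exposure_bounds).transform(sample.A)
        h_matrix = evaluate_basis(basis, a01)
    H = np.asarray(h_matrix, float)
    Hc = H - H.mean(axis=0)
    Z = ws.weights[:, None] * Hc
    n = ws.n

    r = ws.resid.copy()
    eps = eps_frac * float(np.std(sample.Y))
    if eps <= 0:
        eps = eps_frac

    sol0 = solve_sup(Z.T @ r / n, fclass.V, fclass.Gamma, fclass.kappa)
    if hn_coef is None:
        hn_coef = sol0.c
    thresh = float(
        np.std(r * (Z @ np.asarray(hn_coef, float)), ddof=0)
        / np.sqrt(n * np.log(max(n, 3)))
    )

    coef_sum = np.zeros(basis.D)
    losses = [float(np.mean(r**2))]
    deriv = sol0.statistic
    sol = sol0
    steps = 0
    while steps < max_steps:
        deriv = sol.statistic
        if deriv <= thresh:
            break
        step_dir = Z @ sol.c
        while True:
            r_new = r - eps * step_dir
            loss_new = float(np.mean(r_new**2))
            if loss_new <= losses[-1] + 1e-12:
                break
            eps /= 10.0
            if eps < 1e-12:
                raise RuntimeError("TML step size underflow; loss not decreasing")
        r = r_new
        coef_sum += eps * sol.c
        losses.append(loss_new)
        steps += 1
        sol = solve_sup(Z.T @ r / n, fclass.V, fclass.Gamma, fclass.kappa)
    else:
        raise RuntimeError(
            f"TML update did not converge in {max_steps} steps "
            f"(derivative {deriv:.3g} > threshold {thresh:.3g})"
        )
    deriv = sol.statistic

    return TmleState(
        coef_sum=coef_sum,
        resid=r,
        steps_taken=steps,
        step_size=eps,
        final_derivative=float(deriv),
        threshold=thresh,
        loss_path=np.asarray(losses),
    )


def tmle_psi(
    sample,
    qfit,
    gfit,
    state: TmleState,
    theta_star,
    h_matrix,
    use_theta_hat_for_null: bool = True,
    workspace: EstimatorWorkspace | None = None,
) -> PsiEstimate:
    """Plug-in at the targeted fit, with the EIF evaluated there too."""
    ws = workspace or EstimatorWorkspace(sample, qfit, gfit)
    H = np.asarray(h_matrix, float)
    Hc = H - H.mean(axis=0)
    s = Hc @ state.coef_sum  # accumulated fluctuation at the sample points

    theta_tilde_at_A = ws.theta_at_A + ws.rho * s
    Qii_t = sample.Y - state.resid
    # Q-tilde(W_i, A_j) = Q(W_i, A_j) + Z_n(W_i, A_j; accumulated h)
    Qcross_t = ws.Qcross + (ws.num / ws.G.T) * s[None, :]

    ts = ws.theta_star_at_A(theta_star)
    U = plugin_psi(theta_tilde_at_A, ts, H)
    Phi = _eif_matrix(ws, theta_tilde_at_A, Qcross_t, Qii_t, H, ts,
                      use_theta_hat_for_null)

    from .rkhs import evaluate_basis, padded_scaler

    scaler = padded_scaler(sample.exposure_bounds)
    h_mean = H.mean(axis=0)
    base_theta = plugin_theta(qfit, sample)
    from .rkhs import SobolevBasis

    fclass_basis = SobolevBasis(D=H.shape[1])

    def theta_tilde(a):
        a = np.atleast_1d(np.asarray(a, float))
        Gm = gfit.predict_matrix(a, sample.W)  # (len(a), n)
        rho_a = Gm.mean(axis=1) * np.mean(1.0 / Gm, axis=1)
        Ha = evaluate_basis(fclass_basis, scaler.transform(a)) - h_mean
        return base_theta(a) + rho_a * (Ha @ state.coef_sum)

    return PsiEstimate(U=U, kind="tmle", Phi=Phi, theta_hat=theta_tilde)


# ---------------------------------------------------------------------------
# Exact functionals on a discrete distribution (derivative oracle seam)
# ---------------------------------------------------------------------------


@dataclass
class DiscreteDistribution:
    """A joint distribution on finitely many (w, a, y) support points.

    Supports exact evaluation of psi and of the analytic EIF, so the
    pathwise (Gateaux) derivative of psi along point-mass mixtures can be
    checked by finite differences.  Requires every (w, a) combination to
    have positive probability so conditionals are defined.
    """

    w: np.ndarray
    a: np.ndarray
    y: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float).ravel()
        self.a = np.asarray(self.a, float).ravel()
        self.y = np.asarray(self.y, float).ravel()
        self.p = np.asarray(self.p, float).ravel()
        if not (self.w.size == self.a.size == self.y.size == self.p.size):
            raise ValueError("support arrays must share a length")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to one")
        wu, au = np.unique(self.w), np.unique(self.a)
        joint = np.zeros((wu.size, au.size))
        for wi, ai, pi in zip(self.w, self.a, self.p):
            joint[np.searchsorted(wu, wi), np.searchsorted(au, ai)] += pi
        if np.any(joint <= 0):
            raise ValueError("every (w, a) combination needs positive mass")
        self._wu, self._au, self._joint_wa = wu, au, joint

    def _tables(self):
        wu, au, joint = self._wu, self._au, self._joint_wa
        pW = joint.sum(axis=1)
        pA = joint.sum(axis=0)
        Qnum = np.zeros_like(joint)
        for wi, ai, yi, pi in zip(self.w, self.a, self.y, self.p):
            Qnum[np.searchsorted(wu, wi), np.searchsorted(au, ai)] += pi * yi
        Q = Qnum / joint
        g = joint / pW[:, None]  # g(a | w)
        theta = pW @ Q  # theta(a) on au
        return pW, pA, Q, g, theta

    def psi(self, h, theta_star=None) -> float:
        """Exact psi(h) = E[(theta-bar - theta-bar*)(A) h(A)]."""
        _, pA, _, _, theta = self._tables()
        au = self._au
        hst = np.zeros_like(au) if theta_star is None else np.asarray(
            theta_star(au), float
        )
        tbar = theta - pA @ theta
        tsbar = hst - pA @ hst
        hv = np.asarray(h(au), float)
        return float(pA @ ((tbar - tsbar) * hv))

    def eif(self, w0, a0, y0, h, theta_star=None) -> float:
        """Analytic EIF at the point (w0, a0, y0)."""
        pW, pA, Q, g, theta = self._tables()
        wu, au = self._wu, self._au
        iw, ia = np.searchsorted(wu, w0), np.searchsorted(au, a0)
        hv = np.asarray(h(au), float)
        hst = np.zeros_like(au) if theta_star is None else np.asarray(
            theta_star(au), float
        )
        Eh = float(pA @ hv)
        tbar = theta - pA @ theta
        tsbar = hst - pA @ hst
        ratio = float(pW @ g[:, ia]) / g[iw, ia]
        bracket = tbar[ia] - tsbar[ia] + ratio * (y0 - Q[iw, ia])
        termQ = float(pA @ (Q[iw, :] * (hv - Eh)))
        return float(
            bracket * (hv[ia] - Eh)
            + termQ
            - 2.0 * float(pA @ (tbar * hv))
            + float(pA @ (tsbar * hv))
        )

    def mix_with_pointmass(self, idx: int, t: float) -> "DiscreteDistribution":
        """The mixture (1 - t) P + t * delta_{o_idx} (t may be negative)."""
        p = self.p * (1.0 - t)
        p[idx] += t
        return DiscreteDistribution(self.w, self.a, self.y, p)
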