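"""Second-order Sobolev eigenbasis, roughness functional, and the
data-adaptive roughness bound for the test's function class.

The test maximizes estimated inner products over the class

    H_kappa = { h = sum_d c_d eta_d : J(h) <= kappa, Var_n(h(A)) = 1 },

where ``eta_d`` are the eigenfunctions of the second-order Sobolev RKHS on
[0, 1] (Fourier pairs ``sqrt(2) cos(2 pi d u)``, ``sqrt(2) sin(2 pi d u)``
with eigenvalues ``gamma = (2 pi d)^{-4}``) and ``J(h) = sum_d c_d^2 /
gamma_d`` is the RKHS roughness.  Exposures are affinely rescaled onto
[0, 1] before basis evaluation.

``kappa`` can be supplied (oracle mode) or estimated from the data by
projecting a doubly robust pseudo-outcome onto the basis with a
generalized-ridge penalty ``lambda J`` and applying the one-standard-error
cross-validation rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SobolevBasis",
    "FunctionClass",
    "ExposureScaler",
    "BASIS_PADDING",
    "padded_scaler",
    "evaluate_basis",
    "gram_matrices",
    "roughness",
    "pseudo_outcome",
    "fit_penalized_projection",
    "estimate_kappa",
    "DEFAULT_KAPPA_FALLBACK",
]

#: roughness of the smoothest nonconstant eigenfunction, (2 pi)^4; used as
#: the fallback kappa when an adaptive fit is flat
DEFAULT_KAPPA_FALLBACK = float((2.0 * np.pi) ** 4)

#: fraction of the exposure range added on each side before rescaling to
#: [0, 1].  The Fourier eigenbasis is periodic, so mapping the observed
#: support exactly onto [0, 1] would force every candidate function to take
#: the same value at both ends of the support; padding moves the periodic
#: identification outside the data range.
BASIS_PADDING = 0.15


def padded_scaler(bounds, padding: float = BASIS_PADDING) -> "ExposureScaler":
    """Scaler mapping the padded exposure range onto [0, 1]."""
    lo, hi = bounds
    pad = padding * (hi - lo)
    return ExposureScaler(lo - pad, hi + pad)


@dataclass(frozen=True)
class ExposureScaler:
    """Invertible affine map from the observed exposure range onto [0, 1]."""

    a_min: float
    a_max: float

    def __post_init__(self) -> None:
        if not self.a_min < self.a_max:
            raise ValueError("require a_min < a_max")

    def transform(self, a):
        return (np.asarray(a, float) - self.a_min) / (self.a_max - self.a_min)

    def inverse(self, u):
        return self.a_min + np.asarray(u, float) * (self.a_max - self.a_min)


@dataclass(frozen=True)
class SobolevBasis:
    """Truncated eigenbasis of the second-order Sobolev RKHS on [0, 1]."""

    D: int = 20

    def __post_init__(self) -> None:
        if self.D < 2 or self.D % 2 != 0:
            raise ValueError("D must be a positive even integer")

    @property
    def gamma(self) -> np.ndarray:
        d = np.repeat(np.arange(1, self.D // 2 + 1), 2)
        return (2.0 * np.pi * d) ** (-4.0)

    def __call__(self, a01):
        return evaluate_basis(self, a01)


def evaluate_basis(basis: SobolevBasis, a01) -> np.ndarray:
    """Evaluate all eigenfunctions at scaled exposures; shape (n, D)."""
    u = np.asarray(a01, dtype=float)
    if np.any(u < -1e-12) or np.any(u > 1.0 + 1e-12):
        raise ValueError("scaled exposures must lie in [0, 1]")
    u = np.atleast_1d(u)
    out = np.empty((u.size, basis.D))
    for d in range(1, basis.D // 2 + 1):
        arg = 2.0 * np.pi * d * u
        out[:, 2 * d - 2] = np.sqrt(2.0) * np.cos(arg)
        out[:, 2 * d - 1] = np.sqrt(2.0) * np.sin(arg)
    return out


def gram_matrices(basis: SobolevBasis, a01) -> tuple[np.ndarray, np.ndarray]:
    """Empirical covariance V of the basis at the sample and penalty Gamma.

    ``V[d, e] = n^{-1} sum_i (eta_d(A_i) - mean)(eta_e(A_i) - mean)`` so that
    ``Var_n(h(A)) = c' V c``; ``Gamma = diag(1 / gamma_d)`` so that
    ``J(h) = c' Gamma c``.  Warns when V is numerically singular.
    """
    H = evaluate_basis(basis, a01)
    n = H.shape[0]
    if n < basis.D:
        raise ValueError("need n >= D observations for the covariance matrix")
    Hc = H - H.mean(axis=0)
    V = (Hc.T @ Hc) / n
    if np.linalg.cond(V) > 1e12:
        import warnings

        warnings.warn("basis covariance matrix V is numerically singular")
    Gamma = np.diag(1.0 / basis.gamma)
    return V, Gamma


def roughness(c, basis: SobolevBasis) -> float:
    """RKHS roughness J(h) = sum_d c_d^2 / gamma_d of h = sum_d c_d eta_d."""
    c = np.asarray(c, float)
    return float(np.sum(c**2 / basis.gamma))


@dataclass
class FunctionClass:
    """The constraint set H_kappa in coefficient space.

    A coefficient vector ``c`` represents a member iff ``c' V c = 1`` and
    ``c' Gamma c <= kappa``.
    """

    basis: SobolevBasis
    kappa: float
    V: np.ndarray
    Gamma: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def is_member(self, c, tol: float = 1e-6) -> bool:
        c = np.asarray(c, float)
        return (
            abs(float(c @ self.V @ c) - 1.0) <= tol
            and float(c @ self.Gamma @ c) <= self.kappa + tol
        )


# ---------------------------------------------------------------------------
# Pseudo-outcome and the adaptive roughness bound
# ---------------------------------------------------------------------------


def pseudo_outcome(sample, qfit, gfit, theta_star=None) -> np.ndarray:
    """Doubly robust pseudo-outcome whose regression on A recovers
    theta0 - theta*.

    ``f_i = n^{-1} sum_j Q(W_j, A_i) + w_i (Y_i - Q(W_i, A_i)) - theta*(A_i)``
    with ``w_i`` the density-ratio weight ``(n^{-1} sum_j g(A_i|W_j)) /
    g(A_i|W_i)``.
    """
    from .nuisance import density_ratio_weights

    n = sample.n
    Qcross = qfit.predict_matrix(sample.W, sample.A)  # Q(W_i, A_j)
    theta_at_A = Qcross.mean(axis=0)
    Qii = np.diag(Qcross) if Qcross.shape[0] == Qcross.shape[1] else qfit.predict(
        sample.W, sample.A
    )
    w = density_ratio_weights(gfit, sample)
    f = theta_at_A + w * (sample.Y - Qii)
    if theta_star is not None:
        f = f - np.asarray(theta_star(sample.A), float)
    return f


def fit_penalized_projection(
    f,
    basis: SobolevBasis,
    a01,
    lambda_grid=None,
    folds: int = 10,
    seed: int = 0,
):
    """Penalized least squares projection of ``f`` onto the eigenbasis.

    Minimizes ``n^{-1} sum_i (f_i - c0 - sum_d c_d eta_d(A_i))^2 +
    lambda J(c)`` -- a generalized ridge with diagonal penalty, solved in
    closed form per candidate lambda.  lambda is chosen by K-fold
    cross-validation with the one-standard-error rule (the largest candidate
    whose CV error is within one SE of the minimum).

    Returns ``(coef, lambda_selected)`` where ``coef = (c0, c1, ..., cD)``.
    """
    f = np.asarray(f, float)
    n = f.size
    H = evaluate_basis(basis, a01)
    B = np.column_stack([np.ones(n), H])
    pen = np.concatenate([[0.0], 1.0 / basis.gamma])  # no penalty on intercept

    if lambda_grid is None:
        scale = max(float(np.var(f)), 1e-12)
        lambda_grid = np.geomspace(1e-6, 1e2, 50) * scale
    lambda_grid = np.sort(np.asarray(lambda_grid, float))
    if lambda_grid.size < 1 or np.any(lambda_grid <= 0):
        raise ValueError("lambda_grid must be positive and nonempty")

    def _solve(Bm, fm, lam):
        G = (Bm.T @ Bm) / Bm.shape[0] + lam * np.diag(pen)
        return np.linalg.solve(G, Bm.T @ fm / Bm.shape[0])

    rng = np.random.default_rng(seed)
    fold_id = rng.permutation(np.arange(n) % folds)
    cv = np.zeros((lambda_grid.size, folds))
    for k in range(folds):
        tr, va = fold_id != k, fold_id == k
        for j, lam in enumerate(lambda_grid):
            c = _solve(B[tr], f[tr], lam)
            resid = f[va] - B[va] @ c
            cv[j, k] = float(np.mean(resid**2))
    mean_cv = cv.mean(axis=1)
    se_cv = cv.std(axis=1, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(mean_cv))
    threshold = mean_cv[j_min] + se_cv[j_min]
    j_sel = int(np.max(np.nonzero(mean_cv <= threshold)[0]))
    lam_sel = float(lambda_grid[j_sel])
    coef = _solve(B, f, lam_sel)
    return coef, lam_sel


def estimate_kappa(coef, basis: SobolevBasis, V: np.ndarray):
    """Adaptive roughness bound and direction from projection coefficients.

    Given the penalized-projection coefficients ``(c0, c)``, standardizes
    the fitted function to unit empirical variance: ``h_n`` has coefficients
    ``c / sqrt(c' V c)`` and ``kappa_n = J(c) / (c' V c)``, so that by
    construction ``J(h_n) = kappa_n`` and ``Var_n(h_n(A)) = 1``.

    Raises ``ValueError`` on a (near-)flat fit; callers fall back to
    ``DEFAULT_KAPPA_FALLBACK``.
    """
    c = np.asarray(coef, float)
    if c.size == basis.D + 1:
        c = c[1:]  # drop intercept
    var = float(c @ V @ c)
    if var <= 1e-12:
        raise ValueError("projection is flat; no adaptive kappa available")
    kappa_n = roughness(c, basis) / var
    h_n = c / np.sqrt(var)
    return kappa_n, h_n
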