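"""Nonparametric nuisance estimation: the outcome regression
``Q0(w, a) = E[Y | W=w, A=a]`` and the conditional exposure density
``g0(a | w)``.

Two learner families are provided behind one contract:

* ``"lasso_hal"`` (default) -- an L1-penalized regression on a zero-order
  spline (indicator) tensor basis over (W, A) with main effects and all
  two-way interactions, penalty chosen by K-fold cross-validation.  This is
  a highly-adaptive-LASSO-style fit whose bounded-variation penalty keeps
  the estimator in a Donsker class.
* ``"ridge_poly"`` -- a fast tensor-polynomial ridge regression intended
  for large Monte-Carlo experiments.

The conditional density is estimated by kernel-smoothed regression: for a
bandwidth ``r`` and each point ``a_j`` of a fixed exposure grid, the
kernel-transformed response ``r^{-1} phi((A_i - a_j)/r)`` is regressed on
``W_i`` under a log link (``phi`` the standard normal density); predictions
interpolate the fitted log-density between grid points and are floored at a
small positive constant.  The bandwidth is selected by cross-validating the
log loss of a marginal kernel density estimate of ``A``.

True nuisances from :mod:`doseresp.synthetic` satisfy the same interface,
which is the injection seam used to validate downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.linear_model import LassoCV, PoissonRegressor, Ridge, RidgeCV

__all__ = [
    "LearnerConfig",
    "QFit",
    "GFit",
    "fit_outcome_regression",
    "select_bandwidth",
    "fit_conditional_density",
    "density_ratio_weights",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class LearnerConfig:
    """Configuration shared by the outcome-regression and density learners."""

    learner: str = "lasso_hal"
    cv_folds: int = 5
    seed: int = 0
    num_knots: int = 10  # knots per dimension for the indicator basis
    density_grid_size: int = 50
    density_floor_frac: float = 1e-3
    density_bandwidth: float | None = None  # None -> select_bandwidth

    def __post_init__(self) -> None:
        if self.learner not in ("lasso_hal", "ridge_poly"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.density_grid_size < 5:
            raise ValueError("density grid needs at least 5 points")


# ---------------------------------------------------------------------------
# feature builders
# ---------------------------------------------------------------------------


def _poly_columns(X: np.ndarray, degree: int) -> np.ndarray:
    """All monomials of the columns of X up to total degree (no constant)."""
    from itertools import combinations_with_replacement

    cols = []
    for deg in range(1, degree + 1):
        for combo in combinations_with_replacement(range(X.shape[1]), deg):
            col = np.ones(X.shape[0])
            for j in combo:
                col = col * X[:, j]
            cols.append(col)
    return np.column_stack(cols)


class _PolyFeatures:
    """Tensor of exposure powers with covariate monomials."""

    def __init__(self, a_degree: int = 3, w_degree: int = 3):
        self.a_degree = a_degree
        self.w_degree = w_degree

    def __call__(self, W: np.ndarray, a: np.ndarray) -> np.ndarray:
        wpoly = np.column_stack(
            [np.ones(W.shape[0]), _poly_columns(W, self.w_degree)]
        )
        apow = np.column_stack([a**p for p in range(self.a_degree + 1)])
        cols = (apow[:, :, None] * wpoly[:, None, :]).reshape(W.shape[0], -1)
        return cols[:, 1:]  # drop the constant (intercept handled by model)


class _IndicatorFeatures:
    """Zero-order spline basis: I(x >= knot) main effects + 2-way products."""

    def __init__(self, knots: list[np.ndarray]):
        self.knots = knots  # one knot vector per input column

    @classmethod
    def from_data(cls, X: np.ndarray, num_knots: int) -> "_IndicatorFeatures":
        qs = np.linspace(0.0, 1.0, num_knots + 2)[1:-1]
        return cls([np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])])

    def __call__(self, X: np.ndarray) -> np.ndarray:
        mains = [
            (X[:, j][:, None] >= self.knots[j][None, :]).astype(float)
            for j in range(X.shape[1])
        ]
        blocks = list(mains)
        for j in range(len(mains)):
            for k in range(j + 1, len(mains)):
                blocks.append(
                    (mains[j][:, :, None] * mains[k][:, None, :]).reshape(
                        X.shape[0], -1
                    )
                )
        return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# outcome regression
# ---------------------------------------------------------------------------


class QFit:
    """Fitted outcome regression with vectorized cross-evaluation.

    ``predict_matrix(W, a_values)`` returns the matrix ``Q(W_i, a_j)``; for
    long exposure vectors the model is evaluated on an internal exposure
    grid and linearly interpolated, which is accurate for the smooth fits
    used here and keeps the n x n evaluations cheap.
    """

    _INTERP_GRID = 101

    def __init__(self, predict_fn, bounds, clip, training_meta: str,
                 df: float = 0.0):
        self._predict_fn = predict_fn  # (W, a_vector) -> predictions
        self._bounds = bounds
        self._clip = clip
        self.training_meta = training_meta
        #: effective degrees of freedom of the fit (0 when unknown); used
        #: downstream for a leverage-style correction of residual scale
        self.df = df

    def predict(self, W, a) -> np.ndarray:
        W = np.atleast_2d(np.asarray(W, float))
        a = np.broadcast_to(np.asarray(a, float), (W.shape[0],))
        return np.clip(self._predict_fn(W, a), *self._clip)

    def predict_matrix(self, W, a_values) -> np.ndarray:
        W = np.atleast_2d(np.asarray(W, float))
        a = np.atleast_1d(np.asarray(a_values, float))
        if a.size <= self._INTERP_GRID:
            out = np.column_stack(
                [self._predict_fn(W, np.full(W.shape[0], aj)) for aj in a]
            )
            return np.clip(out, *self._clip)
        lo = min(self._bounds[0], float(a.min()))
        hi = max(self._bounds[1], float(a.max()))
        grid = np.linspace(lo, hi, self._INTERP_GRID)
        on_grid = np.column_stack(
            [self._predict_fn(W, np.full(W.shape[0], aj)) for aj in grid]
        )
        idx = np.clip(np.searchsorted(grid, a) - 1, 0, grid.size - 2)
        t = (a - grid[idx]) / (grid[idx + 1] - grid[idx])
        out = on_grid[:, idx] * (1.0 - t) + on_grid[:, idx + 1] * t
        return np.clip(out, *self._clip)


def fit_outcome_regression(sample, config: LearnerConfig | None = None) -> QFit:
    """Fit a flexible regression of Y on (W, A).

    Constant outcomes return the constant fit; a constant exposure is an
    error because the continuous-exposure methodology is then undefined.
    Predictions are clipped to the observed outcome range padded by half
    the range on each side.
    """
    config = config or LearnerConfig()
    if sample.n < 20:
        raise ValueError("need at least 20 observations")
    if np.ptp(sample.A) <= 0:
        raise ValueError("exposure is constant; continuous-exposure fit undefined")

    y = sample.Y
    rng_y = float(np.ptp(y))
    clip = (float(y.min()) - 0.5 * rng_y - 1e-12, float(y.max()) + 0.5 * rng_y + 1e-12)

    if rng_y == 0.0:
        c = float(y[0])
        return QFit(
            lambda W, a: np.full(W.shape[0], c),
            sample.exposure_bounds,
            (c, c),
            "constant outcome",
        )

    if config.learner == "ridge_poly":
        feats = _PolyFeatures(a_degree=3, w_degree=3 if sample.W.shape[1] <= 2 else 2)
        X = feats(sample.W, sample.A)
        model = RidgeCV(alphas=np.geomspace(1e-4, 1e2, 13))
        model.fit(X, y)
        meta = f"ridge_poly (alpha={model.alpha_:.3g})"
        sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        df = 1.0 + float(np.sum(sv**2 / (sv**2 + model.alpha_)))

        def predict_fn(W, a, feats=feats, model=model):
            return model.predict(feats(W, a))

    else:  # lasso_hal
        XA = np.column_stack([sample.W, sample.A])
        feats = _IndicatorFeatures.from_data(XA, config.num_knots)
        X = feats(XA)
        model = LassoCV(
            cv=config.cv_folds,
            random_state=config.seed,
            alphas=30,
            max_iter=5000,
        )
        model.fit(X, y)
        meta = f"lasso_hal (alpha={model.alpha_:.3g}, {X.shape[1]} columns)"
        df = 1.0 + float(np.count_nonzero(model.coef_))

        def predict_fn(W, a, feats=feats, model=model):
            return model.predict(feats(np.column_stack([W, a])))

    return QFit(predict_fn, sample.exposure_bounds, clip, meta, df=df)


# ---------------------------------------------------------------------------
# conditional density
# ---------------------------------------------------------------------------


def select_bandwidth(
    sample, folds: int = 5, seed: int = 0, candidates=None
) -> float:
    """Bandwidth minimizing K-fold CV log loss of a marginal Gaussian KDE.

    Candidates form a logarithmic grid around the normal-reference rate
    ``sd(A) n^{-1/5}``.  Because the exposure support is bounded, the KDE
    used for selection applies a reflection boundary correction (data
    mirrored at both support endpoints); without it the log-loss criterion
    degenerates toward zero bandwidth for densities that are positive at
    the boundary.
    """
    A = sample.A
    n = A.size
    if n < 20:
        raise ValueError("need at least 20 observations")
    lo, hi = sample.exposure_bounds
    if candidates is None:
        # capped at 1.5x the normal-reference rate: the density enters the
        # estimators through ratio weights, where oversmoothing in the
        # exposure direction attenuates the confounding correction, while
        # undersmoothing only adds variance that the density floor controls
        r0 = float(np.std(A)) * n ** (-0.2)
        candidates = r0 * np.geomspace(0.2, 1.5, 12)
    candidates = np.asarray(candidates, float)
    rng = np.random.default_rng(seed)
    fold_id = rng.permutation(np.arange(n) % folds)
    scores = np.zeros(candidates.size)
    for k in range(folds):
        tr, va = A[fold_id != k], A[fold_id == k]
        refl = np.concatenate([tr, 2.0 * lo - tr, 2.0 * hi - tr])
        diff2 = (va[:, None] - refl[None, :]) ** 2
        for j, r in enumerate(candidates):
            logk = -diff2 / (2.0 * r**2) - np.log(r * _SQRT2PI)
            scores[j] += -np.sum(logsumexp(logk, axis=1) - np.log(tr.size))
    return float(candidates[int(np.argmin(scores))])


class GFit:
    """Fitted conditional exposure density.

    Stores one log-link regression per exposure grid point; predictions
    interpolate the fitted log-density linearly between adjacent grid
    points, exponentiate, and floor at ``floor``.
    """

    def __init__(self, models, feature_fn, grid, floor, bandwidth):
        self._models = models
        self._features = feature_fn
        self.grid = grid
        self.floor = floor
        self.bandwidth = bandwidth

    def _log_density_on_grid(self, W: np.ndarray) -> np.ndarray:
        """Matrix of fitted log g(a_j | W_i); shape (len(W), grid)."""
        X = self._features(W)
        return np.column_stack(
            [m.intercept_ + X @ m.coef_ for m in self._models]
        )

    def predict_matrix(self, a_values, W) -> np.ndarray:
        """Matrix g(a_i | W_j); shape (len(a_values), len(W))."""
        W = np.atleast_2d(np.asarray(W, float))
        a = np.atleast_1d(np.asarray(a_values, float))
        L = self._log_density_on_grid(W)  # (m, G)
        idx = np.clip(np.searchsorted(self.grid, a) - 1, 0, self.grid.size - 2)
        t = (a - self.grid[idx]) / (self.grid[idx + 1] - self.grid[idx])
        t = np.clip(t, 0.0, 1.0)
        logg = L[:, idx] * (1.0 - t) + L[:, idx + 1] * t  # (m, len(a))
        return np.maximum(np.exp(logg).T, self.floor)

    def predict(self, a, W) -> np.ndarray:
        W = np.atleast_2d(np.asarray(W, float))
        a = np.broadcast_to(np.asarray(a, float), (W.shape[0],))
        L = self._log_density_on_grid(W)
        idx = np.clip(np.searchsorted(self.grid, a) - 1, 0, self.grid.size - 2)
        t = np.clip((a - self.grid[idx]) / (self.grid[idx + 1] - self.grid[idx]), 0, 1)
        rows = np.arange(W.shape[0])
        logg = L[rows, idx] * (1.0 - t) + L[rows, idx + 1] * t
        return np.maximum(np.exp(logg), self.floor)


def fit_conditional_density(
    sample, r: float, config: LearnerConfig | None = None
) -> GFit:
    """Kernel-smoothed conditional density regression under a log link.

    At each of ``density_grid_size`` equispaced points across the exposure
    range, the response ``r^{-1} phi((A_i - a_j)/r)`` is regressed on
    covariate features with a Poisson (log-link) regression.  The floor is
    ``density_floor_frac`` of the maximum fitted density over the sample.
    """
    config = config or LearnerConfig()
    if r <= 0:
        raise ValueError("bandwidth must be positive")
    lo, hi = sample.exposure_bounds
    grid = np.linspace(lo, hi, config.density_grid_size)

    if config.learner == "ridge_poly":
        degree = 3 if sample.W.shape[1] <= 2 else 2

        def feature_fn(W, degree=degree):
            return _poly_columns(np.atleast_2d(np.asarray(W, float)), degree)

    else:
        feats = _IndicatorFeatures.from_data(sample.W, config.num_knots)

        def feature_fn(W, feats=feats):
            return feats(np.atleast_2d(np.asarray(W, float)))

    X = feature_fn(sample.W)
    K = np.exp(-((sample.A[:, None] - grid[None, :]) ** 2) / (2.0 * r**2)) / (
        r * _SQRT2PI
    )
    models = []
    for j in range(grid.size):
        m = PoissonRegressor(alpha=1e-4, max_iter=500, tol=1e-7)
        m.fit(X, K[:, j])
        models.append(m)

    gfit = GFit(models, feature_fn, grid, floor=0.0, bandwidth=r)
    fitted = np.exp(gfit._log_density_on_grid(sample.W))
    gfit.floor = config.density_floor_frac * float(fitted.max())
    return gfit


def density_ratio_weights(gfit, sample) -> np.ndarray:
    """Weights ``w_i = (n^{-1} sum_j g(A_i | W_j)) / g(A_i | W_i)``.

    These are the stabilized inverse-density weights of the one-step
    correction; flooring of the fitted density keeps them finite.
    """
    G = gfit.predict_matrix(sample.A, sample.W)  # (n, n): g(A_i | W_j)
    num = G.mean(axis=1)
    return num / np.diag(G)
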