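"""Trait predictors: rrBLUP ridge regression and an SVR wrapper.

rrBLUP models the trait as ``y = 1*beta0 + X*beta + e`` with marker
effects ``beta ~ N(0, sigma_beta^2 I)`` and residuals
``e ~ N(0, sigma_e^2 I)``.  The variance components are estimated by
restricted maximum likelihood (REML) through a single spectral
decomposition of the marker covariance ``Xc Xc'`` projected off the
intercept; the penalized estimator at ``lambda = sigma_e^2 / sigma_beta^2``
is then the best linear unbiased predictor of the random effects, and
coincides with ridge regression at that penalty.

Penalty convention: ``ridge_solve`` minimizes
``||y - beta0 - X beta||^2 + lambda * ||beta||^2`` with an unpenalized
intercept handled by centering.  Under this convention the BLUP penalty is
exactly ``lambda = sigma_e^2 / sigma_beta^2``; any global rescaling of the
squared-error term only reparametrizes ``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import solve
from scipy.optimize import minimize_scalar

from .core import ValidationError


class SingularityError(np.linalg.LinAlgError):
    """Unpenalized least squares requested on a rank-deficient design."""


class DegenerateTraitError(ValueError):
    """The training trait is constant; variance components are undefined."""


@dataclass(frozen=True)
class RRBlupModel:
    """Fitted ridge-regression BLUP.

    ``lam`` is the ridge weight ``sigma_e_sq / sigma_beta_sq``;
    ``boundary`` is set when the REML search stopped at an edge of its
    ``log10(lambda)`` box (e.g. a noiseless trait drives ``lambda`` to the
    lower bound).
    """

    feature_ids: tuple[str, ...]
    beta0: float
    beta: np.ndarray
    lam: float
    sigma_beta_sq: float
    sigma_e_sq: float
    boundary: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=np.float64)
        if b.shape != (len(self.feature_ids),):
            raise ValidationError("effects length does not match feature ids")
        b.setflags(write=False)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("design matrix must be 2-D")
    return X


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Closed-form ridge with an unpenalized intercept.

    Minimizes ``||y - beta0 - X beta||^2 + lam ||beta||^2`` via the
    centered normal equations.  ``lam = 0`` demands a full-column-rank
    centered design.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=np.float64)
    n, m = X.shape
    if y.shape != (n,):
        raise ValidationError("X row count and y length differ")
    if lam < 0:
        raise ValidationError("ridge penalty must be nonnegative")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    if lam == 0 and np.linalg.matrix_rank(Xc) < m:
        raise SingularityError(
            "unpenalized least squares on a rank-deficient centered design"
        )
    A = Xc.T @ Xc + lam * np.eye(m)
    beta = solve(A, Xc.T @ yc, assume_a="pos")
    beta0 = ym - float(xm @ beta)
    return beta0, beta


def fit_rrblup(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    log10_lambda_bounds: tuple[float, float] = (-8.0, 8.0),
    tol: float = 1e-6,
) -> RRBlupModel:
    """Estimate variance components by REML and solve for BLUP effects.

    The restricted likelihood is profiled over the variance ratio
    ``delta = sigma_e^2 / sigma_beta^2``: after projecting the data onto
    an orthonormal complement of the intercept and diagonalizing the
    projected ``Xc Xc'`` once, each objective evaluation is O(n).  The
    ratio is maximized over ``log10(delta)`` in ``log10_lambda_bounds``
    with a bounded scalar search; the result is deterministic.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=np.float64)
    n, m = X.shape
    if y.shape != (n,):
        raise ValidationError("X row count and y length differ")
    if n < 3:
        raise ValidationError("rrBLUP needs at least 3 samples")
    if m < 1:
        raise ValidationError("rrBLUP needs at least 1 feature")
    if np.ptp(y) == 0:
        raise DegenerateTraitError("training trait is constant")
    if feature_ids is None:
        feature_ids = tuple(f"f{j}" for j in range(m))
    elif len(feature_ids) != m:
        raise ValidationError("feature_ids length does not match X width")

    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym

    # orthonormal basis of the intercept's complement, then one spectral
    # decomposition; the REML objective reuses it at every lambda
    Qfull = np.linalg.qr(np.ones((n, 1)), mode="complete")[0]
    Q = Qfull[:, 1:]  # n x (n-1)
    K = Xc @ Xc.T
    M = Q.T @ K @ Q
    xi, V = np.linalg.eigh(M)
    xi = np.clip(xi, 0.0, None)
    u2 = (V.T @ (Q.T @ y)) ** 2
    nr = n - 1

    def neg_restricted_ll(log10_delta: float) -> float:
        w = xi + 10.0**log10_delta
        s2b = float((u2 / w).sum()) / nr
        return nr * np.log(s2b) + float(np.log(w).sum())

    res = minimize_scalar(
        neg_restricted_ll,
        bounds=log10_lambda_bounds,
        method="bounded",
        options={"xatol": tol},
    )
    log10_lam = float(res.x)
    lam = 10.0**log10_lam
    sigma_beta_sq = float((u2 / (xi + lam)).sum()) / nr
    sigma_e_sq = lam * sigma_beta_sq
    lo, hi = log10_lambda_bounds
    boundary = (log10_lam - lo) < 10 * tol or (hi - log10_lam) < 10 * tol

    # dual-form ridge at the REML lambda: identical to the primal solution
    alpha = solve(K + lam * np.eye(n), yc, assume_a="pos")
    beta = Xc.T @ alpha
    beta0 = ym - float(xm @ beta)
    return RRBlupModel(
        tuple(feature_ids), beta0, beta, lam, sigma_beta_sq, sigma_e_sq, boundary
    )


def predict(model: RRBlupModel, X: np.ndarray) -> np.ndarray:
    """``beta0 + X beta`` for rows whose columns match the fit-time features."""
    X = _as_2d(X)
    if X.shape[1] != len(model.feature_ids):
        raise ValidationError(
            f"design has {X.shape[1]} features, model has {len(model.feature_ids)}"
        )
    return model.beta0 + X @ model.beta


# --- support vector regression (delegated) ---------------------------------

SVRKernel = Literal["linear", "polynomial", "radial", "sigmoid"]

_SKLEARN_KERNELS = {
    "linear": "linear",
    "polynomial": "poly",
    "radial": "rbf",
    "sigmoid": "sigmoid",
}


@dataclass(frozen=True)
class SVRConfig:
    """Epsilon-SVR hyperparameters; ``gamma=None`` means ``1/m``."""

    kernel: SVRKernel = "sigmoid"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float | None = None
    coef0: float = 0.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kernel not in _SKLEARN_KERNELS:
            raise ValidationError(f"unknown SVR kernel {self.kernel!r}")
        if self.C <= 0 or self.epsilon < 0 or self.degree < 1:
            raise ValidationError("invalid SVR hyperparameters")
        if self.gamma is not None and self.gamma <= 0:
            raise ValidationError("SVR gamma must be positive")


@dataclass
class SVRModel:
    """Fitted SVR plus the training standardization it was fitted under."""

    config: SVRConfig
    mean: np.ndarray
    scale: np.ndarray
    _svr: object = field(repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _as_2d(X)
        return np.asarray(self._svr.predict((X - self.mean) / self.scale))


def fit_svr(X: np.ndarray, y: np.ndarray, cfg: SVRConfig | None = None) -> SVRModel:
    """Epsilon-insensitive support vector regression (scikit-learn backend).

    Features are standardized on the training data; zero-variance columns
    keep scale 1 so they pass through as constants.
    """
    from sklearn.svm import SVR  # deferred: keep import cost off the hot path

    cfg = cfg or SVRConfig()
    X = _as_2d(X)
    y = np.asarray(y, dtype=np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    gamma = cfg.gamma if cfg.gamma is not None else 1.0 / X.shape[1]
    svr = SVR(
        kernel=_SKLEARN_KERNELS[cfg.kernel],
        C=cfg.C,
        epsilon=cfg.epsilon,
        gamma=gamma,
        coef0=cfg.coef0,
        degree=cfg.degree,
    )
    svr.fit((X - mean) / scale, y)
    return SVRModel(cfg, mean, scale, svr)
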