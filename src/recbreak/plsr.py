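"""Partial least squares regression of localization error on genomic features.

A single-response PLSR (NIPALS) with standardized predictors.  Each latent
factor is the unit direction in predictor space maximizing covariance with
the current response residual; both X and y are deflated between factors.
The variance of the response explained by factor i is pi_i, and the share
attributed to predictor j is

    p_j = sum_i (w_ij^2 / w_i) * pi_i,    w_i = sum_j w_ij^2,

where w_ij is predictor j's loading on factor i.  Since the weight vectors
are unit-normalized, sum_j p_j = sum_i pi_i exactly, so the per-predictor
contributions partition the total explained variance.  Coefficient
uncertainty is assessed by case-resampling bootstrap with percentile
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSRResult",
    "fit_plsr",
    "explained_variance",
    "bootstrap_coefficients",
    "choose_k_cv",
]


@dataclass
class PLSRResult:
    k: int
    feature_names: list
    x_weights: np.ndarray  # (p, k), columns unit norm
    x_loadings: np.ndarray  # (p, k)
    y_loadings: np.ndarray  # (k,)
    factor_r2: np.ndarray  # (k,) variance of y explained per factor (pi_i)
    coef_std: np.ndarray  # coefficients on the standardized scale
    coef: np.ndarray  # coefficients on the original predictor scale
    intercept: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    dropped: list = field(default_factory=list)

    @property
    def total_r2(self) -> float:
        return float(self.factor_r2.sum())

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef

    def explained_variance(self) -> dict:
        return explained_variance(self)


def _standardize(X, y):
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    keep = x_std > 0
    Xs = (X[:, keep] - x_mean[keep]) / x_std[keep]
    y_mean = float(np.mean(y))
    return Xs, y - y_mean, x_mean, x_std, keep


def fit_plsr(X, y, k: int, feature_names=None) -> PLSRResult:
    """Fit a NIPALS PLSR of y on standardized X with k latent factors.

    Constant predictor columns are dropped with a warning; k is reduced to
    the effective rank when necessary.  Coefficients are reported both on
    the standardized scale (comparable across predictors) and back on the
    original predictor scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    Xs, yc, x_mean, x_std, keep = _standardize(X, y)
    dropped = [feature_names[j] for j in range(p) if not keep[j]]
    if dropped:
        warnings.warn(f"dropping constant predictors: {dropped}")
    names = [feature_names[j] for j in range(p) if keep[j]]
    p_eff = Xs.shape[1]
    k = min(k, p_eff, n - 1)
    ss_y = float(yc @ yc)
    if ss_y == 0:
        raise ValueError("response is constant")

    W = np.zeros((p_eff, k))
    P = np.zeros((p_eff, k))
    q = np.zeros(k)
    r2 = np.zeros(k)
    Xd, yd = Xs.copy(), yc.copy()
    k_used = 0
    for i in range(k):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pl = Xd.T @ t / tt
        qi = float(yd @ t) / tt
        W[:, i] = w
        P[:, i] = pl
        q[i] = qi
        r2[i] = qi**2 * tt / ss_y
        Xd = Xd - np.outer(t, pl)
        yd = yd - qi * t
        k_used = i + 1
    W, P, q, r2 = W[:, :k_used], P[:, :k_used], q[:k_used], r2[:k_used]
    coef_std = W @ np.linalg.solve(P.T @ W, q) if k_used else np.zeros(p_eff)

    coef = np.zeros(p)
    coef[keep] = coef_std / x_std[keep]
    intercept = float(np.mean(y) - x_mean @ coef)
    return PLSRResult(
        k=k_used,
        feature_names=names,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        factor_r2=r2,
        coef_std=coef_std,
        coef=coef,
        intercept=intercept,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=float(np.mean(y)),
        dropped=dropped,
    )


def explained_variance(result: PLSRResult) -> dict:
    """Per-predictor explained variance p_j (sums to the total explained R^2)."""
    W2 = result.x_weights**2  # (p, k)
    w_i = W2.sum(axis=0)  # (k,)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(w_i > 0, W2 / w_i, 0.0)
    p_j = share @ result.factor_r2
    return dict(zip(result.feature_names, p_j))


def bootstrap_coefficients(X, y, k: int, R: int = 1000, rng=None,
                           feature_names=None, level: float = 0.95) -> pd.DataFrame:
    """Case-resampling bootstrap percentile CIs for the PLSR coefficients.

    A coefficient is flagged significant when its interval excludes zero.
    Resamples yielding a constant predictor column are redrawn.
    """
    if R < 100:
        raise ValueError("R must be >= 100")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    fit = fit_plsr(X, y, k, feature_names)
    boots = np.empty((R, p))
    for r in range(R):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if np.all(Xb.std(axis=0) > 0):
                break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boots[r] = fit_plsr(Xb, y[idx], k, feature_names).coef
    a = (1.0 - level) / 2.0
    lo = np.quantile(boots, a, axis=0)
    hi = np.quantile(boots, 1.0 - a, axis=0)
    return pd.DataFrame(
        {
            "predictor": feature_names,
            "coef": fit.coef,
            "ci_lower": lo,
            "ci_upper": hi,
            "sign": np.where(fit.coef >= 0, "+", "-"),
            "significant": (lo > 0) | (hi < 0),
        }
    )


def choose_k_cv(X, y, k_max: int, folds: int = 10, rng=None) -> int:
    """Number of latent factors minimizing k-fold cross-validated MSE."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    idx = rng.permutation(n)
    fold_of = np.arange(n) % folds
    mses = []
    for k in range(1, k_max + 1):
        sq = 0.0
        for f in range(folds):
            test = idx[fold_of == f]
            train = idx[fold_of != f]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_plsr(X[train], y[train], k)
            pred = fit.intercept + X[test] @ fit.coef
            sq += float(np.sum((y[test] - pred) ** 2))
        mses.append(sq / n)
    return int(np.argmin(mses)) + 1
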