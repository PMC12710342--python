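"""Gaussian random-intercept linear mixed model via profiled REML.

The longitudinal models used throughout (abundance ~ visit + (1|woman),
hormone ~ visit + abundance + (1|woman) + covariates) all share one
structure: a single grouping factor with a random intercept.  For that
structure the covariance V = sigma_e^2 (I + lambda Z Z') is block diagonal
with closed-form inverse and determinant per group, so REML reduces to a
one-dimensional optimization over the variance ratio
lambda = sigma_b^2/sigma_e^2.  This makes a fit cheap enough to repeat
thousands of times inside permutation loops; correctness is checked in the
test suite against statsmodels' general MixedLM implementation.

Wald p-values use the normal approximation on beta/SE; permutation-based
empirical p-values are the calibrated quantity reported alongside them by
the association layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["RandomInterceptFit", "RandomInterceptModel", "fit_random_intercept"]


@dataclass
class RandomInterceptFit:
    """Result of one random-intercept fit.

    ``beta``/``se``/``p`` are aligned with the design columns; ``icc`` is
    sigma_b^2/(sigma_b^2+sigma_e^2).  ``singular`` flags a boundary
    variance estimate (lambda at 0 or the optimizer ceiling, or a
    vanishing residual variance).
    """

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    sigma_b2: float
    sigma_e2: float
    icc: float
    reml: float
    converged: bool
    singular: bool

    def ci(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - z * self.se, self.beta + z * self.se])


class RandomInterceptModel:
    """Reusable fitter for a fixed design X and grouping; refit per outcome.

    ``X`` must include an intercept column.  Group-level sufficient
    statistics of X are precomputed once so that permutation refits (which
    only change y) cost a single pass over the data per likelihood
    evaluation.
    """

    _LOG_LAMBDA_BOUNDS = (-10.0, 10.0)

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        codes, _ = _group_codes(groups)
        order = np.argsort(codes, kind="stable")
        self.order = order
        self.X = X[order]
        codes = codes[order]
        boundaries = np.flatnonzero(np.r_[True, np.diff(codes) > 0])
        self.boundaries = boundaries
        self.group_sizes = np.diff(np.r_[boundaries, len(codes)]).astype(float)
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ValueError("more parameters than observations")
        self.XtX = self.X.T @ self.X
        self.Sx = np.add.reduceat(self.X, boundaries, axis=0)  # group sums of X

    def fit(self, y: np.ndarray) -> RandomInterceptFit:
        y = np.asarray(y, dtype=float)[self.order]
        yty = float(y @ y)
        Xty = self.X.T @ y
        Sy = np.add.reduceat(y, self.boundaries)
        n, p = self.n, self.p
        ns = self.group_sizes

        def profile(lam: float):
            w = lam / (1.0 + lam * ns)
            XtVX = self.XtX - (self.Sx.T * w) @ self.Sx
            XtVy = Xty - self.Sx.T @ (w * Sy)
            yVy = yty - float(w @ Sy**2)
            try:
                c, low = _chol(XtVX)
            except np.linalg.LinAlgError:
                return None
            beta = _chol_solve(c, XtVy)
            rss = max(yVy - float(beta @ XtVy), 1e-300)
            sigma_e2 = rss / (n - p)
            logdet_V = float(np.sum(np.log1p(lam * ns)))
            logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(c))))
            crit = (n - p) * np.log(sigma_e2) + logdet_V + logdet_XtVX
            return crit, beta, sigma_e2, c

        def objective(log_lam: float) -> float:
            res = profile(np.exp(log_lam))
            return np.inf if res is None else res[0]

        lo, hi = self._LOG_LAMBDA_BOUNDS
        opt = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        candidates = [(objective(lo), lo), (opt.fun, float(opt.x))]
        crit0 = profile(0.0)
        best_crit, best_loglam = min(candidates)
        if crit0 is not None and crit0[0] <= best_crit:
            lam = 0.0
        else:
            lam = float(np.exp(best_loglam))
        res = profile(lam)
        if res is None:  # pragma: no cover - pathological design
            raise np.linalg.LinAlgError("singular penalized design")
        crit, beta, sigma_e2, c = res
        cov = sigma_e2 * _chol_inverse(c)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, 0.0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        sigma_b2 = lam * sigma_e2
        icc = sigma_b2 / (sigma_b2 + sigma_e2) if (sigma_b2 + sigma_e2) > 0 else 0.0
        singular = (
            lam == 0.0
            or np.log(max(lam, 1e-300)) >= hi - 1e-3
            or sigma_e2 < 1e-10
        )
        return RandomInterceptFit(
            beta=beta,
            se=se,
            p=pvals,
            sigma_b2=float(sigma_b2),
            sigma_e2=float(sigma_e2),
            icc=float(icc),
            reml=-0.5 * float(crit),
            converged=bool(opt.success),
            singular=bool(singular),
        )


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> RandomInterceptFit:
    """One-shot convenience wrapper around :class:`RandomInterceptModel`."""
    return RandomInterceptModel(X, groups).fit(y)


def _group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(groups)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes, uniq


def _chol(a: np.ndarray):
    c = np.linalg.cholesky(a)
    return c, True


def _chol_solve(c: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    z = solve_triangular(c, b, lower=True)
    return solve_triangular(c.T, z, lower=False)


def _chol_inverse(c: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    eye = np.eye(c.shape[0])
    inv_l = solve_triangular(c, eye, lower=True)
    return inv_l.T @ inv_l
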