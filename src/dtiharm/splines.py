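"""Penalized cubic-spline smoothers shared across the package.

One basis serves four jobs: the ComBat-GAM covariate surface, the mean
lifespan curve, the SD smooth, and the quantile (centile) curves. The basis
is a cubic B-spline expansion with `n_basis` functions (default 10) on
equally spaced interior knots; smoothness is controlled by a second-order
difference penalty on the coefficients, with the penalty weight chosen by
generalized cross-validation (GCV) for least-squares fits. Quantile curves
minimize a smoothed pinball (check) loss with the same penalty.

Evaluation outside the fitted age span clamps to the span endpoints rather
than extrapolating the spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit

DEFAULT_N_BASIS = 10


def bspline_design(x: np.ndarray, lo: float, hi: float,
                   n_basis: int = DEFAULT_N_BASIS, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with n_basis columns on [lo, hi].

    x values outside [lo, hi] are clamped to the boundary.
    """
    if n_basis <= degree:
        raise ValueError("n_basis must exceed the spline degree")
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    n_inner = n_basis - degree - 1
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1] if n_inner > 0 else np.array([])
    knots = np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])
    return BSpline.design_matrix(x, knots, degree).toarray()


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """Penalty matrix D'D for order-th differences of spline coefficients."""
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


@dataclass
class SplineFit:
    """A fitted penalized spline f(x) on [lo, hi] plus optional linear terms."""

    lo: float
    hi: float
    n_basis: int
    coef: np.ndarray          # spline coefficients
    linear_coef: np.ndarray   # coefficients of extra linear columns (may be empty)
    alpha: float

    def basis(self, x) -> np.ndarray:
        return bspline_design(x, self.lo, self.hi, self.n_basis)

    def predict(self, x, linear_cols: np.ndarray | None = None) -> np.ndarray:
        out = self.basis(x) @ self.coef
        if self.linear_coef.size:
            if linear_cols is None:
                raise ValueError("fit has linear terms; linear_cols required")
            out = out + np.asarray(linear_cols, dtype=float) @ self.linear_coef
        return out


def _alpha_grid() -> np.ndarray:
    return np.logspace(-6, 6, 25)


def fit_penalized_spline(x, y, lo=None, hi=None, n_basis: int = DEFAULT_N_BASIS,
                         linear_cols: np.ndarray | None = None,
                         alpha: float | None = None,
                         weights: np.ndarray | None = None) -> SplineFit:
    """Penalized least-squares spline fit; alpha by GCV unless given.

    linear_cols are unpenalized extra regressors (e.g. a sex indicator)
    fitted jointly with the smooth. GCV score = n * RSS / (n - edf)^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = float(x.min()) if lo is None else float(lo)
    hi = float(x.max()) if hi is None else float(hi)
    B = bspline_design(x, lo, hi, n_basis)
    if linear_cols is not None:
        L = np.atleast_2d(np.asarray(linear_cols, dtype=float))
        if L.shape[0] != len(x):
            L = L.T
        X = np.hstack([B, L])
        n_lin = L.shape[1]
    else:
        X = B
        n_lin = 0
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    P = np.zeros((X.shape[1], X.shape[1]))
    P[:n_basis, :n_basis] = difference_penalty(n_basis)
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    n = len(y)

    def solve(a):
        A = XtX + a * P
        coef = np.linalg.solve(A, Xty)
        edf = np.trace(np.linalg.solve(A, XtX))
        return coef, edf

    if alpha is None:
        scores = []
        for a in _alpha_grid():
            coef_a, edf = solve(a)
            rss = float(np.sum((yw - Xw @ coef_a) ** 2))
            denom = max(n - edf, 1e-8)
            scores.append((n * rss / denom**2, a, coef_a))
        gmin = min(s[0] for s in scores)
        # among statistically equivalent alphas (GCV within 0.1% of the
        # minimum) prefer the smoothest fit; stabilizes near-flat signals
        _, alpha, coef = max((s for s in scores if s[0] <= gmin * 1.001),
                             key=lambda s: s[1])
    else:
        coef, _ = solve(alpha)
    return SplineFit(lo, hi, n_basis, coef[:n_basis],
                     coef[n_basis:], float(alpha))


def fit_quantile_spline(x, y, tau: float, lo=None, hi=None,
                        n_basis: int = DEFAULT_N_BASIS,
                        alpha: float | None = None,
                        eps: float | None = None) -> SplineFit:
    """Quantile-regression spline at level tau via a smoothed pinball loss.

    Loss per residual r = y - f(x):
        rho_eps(r) = (tau - 1) * r + eps * log(1 + exp(r / eps)),
    a convex C-infinity approximation of the check function that converges
    to it as eps -> 0. eps defaults to 0.02 x a robust residual scale, small
    enough that the smoothing-induced quantile bias is negligible against
    the residual spread.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = float(x.min()) if lo is None else float(lo)
    hi = float(x.max()) if hi is None else float(hi)
    B = bspline_design(x, lo, hi, n_basis)
    P = difference_penalty(n_basis)
    # warm start and default penalty from the mean fit
    mean_fit = fit_penalized_spline(x, y, lo=lo, hi=hi, n_basis=n_basis,
                                    alpha=alpha)
    if alpha is None:
        alpha = mean_fit.alpha
    resid = y - B @ mean_fit.coef
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if eps is None:
        eps = max(0.02 * scale, 1e-8)
    theta0 = mean_fit.coef.copy()
    n = len(y)
    # Match the effective smoothing of the least-squares fit: the pinball
    # data term has per-observation curvature ~= the residual density at the
    # target quantile (vs 1 for LS), so a GCV-chosen LS alpha must be scaled
    # by the mean local curvature to yield a comparable effective df.
    s0 = expit(resid / eps)
    curvature = float(np.mean(s0 * (1.0 - s0)) / eps)
    alpha = alpha * max(curvature, 1e-12)

    def objective(theta):
        r = y - B @ theta
        z = r / eps
        # log(1+exp(z)) computed stably
        soft = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30))))
        loss = np.sum((tau - 1.0) * r + eps * soft) / n
        pen = alpha * theta @ P @ theta / n
        g_r = (tau - 1.0) + expit(z)
        grad = -B.T @ g_r / n + 2 * alpha * P @ theta / n
        return loss + pen, grad

    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    return SplineFit(lo, hi, n_basis, res.x, np.empty(0), float(alpha))


def loess_smooth(x, y, span: float = 0.1, grid: np.ndarray | None = None) -> np.ndarray:
    """Local linear regression (LOESS, tricube weights) evaluated on a grid.

    Offered as an alternative trend smoother for peak-age robustness checks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 200)
    k = max(int(np.ceil(span * len(x))), 4)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(len(grid))
    for i, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / max(h, 1e-12)) ** 3) ** 3
        X = np.column_stack([np.ones(k), xs[idx] - g])
        W = w[:, None]
        beta, *_ = np.linalg.lstsq(X * W, ys[idx] * w, rcond=None)
        out[i] = beta[0]
    return out
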