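"""ComBat-family harmonization: ComBat, ComBat-GAM and CovBat.

Model: for site i, subject j, feature v,

    y_ijv = surface_v(X_ij) + gamma_iv + delta_iv * e_ijv

where the covariate surface is either linear (intercept + age + sex [+ extras])
or a GAM (penalized cubic spline over age + linear sex [+ extras]), gamma_iv is
an additive site offset and delta_iv a multiplicative site scale on the
residual. Site effects are identified by the size-weighted zero-sum constraint
sum_i n_i gamma_iv = 0 and shrunk across features by parametric empirical
Bayes (normal prior on location, inverse-gamma on squared scale), following
the classical gene-expression batch-adjustment estimator. CovBat additionally
standardizes per-site means and scales of the leading principal-component
scores of the pooled ComBat residuals.

Internally delta is carried on the SD scale (the residual is divided by
delta), while the EB prior acts on the variance delta^2 as in the original
estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .splines import bspline_design, difference_penalty, _alpha_grid, DEFAULT_N_BASIS
from .tables import FeatureTable, CovariateTable, check_paired

DELTA_FLOOR = 1e-6
EB_TOL = 1e-4
EB_MAX_ITER = 100


class EBConvergenceError(RuntimeError):
    """EB iteration failed to converge; carries the last iterate."""

    def __init__(self, message, gamma_star, delta_star):
        super().__init__(message)
        self.gamma_star = gamma_star
        self.delta_star = delta_star


@dataclass
class CombatModel:
    """Fitted covariate surface, pooled scale, and raw + EB site effects."""

    mode: str
    feature_names: list[str]
    batch_levels: list
    batch_counts: np.ndarray
    grand_mean: np.ndarray          # (V,) weighted mean of batch intercepts
    lin_names: list[str]
    lin_coef: np.ndarray            # (n_lin, V)
    pooled_scale: np.ndarray        # (V,) sigma_hat
    gamma_hat: np.ndarray           # (I, V)
    delta_hat: np.ndarray           # (I, V), SD scale
    gamma_star: np.ndarray = None
    delta_star: np.ndarray = None
    eb_hyperparams: dict = None
    eb_enabled: bool = True
    covariate_spec: dict = field(default_factory=dict)
    # gam-mode smooth: age basis with a centering constraint
    spline_lo: float = None
    spline_hi: float = None
    spline_n_basis: int = DEFAULT_N_BASIS
    spline_Z: np.ndarray = None     # (n_basis, n_basis-1) constraint transform
    spline_coef: np.ndarray = None  # (n_basis-1, V)
    spline_alpha: np.ndarray = None
    # standardized residuals of the training data, for the EB step
    standardized_residuals: np.ndarray = None
    train_batch: np.ndarray = None

    def _lin_matrix(self, covars: CovariateTable) -> np.ndarray:
        cols = []
        for name in self.lin_names:
            if name == "age":
                cols.append(covars.age)
            elif name == "sex":
                cols.append(covars.sex.astype(float))
            else:
                cols.append(covars.extras[name].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((covars.n_subjects, 0))

    def surface(self, covars: CovariateTable) -> np.ndarray:
        """Covariate surface (no site terms) evaluated per subject x feature."""
        out = np.tile(self.grand_mean, (covars.n_subjects, 1))
        L = self._lin_matrix(covars)
        if L.shape[1]:
            out = out + L @ self.lin_coef
        if self.mode == "gam":
            B = bspline_design(covars.age, self.spline_lo, self.spline_hi,
                               self.spline_n_basis)
            out = out + (B @ self.spline_Z) @ self.spline_coef
        return out


def _batch_design(batch: np.ndarray, batch_levels: list) -> np.ndarray:
    return np.column_stack([(batch == lev).astype(float) for lev in batch_levels])


def _extras_names(covars: CovariateTable) -> list[str]:
    if covars.extras is None:
        return []
    return [c for c in covars.extras.columns]


def fit_standard_model(features: FeatureTable, covars: CovariateTable,
                       mode: str = "linear", min_site_n: int = 10) -> CombatModel:
    """Fit the covariate surface and raw (non-EB) site effects.

    Returns a CombatModel with gamma_hat/delta_hat populated and the
    standardized residuals Z_ijv = (y - surface) / sigma_hat attached for the
    EB step; gamma_star/delta_star are left unset.
    """
    if mode not in ("linear", "gam"):
        raise ValueError(f"unknown mode: {mode!r}")
    check_paired(features, covars)
    batch_levels = covars.batch_levels
    if len(batch_levels) < 2:
        raise ValueError("at least 2 batch levels are required for fitting")
    Y = features.values
    n, V = Y.shape
    D = _batch_design(covars.batch, batch_levels)
    counts = D.sum(axis=0)
    small = [str(b) for b, c in zip(batch_levels, counts) if c < min_site_n]
    if small:
        raise ValueError(f"batches with fewer than min_site_n={min_site_n} "
                         f"subjects: {small}")

    lin_names = (["age", "sex"] if mode == "linear" else ["sex"]) + _extras_names(covars)
    cols = []
    for name in lin_names:
        if name == "age":
            cols.append(covars.age)
        elif name == "sex":
            cols.append(covars.sex.astype(float))
        else:
            cols.append(covars.extras[name].to_numpy(dtype=float))
    L = np.column_stack(cols) if cols else np.empty((n, 0))

    spline = {}
    if mode == "gam":
        lo, hi = float(covars.age.min()), float(covars.age.max())
        B = bspline_design(covars.age, lo, hi, DEFAULT_N_BASIS)
        # mgcv-style sum-to-zero constraint: removes the confound between the
        # smooth's level and the batch intercepts
        Z = null_space(B.mean(axis=0)[None, :])
        Bc = B @ Z
        P0 = Z.T @ difference_penalty(DEFAULT_N_BASIS) @ Z
        spline = dict(lo=lo, hi=hi, Z=Z, Bc=Bc, P0=P0)

    X_parts = [D, L] + ([spline["Bc"]] if mode == "gam" else [])
    X = np.hstack(X_parts)
    p = X.shape[1]
    I = len(batch_levels)
    n_lin = L.shape[1]

    if mode == "linear":
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("singular design matrix (collinear covariates "
                             "or confounded batch)")
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        alphas = None
    else:
        # penalized LS; batch and linear columns unpenalized, per-feature GCV
        Pfull = np.zeros((p, p))
        sl = slice(I + n_lin, p)
        Pfull[sl, sl] = spline["P0"]
        XtX = X.T @ X
        XtY = X.T @ Y
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("singular design matrix (collinear covariates "
                             "or confounded batch)")
        coef = np.empty((p, V))
        alphas = np.empty(V)
        grid = _alpha_grid()
        # precompute per-alpha solves shared across features
        sols, edfs = [], []
        for a in grid:
            A = XtX + a * Pfull
            sols.append(np.linalg.solve(A, XtY))
            edfs.append(np.trace(np.linalg.solve(A, XtX)))
        for v in range(V):
            best = (np.inf, 0)
            for gi, a in enumerate(grid):
                r = Y[:, v] - X @ sols[gi][:, v]
                rss = float(r @ r)
                gcv = n * rss / max(n - edfs[gi], 1e-8) ** 2
                if gcv < best[0]:
                    best = (gcv, gi)
            gi = best[1]
            coef[:, v] = sols[gi][:, v]
            alphas[v] = grid[gi]

    resid = Y - X @ coef
    var_pooled = (resid ** 2).mean(axis=0)
    zero = np.flatnonzero(var_pooled <= 1e-16)  # numerically constant feature
    if zero.size:
        raise ValueError("constant feature(s) with zero pooled residual "
                         f"variance: {[features.feature_names[v] for v in zero]}")
    sigma = np.sqrt(var_pooled)

    w = counts / n
    batch_coef = coef[:I]                     # (I, V) per-batch intercepts
    grand_mean = w @ batch_coef
    lin_coef = coef[I:I + n_lin]

    model = CombatModel(
        mode=mode, feature_names=list(features.feature_names),
        batch_levels=batch_levels, batch_counts=counts,
        grand_mean=grand_mean, lin_names=lin_names, lin_coef=lin_coef,
        pooled_scale=sigma, gamma_hat=None, delta_hat=None,
        covariate_spec={"mode": mode, "linear": lin_names,
                        "smooth": (["age"] if mode == "gam" else [])},
    )
    if mode == "gam":
        model.spline_lo, model.spline_hi = spline["lo"], spline["hi"]
        model.spline_Z = spline["Z"]
        model.spline_coef = coef[I + n_lin:]
        model.spline_alpha = alphas

    stand_mean = model.surface(covars)
    Zdata = (Y - stand_mean) / sigma
    gamma_hat = np.empty((I, V))
    delta_hat = np.empty((I, V))
    for i in range(I):
        rows = D[:, i] > 0
        gamma_hat[i] = Zdata[rows].mean(axis=0)
        # ddof=0 keeps delta consistent with the 1/n pooled scale, so two
        # identical batches give delta = 1 exactly
        sd = Zdata[rows].std(axis=0, ddof=0)
        if np.any(sd < DELTA_FLOOR):
            warnings.warn(f"zero within-site variance floored for batch "
                          f"{batch_levels[i]!r}", stacklevel=2)
            sd = np.maximum(sd, DELTA_FLOOR)
        delta_hat[i] = sd
    model.gamma_hat = gamma_hat
    model.delta_hat = delta_hat
    model.standardized_residuals = Zdata
    model.train_batch = covars.batch.copy()
    return model


def _eb_site(z_site: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray):
    """Iterated conditional posterior means for one site (variance-scale EB)."""
    n_i, V = z_site.shape
    d_hat = delta_hat ** 2
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m = d_hat.mean()
    s2 = d_hat.var(ddof=1)
    if s2 <= 0 or tau2 <= 0:
        # degenerate priors (e.g. identical features): infinitely tight prior
        # would erase signal, so keep raw estimates
        return gamma_hat.copy(), delta_hat.copy(), dict(
            gamma_bar=gamma_bar, tau2=tau2, a=np.nan, b=np.nan, degenerate=True)
    a = (2 * s2 + m ** 2) / s2
    b = (m * s2 + m ** 3) / s2
    g_old = gamma_hat.copy()
    d_old = d_hat.copy()
    for _ in range(EB_MAX_ITER):
        g_new = (n_i * tau2 * gamma_hat + d_old * gamma_bar) / (n_i * tau2 + d_old)
        sum2 = ((z_site - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n_i / 2.0 + a - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                     np.max(np.abs(d_new - d_old) / d_old))
        g_old, d_old = g_new, d_new
        if change <= EB_TOL:
            break
    else:
        raise EBConvergenceError(
            f"EB iteration did not converge within {EB_MAX_ITER} iterations",
            g_old, np.sqrt(d_old))
    return g_old, np.sqrt(d_old), dict(gamma_bar=gamma_bar, tau2=tau2,
                                       a=a, b=b, degenerate=False)


def estimate_site_effects_eb(standardized_residuals: np.ndarray,
                             batch: np.ndarray, batch_levels: list,
                             gamma_hat: np.ndarray, delta_hat: np.ndarray,
                             eb: bool = True):
    """EB-shrunken site effects (gamma*, delta*) from standardized residuals.

    With eb=False the raw estimates are passed through unchanged. With a
    single feature EB cannot pool and falls back to the raw estimates with a
    warning.
    """
    V = standardized_residuals.shape[1]
    if not eb:
        return gamma_hat.copy(), delta_hat.copy(), {"eb": False}
    if V < 2:
        warnings.warn("single feature: EB pooling impossible, using raw "
                      "site effects", stacklevel=2)
        return gamma_hat.copy(), delta_hat.copy(), {"eb": False, "reason": "single feature"}
    I = len(batch_levels)
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    hyper = {"eb": True, "sites": {}}
    for i, lev in enumerate(batch_levels):
        rows = batch == lev
        g, d, h = _eb_site(standardized_residuals[rows], gamma_hat[i], delta_hat[i])
        gamma_star[i], delta_star[i] = g, d
        hyper["sites"][str(lev)] = h
    return gamma_star, delta_star, hyper


def apply_adjustment(model: CombatModel, features: FeatureTable,
                     covars: CovariateTable) -> FeatureTable:
    """Remove site location/scale effects and restore the covariate surface."""
    check_paired(features, covars)
    if features.feature_names != model.feature_names:
        raise ValueError("feature names do not match the fitted model")
    if model.gamma_star is None:
        raise ValueError("model has no EB site effects; run "
                         "estimate_site_effects_eb (or fit_combat) first")
    unseen = sorted(set(covars.batch.tolist()) - set(model.batch_levels), key=str)
    if unseen:
        raise ValueError(f"unseen batch level(s) {unseen}: harmonize new sites "
                         "against a reference bundle (see dtiharm.site)")
    stand_mean = model.surface(covars)
    Z = (features.values - stand_mean) / model.pooled_scale
    out = np.empty_like(Z)
    for i, lev in enumerate(model.batch_levels):
        rows = covars.batch == lev
        if not rows.any():
            continue
        out[rows] = (Z[rows] - model.gamma_star[i]) / model.delta_star[i]
    out = out * model.pooled_scale + stand_mean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # adjusted FA may nudge past [0, 1]
        return FeatureTable(features.subject_ids, features.feature_names, out)


def fit_combat(features: FeatureTable, covars: CovariateTable,
               mode: str = "linear", eb: bool = True,
               min_site_n: int = 10):
    """Full ComBat pipeline: surface fit -> EB site effects -> adjustment.

    Returns (CombatModel, harmonized FeatureTable).
    """
    model = fit_standard_model(features, covars, mode=mode, min_site_n=min_site_n)
    gamma_star, delta_star, hyper = estimate_site_effects_eb(
        model.standardized_residuals, model.train_batch, model.batch_levels,
        model.gamma_hat, model.delta_hat, eb=eb)
    model.gamma_star, model.delta_star = gamma_star, delta_star
    model.eb_hyperparams = hyper
    model.eb_enabled = bool(eb) and hyper.get("eb", False)
    harmonized = apply_adjustment(model, features, covars)
    return model, harmonized


@dataclass
class CovbatModel:
    """ComBat plus per-site standardization of leading residual PC scores."""

    inner_combat: CombatModel
    pc_basis: np.ndarray          # (V, q) eigenvectors phi_k
    pc_center: np.ndarray         # (V,) pooled residual mean
    pooled_score_sd: np.ndarray   # (K,) target scale per adjusted component
    scores_center: np.ndarray     # (I, K) mu_ik
    scores_scale: np.ndarray      # (I, K) rho_ik
    n_components_total: int
    n_components_adjusted: int
    pct_var: float
    explained_variance_ratio: np.ndarray


def fit_covbat(features: FeatureTable, covars: CovariateTable,
               pct_var: float = 0.95, eb: bool = True,
               min_site_n: int = 10):
    """CovBat: ComBat (linear mode) then covariance harmonization of residuals.

    PCA is run on the pooled ComBat-adjusted residuals; for the first K
    components (cumulative explained variance >= pct_var) per-site score
    center and scale are removed and the scores rescaled to the pooled
    per-component SD; trailing components pass through; the covariate surface
    is re-added. Returns (CovbatModel, harmonized FeatureTable).
    """
    if not 0.0 < pct_var <= 1.0:
        raise ValueError("pct_var must lie in (0, 1]")
    if features.n_features < 2:
        raise ValueError("CovBat requires at least 2 features")
    model, combat_out = fit_combat(features, covars, mode="linear", eb=eb,
                                   min_site_n=min_site_n)
    stand_mean = model.surface(covars)
    E = combat_out.values - stand_mean          # ComBat-adjusted residuals
    n, V = E.shape
    q_max = min(n - 1, V)
    if V > n - 1:
        warnings.warn(f"more features ({V}) than informative components; "
                      f"using q = {q_max}", stacklevel=2)
    center = E.mean(axis=0)
    Ec = E - center
    cov = Ec.T @ Ec / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:q_max]
    evals = np.maximum(evals[order], 0.0)
    phi = evecs[:, order]
    ratio = evals / evals.sum() if evals.sum() > 0 else np.full(q_max, 1.0 / q_max)
    K = int(np.searchsorted(np.cumsum(ratio), pct_var - 1e-12) + 1)
    K = min(max(K, 1), q_max)

    scores = Ec @ phi                           # (n, q)
    I = len(model.batch_levels)
    mu = np.empty((I, K))
    rho = np.empty((I, K))
    # ddof=0 throughout so identical sites are an exact no-op
    pooled_sd = scores[:, :K].std(axis=0, ddof=0)
    adj = scores.copy()
    for i, lev in enumerate(model.batch_levels):
        rows = covars.batch == lev
        mu[i] = scores[rows, :K].mean(axis=0)
        rho[i] = np.maximum(scores[rows, :K].std(axis=0, ddof=0), DELTA_FLOOR)
        adj[rows, :K] = (scores[rows, :K] - mu[i]) / rho[i] * pooled_sd
    E_adj = adj @ phi.T + center
    out_values = E_adj + stand_mean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        harmonized = FeatureTable(features.subject_ids, features.feature_names,
                                  out_values)
    cb = CovbatModel(
        inner_combat=model, pc_basis=phi, pc_center=center,
        pooled_score_sd=pooled_sd, scores_center=mu, scores_scale=rho,
        n_components_total=q_max, n_components_adjusted=K,
        pct_var=pct_var, explained_variance_ratio=ratio)
    return cb, harmonized
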