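"""Evaluation statistics for harmonized lifespan curves.

Peak-age extraction and MAE against a silver standard, discrete Fréchet
curve similarity, sex- and group-effect models with Benjamini-Hochberg FDR,
acquisition-parameter correlations with site harmonization parameters,
longitudinal harmonization-strategy comparison via mixed models, and
train-vs-test MAE comparison against a reference bundle.

"Standardized beta" throughout means both the outcome and the predictor are
z-scored before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import null_space
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .reference import LifespanCurve, ReferenceBundle
from .site import SiteHarmonizationModel, fit_site_to_reference, apply_site_model
from .splines import bspline_design, loess_smooth, DEFAULT_N_BASIS
from .tables import FeatureTable, CovariateTable, check_paired

# Synthetic placeholder silver-standard peak ages (years): midpoint of the
# expected young-adult peak window for the twelve classically reported
# regions. This is configuration — real analyses should substitute the
# published single-site peak table they wish to benchmark against.
SILVER_STANDARD_PLACEHOLDER = {
    roi: 30.0 for roi in
    ["AverageFA", "ACR", "ALIC", "BCC", "CGC", "CGH", "EC", "GCC", "PLIC",
     "PTR", "SLF", "SS"]
}


@dataclass
class PeakResult:
    roi: str
    peak_age: int            # reported, rounded to nearest year
    peak_age_raw: float      # grid value
    peak_value: float
    concave_down: bool


def peak_age(curve, roi: str = None, smoother: str = "gam",
             loess_span: float = 0.1) -> PeakResult:
    """Age of maximum FA on the curve's grid.

    Accepts a LifespanCurve or an (age_grid, values) pair. Ties break toward
    the younger age; the trajectory is flagged concave-down only when the
    argmax is interior (more than 1 year from either endpoint). With
    smoother="loess" the raw values are first re-smoothed by local linear
    regression (robustness check for spline-driven peaks).
    """
    if isinstance(curve, LifespanCurve):
        grid, values = curve.age_grid, curve.values
        roi = roi if roi is not None else curve.roi
    else:
        grid, values = np.asarray(curve[0], dtype=float), np.asarray(curve[1], dtype=float)
    if len(grid) < 3:
        raise ValueError("at least 3 grid points are required")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite curve values")
    if smoother == "loess":
        values = loess_smooth(grid, values, span=loess_span, grid=grid)
    elif smoother != "gam":
        raise ValueError(f"unknown smoother {smoother!r}")
    i = int(np.argmax(values))  # first occurrence = youngest age on ties
    raw = float(grid[i])
    interior = (raw - grid[0] > 1.0) and (grid[-1] - raw > 1.0)
    return PeakResult(roi=roi or "", peak_age=int(round(raw)), peak_age_raw=raw,
                      peak_value=float(values[i]), concave_down=interior)


def peak_mae(peaks: dict, silver: dict) -> float:
    """Mean absolute error between two ROI -> peak-age maps (shared keys)."""
    shared = sorted(set(peaks) & set(silver))
    if not shared:
        raise ValueError("no shared ROI keys between peak maps")
    return float(np.mean([abs(float(peaks[r]) - float(silver[r]))
                          for r in shared]))


def discrete_frechet_points(P: np.ndarray, Q: np.ndarray) -> float:
    """Discrete Fréchet distance between two 2-D polylines (DP recursion)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if len(P) == 0 or len(Q) == 0:
        raise ValueError("empty polyline")
    d = np.sqrt(((P[:, None, :] - Q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]),
                           d[i, j])
    return float(ca[-1, -1])


def discrete_frechet(curveA, curveB) -> float:
    """Fréchet distance between two lifespan curves.

    Curves become 2-D polylines with the age axis min-max normalized to
    [0, 1] and the FA values left raw, so the result is comparable only
    within this parameterization.
    """
    def to_poly(c):
        if isinstance(c, LifespanCurve):
            g, v = c.age_grid, c.values
        else:
            g, v = np.asarray(c[0], dtype=float), np.asarray(c[1], dtype=float)
        if len(g) == 0:
            raise ValueError("empty curve")
        span = g[-1] - g[0]
        gn = (g - g[0]) / span if span > 0 else np.zeros_like(g)
        return np.column_stack([gn, v])
    return discrete_frechet_points(to_poly(curveA), to_poly(curveB))


def _fdr_table(rois, betas, pvals) -> pd.DataFrame:
    pvals = np.asarray(pvals, dtype=float)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame({"roi": rois, "beta": betas, "p": pvals, "q": qvals,
                         "significant": qvals < 0.05})


def _centered_spline_basis(age, n_basis=DEFAULT_N_BASIS):
    B = bspline_design(age, float(age.min()), float(age.max()), n_basis)
    Z = null_space(B.mean(axis=0)[None, :])
    return B @ Z


def sex_effects(features: FeatureTable, covars: CovariateTable,
                n_basis: int = DEFAULT_N_BASIS):
    """Per-ROI sex effect with a spline age adjustment, plus interaction test.

    Model: z(FA) ~ z(sex) + spline(age); the sex beta is the standardized
    coefficient with its OLS p-value. The interaction table tests a
    sex-specific age smooth (F-test of spline x sex columns). Both tables
    are BH-FDR corrected across ROIs.
    """
    check_paired(features, covars)
    if len(set(covars.sex.tolist())) < 2:
        raise ValueError("both sexes must be present")
    if covars.n_subjects < 100:
        raise ValueError("at least 100 subjects are required")
    Bc = _centered_spline_basis(covars.age, n_basis)
    sex_z = (covars.sex - covars.sex.mean()) / covars.sex.std(ddof=1)
    X_main = np.column_stack([np.ones(covars.n_subjects), sex_z, Bc])
    X_int = np.column_stack([X_main, Bc * sex_z[:, None]])
    k_int = Bc.shape[1]
    betas, pvals, ipvals = [], [], []
    for vi in range(features.n_features):
        y = features.values[:, vi]
        sd = y.std(ddof=1)
        yz = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        fit = sm.OLS(yz, X_main).fit()
        betas.append(float(fit.params[1]))
        pvals.append(float(fit.pvalues[1]))
        fit_int = sm.OLS(yz, X_int).fit()
        # F-test that all spline-by-sex coefficients vanish
        R = np.zeros((k_int, X_int.shape[1]))
        R[:, -k_int:] = np.eye(k_int)
        ipvals.append(float(fit_int.f_test(R).pvalue))
    main = _fdr_table(features.feature_names, betas, pvals)
    inter = _fdr_table(features.feature_names, [np.nan] * len(ipvals), ipvals)
    return main, inter


def group_effects(features: FeatureTable, covars: CovariateTable,
                  group: np.ndarray, interaction_threshold: float = 0.05):
    """Per-ROI OLS of a group variable (e.g. allele count) on harmonized FA.

    Covariates: age, sex, age x sex, age^2. Group and outcome are z-scored
    (standardized beta). BH-FDR across ROIs; a group x age interaction model
    is fitted only for ROIs nominally significant (p < threshold) in the
    main model. Returns (main table, interaction table).
    """
    check_paired(features, covars)
    group = np.asarray(group, dtype=float)
    if len(group) != covars.n_subjects:
        raise ValueError("group length mismatch")
    if group.std(ddof=1) == 0:
        raise ValueError("group variable is constant")
    age = covars.age
    sex = covars.sex.astype(float)
    gz = (group - group.mean()) / group.std(ddof=1)
    az = (age - age.mean()) / age.std(ddof=1)
    X = np.column_stack([np.ones(len(age)), gz, az, sex, az * sex, az ** 2])
    names = ["const", "group", "age", "sex", "age:sex", "age^2"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear design; columns: {names}")
    X_int = np.column_stack([X, gz * az])
    betas, pvals = [], []
    for vi in range(features.n_features):
        y = features.values[:, vi]
        sd = y.std(ddof=1)
        yz = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        fit = sm.OLS(yz, X).fit()
        betas.append(float(fit.params[1]))
        pvals.append(float(fit.pvalues[1]))
    main = _fdr_table(features.feature_names, betas, pvals)
    inter_rows = []
    for vi, roi in enumerate(features.feature_names):
        if main.loc[main["roi"] == roi, "p"].iloc[0] >= interaction_threshold:
            continue
        y = features.values[:, vi]
        sd = y.std(ddof=1)
        yz = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        fit = sm.OLS(yz, X_int).fit()
        inter_rows.append({"roi": roi, "beta": float(fit.params[-1]),
                           "p": float(fit.pvalues[-1])})
    inter = pd.DataFrame(inter_rows, columns=["roi", "beta", "p"])
    return main, inter


def _mixed_age_betas(tables: list, rois: list[str]) -> np.ndarray:
    """Standardized age betas from random-intercept mixed models.

    tables: list of (FeatureTable, CovariateTable) waves stacked long; fixed
    effects age, sex, age x sex, age^2; random intercept per subject.
    """
    frames = []
    for ft, ct in tables:
        df = ft.to_frame().reset_index()
        df["age"] = ct.age
        df["sex"] = ct.sex
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    counts = long["subject_id"].value_counts()
    if (counts < 2).all():
        raise ValueError("no subject has 2+ observations; not longitudinal data")
    az = (long["age"] - long["age"].mean()) / long["age"].std(ddof=1)
    sex = long["sex"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(long)), az, sex, az * sex, az ** 2])
    betas = np.empty(len(rois))
    for vi, roi in enumerate(rois):
        y = long[roi].to_numpy(dtype=float)
        yz = (y - y.mean()) / y.std(ddof=1)
        md = sm.MixedLM(yz, X, groups=long["subject_id"])
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            fit = md.fit(reml=True, maxiter=200, disp=False)
        betas[vi] = float(fit.fe_params[1])
    return betas


def longitudinal_age_effects(baseline, followup, bundle: ReferenceBundle,
                             strategies=("raw", "apply_baseline_params",
                                         "fit_separately"),
                             eb: bool = True, min_site_n: int = 10,
                             constant_reference_sd: bool = False):
    """Compare harmonization strategies for two-wave data.

    baseline / followup are (FeatureTable, CovariateTable) pairs sharing
    subject IDs. Strategies: raw (no harmonization), apply_baseline_params
    (site parameters fitted at baseline and reused at follow-up), and
    fit_separately (parameters refitted per wave). Returns a DataFrame of
    standardized age betas per ROI and strategy plus a dict of Pearson
    correlations of each strategy's betas against the raw betas.
    """
    ft0, ct0 = baseline
    ft1, ct1 = followup
    if not set(ft0.subject_ids) & set(ft1.subject_ids):
        raise ValueError("baseline and follow-up share no subject IDs")
    rois = [r for r in ft0.feature_names if r in ft1.feature_names]
    results = {}
    for strat in strategies:
        if strat == "raw":
            tables = [(ft0, ct0), (ft1, ct1)]
        elif strat == "apply_baseline_params":
            model, h0 = fit_site_to_reference(
                ft0, ct0, bundle, eb=eb, min_site_n=min_site_n,
                constant_reference_sd=constant_reference_sd)
            h1 = apply_site_model(model, ft1, ct1, bundle)
            tables = [(h0, ct0), (h1, ct1)]
        elif strat == "fit_separately":
            _, h0 = fit_site_to_reference(
                ft0, ct0, bundle, eb=eb, min_site_n=min_site_n,
                constant_reference_sd=constant_reference_sd)
            _, h1 = fit_site_to_reference(
                ft1, ct1, bundle, eb=eb, min_site_n=min_site_n,
                constant_reference_sd=constant_reference_sd)
            tables = [(h0, ct0), (h1, ct1)]
        else:
            raise ValueError(f"unknown strategy {strat!r}")
        results[strat] = _mixed_age_betas(tables, rois)
    betas = pd.DataFrame(results, index=pd.Index(rois, name="roi"))
    correlations = {}
    if "raw" in results:
        for strat in strategies:
            if strat == "raw":
                continue
            r, _ = sps.pearsonr(results["raw"], results[strat])
            correlations[strat] = float(r)
    return betas, correlations


def acquisition_correlations(site_models: list, acquisition: dict) -> pd.DataFrame:
    """Correlate per-site shift/scale parameters with acquisition parameters.

    acquisition maps site -> numeric value (e.g. voxel volume in mm^3) or
    site -> {param_name: value}. Returns one row per (ROI, parameter) with
    Pearson r and p for the shift (gamma*) and scale (delta*) parameters
    across sites.
    """
    if len(site_models) < 4:
        raise ValueError("at least 4 sites are required")
    first = next(iter(acquisition.values()))
    if not isinstance(first, dict):
        acquisition = {s: {"voxel_volume": v} for s, v in acquisition.items()}
    param_names = sorted(next(iter(acquisition.values())))
    rois = site_models[0].rois
    rows = []
    for pname in param_names:
        x = np.array([float(acquisition[m.site][pname]) for m in site_models])
        if x.std(ddof=1) == 0:
            raise ValueError(f"acquisition parameter {pname!r} is constant")
        def _corr(a, b):
            if np.std(b) == 0:  # degenerate outcome: correlation undefined
                return np.nan, np.nan
            r, p = sps.pearsonr(a, b)
            return float(r), float(p)

        for vi, roi in enumerate(rois):
            shifts = np.array([m.gamma_star[m.rois.index(roi)] for m in site_models])
            scales = np.array([m.delta_star[m.rois.index(roi)] for m in site_models])
            r_s, p_s = _corr(x, shifts)
            r_d, p_d = _corr(x, scales)
            rows.append({"roi": roi, "parameter": pname,
                         "r_shift": float(r_s), "p_shift": float(p_s),
                         "r_scale": float(r_d), "p_scale": float(p_d)})
    return pd.DataFrame(rows)


def train_test_mae(bundle: ReferenceBundle, harmonized_sites: dict,
                   membership: dict):
    """Per-site MAE to the reference mean curve and a train-vs-test t-test.

    harmonized_sites maps site -> (FeatureTable, CovariateTable) of
    reference-harmonized data; membership maps site -> "train" | "test".
    Per subject the absolute deviation from mu_ref(age, sex) is averaged
    into a site-level MAE per ROI; a Welch t-test compares train vs test
    site MAEs per ROI, BH-FDR corrected. Returns (site_mae DataFrame,
    test DataFrame).
    """
    groups = {"train": [], "test": []}
    for site, grp in membership.items():
        if grp not in groups:
            raise ValueError(f"membership for {site!r} must be 'train' or 'test'")
        groups[grp].append(site)
    for grp, sites in groups.items():
        if len(sites) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 sites")
    rois = next(iter(harmonized_sites.values()))[0].feature_names
    mae_rows = []
    for site, (ft, ct) in harmonized_sites.items():
        row = {"site": site, "group": membership[site]}
        for vi, roi in enumerate(rois):
            mu = bundle.mean_at(roi, ct.age, ct.sex)
            row[roi] = float(np.mean(np.abs(ft.values[:, vi] - mu)))
        mae_rows.append(row)
    site_mae = pd.DataFrame(mae_rows)
    pvals, tvals = [], []
    for roi in rois:
        a = site_mae.loc[site_mae["group"] == "train", roi]
        b = site_mae.loc[site_mae["group"] == "test", roi]
        t, p = sps.ttest_ind(a, b, equal_var=False)
        tvals.append(float(t))
        pvals.append(float(p))
    tests = _fdr_table(rois, tvals, pvals).rename(columns={"beta": "t"})
    return site_mae, tests
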