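"""Harmonizing one new site against a stored lifespan reference bundle.

Instead of refitting ComBat over all cohorts when a site joins, each control
subject is standardized against the reference curves,

    Z_jv = (y_jv - mu_ref,v(age_j, sex_j)) / sigma_ref,v(age_j, sex_j),

the site's location/scale effects (gamma*_v, delta*_v) are estimated on Z
with empirical-Bayes pooling across ROIs (the site is a single batch), and
every row — controls and cases — is mapped back through

    y*_jv = sigma_ref,v * (Z_jv - gamma*_v) / delta*_v + mu_ref,v.

Ages outside the reference span are clamped to the span endpoints (spline
extrapolation is unreliable); the clamped count is recorded. A statistical
QC step removes whole subjects with any ROI beyond k site-level SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .combat import _eb_site, DELTA_FLOOR
from .reference import ReferenceBundle
from .tables import FeatureTable, CovariateTable, check_paired


@dataclass
class SiteHarmonizationModel:
    """One site's per-ROI shift/scale relative to a reference bundle."""

    site: str
    rois: list[str]
    gamma_star: np.ndarray      # per-ROI shift, standardized (Z) scale
    delta_star: np.ndarray      # per-ROI scale, > 0
    eb_enabled: bool
    reference_version: str
    constant_reference_sd: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gamma_star = np.asarray(self.gamma_star, dtype=float)
        self.delta_star = np.asarray(self.delta_star, dtype=float)
        if np.any(self.delta_star <= 0):
            raise ValueError("delta_star must be strictly positive")
        if len(self.rois) != len(self.gamma_star) or \
                len(self.rois) != len(self.delta_star):
            raise ValueError("roi list and parameter length mismatch")

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "rois": list(self.rois),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "eb_enabled": bool(self.eb_enabled),
            "reference_version": self.reference_version,
            "constant_reference_sd": bool(self.constant_reference_sd),
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteHarmonizationModel":
        return cls(site=d["site"], rois=list(d["rois"]),
                   gamma_star=np.asarray(d["gamma_star"], dtype=float),
                   delta_star=np.asarray(d["delta_star"], dtype=float),
                   eb_enabled=bool(d["eb_enabled"]),
                   reference_version=d["reference_version"],
                   constant_reference_sd=bool(d.get("constant_reference_sd", False)),
                   diagnostics=dict(d.get("diagnostics", {})))


def qc_outliers(features: FeatureTable, covars: CovariateTable, k: float = 5.0):
    """Remove subjects with any ROI beyond k SD of their own site's mean.

    Site means/SDs are computed on the raw values per (site, ROI); a subject
    is dropped entirely if any single ROI exceeds the threshold. Returns
    (kept FeatureTable, kept CovariateTable, report) where report is a list
    of dicts (subject, roi, z) for every offending value.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    check_paired(features, covars)
    Y = features.values
    removed = np.zeros(features.n_subjects, dtype=bool)
    report = []
    for site in covars.batch_levels:
        rows = np.flatnonzero(covars.batch == site)
        if len(rows) < 3:
            raise ValueError(f"site {site!r} has fewer than 3 subjects")
        mu = Y[rows].mean(axis=0)
        sd = Y[rows].std(axis=0, ddof=1)
        sd = np.maximum(sd, 1e-12)
        z = (Y[rows] - mu) / sd
        bad = np.abs(z) > k
        for r, v in zip(*np.nonzero(bad)):
            report.append({"subject": features.subject_ids[rows[r]],
                           "roi": features.feature_names[v],
                           "z": float(z[r, v])})
            removed[rows[r]] = True
    keep = np.flatnonzero(~removed)
    return features.select_rows(keep), covars.select_rows(keep), report


def _standardize_to_reference(features, covars, bundle, rois,
                              constant_reference_sd=False):
    """Z-scores against the bundle curves; returns (Z, clamped count, sigma)."""
    lo, hi = bundle.age_span
    clamped = int(np.sum((covars.age < lo) | (covars.age > hi)))
    Z = np.empty((features.n_subjects, len(rois)))
    sigma = np.empty_like(Z)
    values = features.select_features(rois).values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for vi, roi in enumerate(rois):
            mu = bundle.mean_at(roi, covars.age, covars.sex)
            sd = bundle.sd_at(roi, covars.age, covars.sex)
            if constant_reference_sd:
                sd = np.full_like(sd, float(np.mean(sd)))
            sigma[:, vi] = sd
            Z[:, vi] = (values[:, vi] - mu) / sd
    return Z, clamped, sigma


def fit_site_to_reference(features: FeatureTable, covars: CovariateTable,
                          bundle: ReferenceBundle, use_controls_only: bool = True,
                          eb: bool = True, min_site_n: int = 10,
                          constant_reference_sd: bool = False):
    """Estimate one site's shift/scale against the bundle and harmonize it.

    Fitting uses control rows only (unless use_controls_only=False); the
    resulting transform is applied to all rows, cases included. Only ROIs
    present in both the table and the bundle are covered; the output contains
    exactly those columns.
    """
    check_paired(features, covars)
    rois = [r for r in features.feature_names if r in bundle.rois]
    if not rois:
        raise ValueError(
            "no ROI columns match the reference bundle; provided "
            f"{features.feature_names}, expected a subset of {bundle.rois}")
    site_labels = set(covars.batch.tolist())
    if len(site_labels) != 1:
        raise ValueError("fit_site_to_reference expects a single site; got "
                         f"{sorted(site_labels, key=str)}")
    site = str(covars.batch[0])
    fit_rows = np.flatnonzero(covars.is_control) if use_controls_only \
        else np.arange(covars.n_subjects)
    if use_controls_only and fit_rows.size == 0:
        raise ValueError("all rows are cases; pass use_controls_only=False "
                         "to fit on cases")
    if fit_rows.size < min_site_n:
        raise ValueError(f"only {fit_rows.size} control rows; "
                         f"min_site_n={min_site_n} required")

    sub_f = features.select_features(rois).select_rows(fit_rows)
    sub_c = covars.select_rows(fit_rows)
    Z, clamped, _ = _standardize_to_reference(sub_f, sub_c, bundle, rois,
                                              constant_reference_sd)
    gamma_hat = Z.mean(axis=0)
    delta_hat = np.maximum(Z.std(axis=0, ddof=1), DELTA_FLOOR)
    if eb and len(rois) >= 2:
        gamma_star, delta_star, hyper = _eb_site(Z, gamma_hat, delta_hat)
        eb_used = not hyper.get("degenerate", False)
    else:
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        eb_used = False
    if clamped:
        warnings.warn(f"{clamped} subject ages clamped to the reference span",
                      stacklevel=2)
    model = SiteHarmonizationModel(
        site=site, rois=rois, gamma_star=gamma_star, delta_star=delta_star,
        eb_enabled=eb_used, reference_version=str(bundle.meta["version"]),
        constant_reference_sd=constant_reference_sd,
        diagnostics={"n_used": int(fit_rows.size),
                     "n_controls": int(covars.is_control.sum()),
                     "n_total": int(covars.n_subjects),
                     "ages_clamped": clamped})
    harmonized = apply_site_model(model, features, covars, bundle)
    return model, harmonized


def apply_site_model(model: SiteHarmonizationModel, features: FeatureTable,
                     covars: CovariateTable, bundle: ReferenceBundle) -> FeatureTable:
    """Deterministically transform data with stored site parameters.

    Pure function of (model, bundle, age, sex, value); no re-estimation.
    """
    check_paired(features, covars)
    if str(bundle.meta["version"]) != model.reference_version:
        raise ValueError(
            f"reference version mismatch: model was fitted against "
            f"{model.reference_version!r} but bundle is "
            f"{bundle.meta['version']!r}")
    unknown = [r for r in features.feature_names if r not in model.rois]
    known = [r for r in features.feature_names if r in model.rois]
    if unknown and not known:
        raise ValueError(f"no ROI overlaps the site model: {unknown}")
    if unknown:
        raise ValueError(f"ROIs not covered by the site model: {unknown}")
    rois = list(features.feature_names)
    idx = [model.rois.index(r) for r in rois]
    Z, _, sigma = _standardize_to_reference(features, covars, bundle, rois,
                                            model.constant_reference_sd)
    adj = (Z - model.gamma_star[idx]) / model.delta_star[idx]
    out = np.empty_like(adj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for vi, roi in enumerate(rois):
            mu = bundle.mean_at(roi, covars.age, covars.sex)
            out[:, vi] = adj[:, vi] * sigma[:, vi] + mu
        return FeatureTable(features.subject_ids, rois, out)
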