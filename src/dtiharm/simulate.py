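"""Synthetic multi-site FA data with known lifespan curves and site effects.

The generating model per site i, subject j, ROI v:

    y = delta_i * ( f_v(age) + sex_offset_v * sex + b_j + eps ) + gamma_i

with f_v a unimodal gamma-shaped lifespan trajectory peaking in young
adulthood, eps ~ N(0, sigma^2) residual noise, and b_j an optional
subject-level random intercept for longitudinal designs. By default the site
scale delta acts on signal plus noise and the shift gamma is additive;
site_effect_on="residual" instead applies delta to the residual only
(y = f + gamma + delta * eps), which is exactly ComBat's location-scale
decomposition and makes (gamma, delta) its identifiable estimands — up to
the size-weighted zero-sum constraint on shifts and the pooled-scale
normalization of scales — so parameter-recovery targets are well defined.

An optional per-site voxel-volume acquisition parameter can be linked to the
site shift (larger voxels -> lower FA) to emulate resolution-driven site
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rois import DEFAULT_ROIS
from .tables import FeatureTable, CovariateTable


@dataclass
class SiteSpec:
    name: str
    n: int
    shift: float = 0.0           # gamma_i, FA units
    scale: float = 1.0           # delta_i, multiplicative
    age_range: tuple = None      # falls back to the config age range
    voxel_volume: float = None   # mm^3, optional acquisition parameter


@dataclass
class CurveParams:
    """f(age) = c0 + c1 * (age/p)^k * exp(k*(1 - age/p)): max c0+c1 at age p."""
    c0: float = 0.40
    c1: float = 0.10
    peak: float = 30.0
    shape: float = 1.5


@dataclass
class SyntheticConfig:
    sites: list = field(default_factory=list)
    age_range: tuple = (3.0, 95.0)
    rois: list = field(default_factory=lambda: list(DEFAULT_ROIS))
    curves: dict = None                # roi -> CurveParams
    sex_offset: dict = None            # roi -> additive male-minus-female offset
    residual_sd: float = 0.02
    prop_male: float = 0.48
    waves: int = 1
    interval: float = 2.25             # years between longitudinal waves
    subject_sd: float = 0.0            # random-intercept SD (FA units)
    slope_factor: float = 1.0          # within-subject slope multiplier
    site_effect_on: str = "signal_plus_noise"  # or "residual"
    seed: int = 0

    def __post_init__(self):
        if not self.sites:
            self.sites = [SiteSpec("siteA", 200), SiteSpec("siteB", 200)]
        self.sites = [s if isinstance(s, SiteSpec) else SiteSpec(**s)
                      for s in self.sites]
        if self.curves is None:
            rng = np.random.default_rng(12345)  # fixed ROI-level truth
            self.curves = {}
            for r in self.rois:
                self.curves[r] = CurveParams(
                    c0=0.35 + 0.10 * rng.random(),
                    c1=0.06 + 0.06 * rng.random(),
                    peak=float(np.clip(30 + 5 * rng.standard_normal(), 22, 38)),
                    shape=1.0 + rng.random())
        if self.sex_offset is None:
            rng = np.random.default_rng(54321)
            self.sex_offset = {r: float(0.005 * rng.standard_normal())
                               for r in self.rois}
        if self.site_effect_on not in ("signal_plus_noise", "residual"):
            raise ValueError("site_effect_on must be 'signal_plus_noise' or "
                             "'residual'")
        for s in self.sites:
            if s.scale <= 0:
                raise ValueError(f"site {s.name}: scale must be > 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        lo, hi = self.age_range
        for r, cp in self.curves.items():
            if not lo <= cp.peak <= hi:
                raise ValueError(f"curve peak for {r} outside age range")


def truth_curve_values(params: CurveParams, age) -> np.ndarray:
    """Evaluate the unimodal lifespan trajectory at the given ages."""
    if params.shape <= 0:
        raise ValueError("shape parameter k must be > 0")
    if params.peak <= 0:
        raise ValueError("peak age must be > 0")
    age = np.asarray(age, dtype=float)
    rel = age / params.peak
    return params.c0 + params.c1 * rel ** params.shape * np.exp(
        params.shape * (1.0 - rel))


def make_truth_curve(params: CurveParams, age_range=(3.0, 95.0), step=0.1):
    """Ground-truth curve on a regular age grid; returns (grid, values)."""
    lo, hi = age_range
    if not lo < params.peak < hi:
        raise ValueError("peak age must lie inside the age range")
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    return grid, truth_curve_values(params, grid)


def simulate_multisite(config: SyntheticConfig):
    """Cross-sectional multi-site tables plus the generating truth record.

    Returns (FeatureTable, CovariateTable, truth) where truth carries every
    generating parameter (site shifts/scales, curve params, sex offsets,
    residual SD, per-subject ages).
    """
    rng = np.random.default_rng(config.seed)
    rois = config.rois
    ids, ages, sexes, batches, vols = [], [], [], [], []
    rows = []
    for s in config.sites:
        lo, hi = s.age_range if s.age_range is not None else config.age_range
        age = rng.uniform(lo, hi, s.n)
        sex = (rng.random(s.n) < config.prop_male).astype(int)
        eps = rng.normal(0.0, config.residual_sd, (s.n, len(rois)))
        clean = np.column_stack([
            truth_curve_values(config.curves[r], age) +
            config.sex_offset[r] * sex
            for r in rois])
        if config.site_effect_on == "residual":
            # scale acts on the residual only: exactly ComBat's location-scale
            # decomposition, so (shift, scale) are its identifiable estimands
            # up to the size-weighted zero-sum / pooled-scale normalization
            y = clean + s.scale * eps + s.shift
        else:
            y = s.scale * (clean + eps) + s.shift
        rows.append(y)
        ids += [f"{s.name}_{j:05d}" for j in range(s.n)]
        ages.append(age)
        sexes.append(sex)
        batches += [s.name] * s.n
        vols += [s.voxel_volume] * s.n
    values = np.vstack(rows)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        features = FeatureTable(ids, rois, values)
    covars = CovariateTable(ids, np.concatenate(ages), np.concatenate(sexes),
                            np.array(batches, dtype=object))
    truth = {
        "sites": {s.name: {"shift": s.shift, "scale": s.scale, "n": s.n,
                           "voxel_volume": s.voxel_volume} for s in config.sites},
        "curves": {r: vars(config.curves[r]) for r in rois},
        "sex_offset": dict(config.sex_offset),
        "residual_sd": config.residual_sd,
        "seed": config.seed,
    }
    return features, covars, truth


def simulate_longitudinal(config: SyntheticConfig):
    """Multi-wave tables sharing subject IDs; returns (waves, truth).

    waves is a list of (FeatureTable, CovariateTable) of length config.waves.
    Subject random intercepts b_j ~ N(0, subject_sd^2) persist across waves;
    wave w is observed at baseline age + w*interval, and the within-subject
    trajectory follows the curve with slope_factor scaling the age-related
    change relative to the cross-sectional curve.
    """
    if config.waves < 2:
        raise ValueError("longitudinal simulation requires waves >= 2")
    rng = np.random.default_rng(config.seed)
    rois = config.rois
    wave_tables = []
    per_site = []
    for s in config.sites:
        lo, hi = s.age_range if s.age_range is not None else config.age_range
        age0 = rng.uniform(lo, hi, s.n)
        sex = (rng.random(s.n) < config.prop_male).astype(int)
        b = rng.normal(0.0, config.subject_sd, s.n) if config.subject_sd > 0 \
            else np.zeros(s.n)
        per_site.append((s, age0, sex, b))
    for w in range(config.waves):
        ids, ages, sexes, batches = [], [], [], []
        rows = []
        for (s, age0, sex, b) in per_site:
            age_w = age0 + w * config.interval
            eps = rng.normal(0.0, config.residual_sd, (s.n, len(rois)))
            clean = np.column_stack([
                truth_curve_values(config.curves[r], age0) +
                config.slope_factor * (
                    truth_curve_values(config.curves[r], age_w) -
                    truth_curve_values(config.curves[r], age0)) +
                config.sex_offset[r] * sex
                for r in rois])
            y = s.scale * (clean + b[:, None] + eps) + s.shift
            rows.append(y)
            ids += [f"{s.name}_{j:05d}" for j in range(s.n)]
            ages.append(age_w)
            sexes.append(sex)
            batches += [s.name] * s.n
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ft = FeatureTable(ids, rois, np.vstack(rows))
        ct = CovariateTable(ids, np.concatenate(ages), np.concatenate(sexes),
                            np.array(batches, dtype=object))
        wave_tables.append((ft, ct))
    truth = {
        "sites": {s.name: {"shift": s.shift, "scale": s.scale, "n": s.n}
                  for s in config.sites},
        "interval": config.interval, "waves": config.waves,
        "subject_sd": config.subject_sd, "slope_factor": config.slope_factor,
        "residual_sd": config.residual_sd, "seed": config.seed,
    }
    return wave_tables, truth


def simulate_from_bundle(bundle, site_name: str, n: int, shift: float = 0.0,
                         scale: float = 1.0, seed: int = 0,
                         age_range=None, rois=None, n_cases: int = 0):
    """Simulate a site whose data follow a stored reference bundle.

    y = mu_ref(age, sex) + shift + scale * sigma_ref(age, sex) * eps with
    eps ~ N(0, 1), so shift/scale are the site's location and scale effects
    relative to the reference. Optional trailing n_cases rows are flagged as
    non-controls (same generating distribution).
    """
    rng = np.random.default_rng(seed)
    rois = list(rois) if rois is not None else list(bundle.rois)
    lo, hi = age_range if age_range is not None else bundle.age_span
    total = n + n_cases
    age = rng.uniform(lo, hi, total)
    sex = (rng.random(total) < 0.5).astype(int)
    values = np.empty((total, len(rois)))
    for vi, roi in enumerate(rois):
        mu = bundle.mean_at(roi, age, sex)
        sd = bundle.sd_at(roi, age, sex)
        values[:, vi] = mu + shift + scale * sd * rng.standard_normal(total)
    ids = [f"{site_name}_{j:05d}" for j in range(total)]
    is_control = np.arange(total) < n
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        ft = FeatureTable(ids, rois, values)
    ct = CovariateTable(ids, age, sex, np.array([site_name] * total, dtype=object),
                        is_control)
    return ft, ct
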