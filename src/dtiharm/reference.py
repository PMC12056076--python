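"""Sex-specific lifespan reference curves via iterative subsampling + ComBat-GAM.

Because ComBat-family fits are weighted by per-site sample size, one huge
cohort would dominate a pooled fit. The builder instead draws balanced
subsamples (default 25 iterations x 200 subjects per dataset where
available), harmonizes each subsample with ComBat-GAM, pools the outputs of
all iterations (a subject may appear several times), and fits per-ROI,
per-sex curves: a penalized-spline mean, an SD curve from a smooth of
squared residuals, and quantile-GAM centile curves sorted pointwise so
centiles never cross.
"""

from __future__ import annotations

import datetime
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combat import fit_combat
from .splines import fit_penalized_spline, fit_quantile_spline
from .tables import FeatureTable, CovariateTable, check_paired

SEX_LABELS = {0: "F", 1: "M"}
DEFAULT_AGE_SPAN = (3.0, 95.0)
DEFAULT_GRID_STEP = 0.1
DEFAULT_QUANTILES = tuple(np.round(np.arange(0.01, 1.0, 0.01), 2))
SD_FLOOR = 1e-4
_SEMVER_RE = re.compile(r"^\d+\.\d+\.\d+([-.+].*)?$")


@dataclass
class SubsamplePlan:
    """Per-iteration row-index draws for every dataset.

    Datasets large enough to supply every iteration without reuse
    (n >= n_iterations * per_iteration_n) are partitioned into disjoint
    blocks; smaller datasets are re-drawn each iteration (without
    replacement within an iteration, capped at the dataset size).
    """

    n_iterations: int
    per_iteration_n: int
    seed: int
    modes: dict            # dataset -> "partition" | "resample"
    indices: dict          # dataset -> list of np.ndarray, one per iteration

    def iteration_indices(self, it: int) -> dict:
        return {name: idx[it] for name, idx in self.indices.items()}


def plan_subsamples(dataset_sizes: dict, n_iterations: int = 25,
                    per_iteration_n: int = 200, seed: int = 0) -> SubsamplePlan:
    """Deterministic subsampling plan for the iterative harmonization."""
    if any(n <= 0 for n in dataset_sizes.values()):
        bad = {k: v for k, v in dataset_sizes.items() if v <= 0}
        raise ValueError(f"nonpositive dataset sizes: {bad}")
    rng = np.random.default_rng(seed)
    modes, indices = {}, {}
    for name in sorted(dataset_sizes):
        n = dataset_sizes[name]
        if n >= n_iterations * per_iteration_n:
            modes[name] = "partition"
            perm = rng.permutation(n)
            indices[name] = [perm[it * per_iteration_n:(it + 1) * per_iteration_n]
                             for it in range(n_iterations)]
        else:
            modes[name] = "resample"
            k = min(per_iteration_n, n)
            indices[name] = [rng.choice(n, size=k, replace=False)
                             for _ in range(n_iterations)]
    return SubsamplePlan(n_iterations, per_iteration_n, seed, modes, indices)


def run_iterative_harmonization(features: FeatureTable, covars: CovariateTable,
                                plan: SubsamplePlan, mode: str = "gam",
                                eb: bool = True, min_site_n: int = 10) -> pd.DataFrame:
    """Harmonize each planned subsample and pool the outputs.

    Returns a long DataFrame with columns [subject_id, iteration, site, age,
    sex] + one column per ROI; rows are the harmonized values of every
    iteration (subjects may repeat across iterations).
    """
    check_paired(features, covars)
    site_rows = {}
    for name in plan.indices:
        rows = np.flatnonzero(covars.batch == name)
        if rows.size == 0:
            raise ValueError(f"plan covers dataset {name!r} absent from the tables")
        site_rows[name] = rows
    pieces = []
    for it in range(plan.n_iterations):
        rows = []
        for name, idx in plan.iteration_indices(it).items():
            if idx.max() >= len(site_rows[name]):
                raise ValueError(f"plan indices exceed dataset {name!r} size")
            if len(idx) < min_site_n:
                raise ValueError(f"iteration {it}: site {name!r} has "
                                 f"{len(idx)} < min_site_n rows")
            rows.append(site_rows[name][idx])
        rows = np.concatenate(rows)
        ft, ct = features.select_rows(rows), covars.select_rows(rows)
        _, harm = fit_combat(ft, ct, mode=mode, eb=eb, min_site_n=min_site_n)
        df = harm.to_frame().reset_index()
        df.insert(1, "iteration", it)
        df.insert(2, "site", ct.batch)
        df.insert(3, "age", ct.age)
        df.insert(4, "sex", ct.sex)
        pieces.append(df)
    return pd.concat(pieces, ignore_index=True)


@dataclass
class LifespanCurve:
    """One fitted curve (mean, sd, or centile) on a regular age grid."""

    roi: str
    sex: str               # "F" or "M"
    role: str              # "mean", "sd", or "centile"
    age_grid: np.ndarray
    values: np.ndarray
    tau: float = None      # centile level when role == "centile"

    def __post_init__(self):
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.age_grid) != len(self.values):
            raise ValueError("age grid and values length mismatch")
        if not np.all(np.diff(self.age_grid) > 0):
            raise ValueError("age grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite curve values")
        if self.role == "sd" and np.any(self.values <= 0):
            raise ValueError("sd curve must be strictly positive")


def _age_grid(span, step=DEFAULT_GRID_STEP):
    lo, hi = span
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def fit_lifespan_curves(pooled: pd.DataFrame, rois: list[str],
                        quantile_grid=DEFAULT_QUANTILES,
                        age_span=None, grid_step=DEFAULT_GRID_STEP,
                        min_rows_per_sex: int = 50) -> dict:
    """Per-(ROI, sex) mean, SD, and centile curves from pooled harmonized data.

    pooled must carry `age`, `sex` (0/1) and one column per ROI. Centile
    curves are quantile-regression splines fitted independently per tau and
    then sorted pointwise across tau to enforce non-crossing; the count of
    grid points reordered by the sort is recorded per curve set.
    """
    quantile_grid = [float(t) for t in quantile_grid]
    if any(not 0.0 < t < 1.0 for t in quantile_grid):
        raise ValueError("quantile grid must lie strictly inside (0, 1)")
    quantile_grid = sorted(quantile_grid)
    sexes = sorted(set(pooled["sex"].tolist()))
    if set(sexes) != {0, 1}:
        raise ValueError("both sexes must be present in the pooled data")
    if age_span is None:
        age_span = (float(pooled["age"].min()), float(pooled["age"].max()))
    grid = _age_grid(age_span, grid_step)
    curve_sets = {}
    for roi in rois:
        curve_sets[roi] = {}
        for sex_code in (0, 1):
            sub = pooled[pooled["sex"] == sex_code]
            if len(sub) < min_rows_per_sex:
                raise ValueError(f"fewer than {min_rows_per_sex} rows for "
                                 f"sex={SEX_LABELS[sex_code]} ({len(sub)})")
            age = sub["age"].to_numpy(dtype=float)
            y = sub[roi].to_numpy(dtype=float)
            lo, hi = age_span
            mean_fit = fit_penalized_spline(age, y, lo=lo, hi=hi)
            mean_curve = mean_fit.predict(grid)
            resid = y - mean_fit.predict(age)
            sd_fit = fit_penalized_spline(age, resid ** 2, lo=lo, hi=hi)
            sd_curve = np.sqrt(np.maximum(sd_fit.predict(grid), SD_FLOOR ** 2))
            cent = np.empty((len(quantile_grid), len(grid)))
            for ti, tau in enumerate(quantile_grid):
                qf = fit_quantile_spline(age, y, tau, lo=lo, hi=hi,
                                         alpha=mean_fit.alpha)
                cent[ti] = qf.predict(grid)
            sorted_cent = np.sort(cent, axis=0)
            presort_violations = int((cent != sorted_cent).sum() // 2)
            curve_sets[roi][SEX_LABELS[sex_code]] = {
                "age_grid": grid,
                "mean": mean_curve,
                "sd": sd_curve,
                "centiles": {tau: sorted_cent[ti]
                             for ti, tau in enumerate(quantile_grid)},
                "presort_violations": presort_violations,
            }
    return curve_sets


@dataclass
class ReferenceBundle:
    """Versioned per-ROI, per-sex lifespan mean/SD/centile curves."""

    rois: list[str]
    curves: dict           # roi -> "F"/"M" -> {age_grid, mean, sd, centiles}
    age_span: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        version = self.meta.get("version")
        if not version or not _SEMVER_RE.match(str(version)):
            raise ValueError("meta.version missing or not semantic-version "
                             f"formatted: {version!r}")
        for roi in self.rois:
            if roi not in self.curves:
                raise ValueError(f"missing curves for ROI {roi!r}")
            for sex in ("F", "M"):
                if sex not in self.curves[roi]:
                    raise ValueError(f"missing sex {sex!r} for ROI {roi!r}")
                cs = self.curves[roi][sex]
                grid = np.asarray(cs["age_grid"], dtype=float)
                mean = np.asarray(cs["mean"], dtype=float)
                sd = np.asarray(cs["sd"], dtype=float)
                if not np.all(np.diff(grid) > 0):
                    raise ValueError(f"{roi}/{sex}: age grid not strictly increasing")
                if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(sd))):
                    raise ValueError(f"{roi}/{sex}: non-finite curve values")
                if np.any(sd <= 0):
                    raise ValueError(f"{roi}/{sex}: sd curve not strictly positive")
                taus = sorted(cs["centiles"])
                if taus:
                    stack = np.vstack([np.asarray(cs["centiles"][t], dtype=float)
                                       for t in taus])
                    if np.any(np.diff(stack, axis=0) < -1e-10):
                        raise ValueError(f"{roi}/{sex}: crossing centile curves")
                    med = min(taus, key=lambda t: abs(t - 0.5))
                    if abs(med - 0.5) < 0.05:
                        medc = np.asarray(cs["centiles"][med], dtype=float)
                        if np.any(np.abs(medc - mean) > 3 * sd):
                            raise ValueError(f"{roi}/{sex}: median centile "
                                             "further than 3 SD from the mean curve")

    def _curve(self, roi, sex_label, key):
        return (np.asarray(self.curves[roi][sex_label]["age_grid"], dtype=float),
                np.asarray(self.curves[roi][sex_label][key], dtype=float))

    def _interp(self, roi, key, age, sex):
        age = np.atleast_1d(np.asarray(age, dtype=float))
        sex = np.atleast_1d(np.asarray(sex, dtype=int))
        lo, hi = self.age_span
        if np.any(age < lo) or np.any(age > hi):
            warnings.warn("ages outside the reference span are clamped to the "
                          "endpoints", stacklevel=3)
        out = np.empty(len(age))
        for code, label in SEX_LABELS.items():
            rows = sex == code
            if rows.any():
                grid, vals = self._curve(roi, label, key)
                out[rows] = np.interp(np.clip(age[rows], lo, hi), grid, vals)
        return out

    def mean_at(self, roi, age, sex):
        """Reference mean curve interpolated at (age, sex); ages are clamped."""
        return self._interp(roi, "mean", age, sex)

    def sd_at(self, roi, age, sex):
        """Reference SD curve interpolated at (age, sex); ages are clamped."""
        return self._interp(roi, "sd", age, sex)

    def centile_curve(self, roi, sex_label, tau) -> LifespanCurve:
        taus = sorted(self.curves[roi][sex_label]["centiles"])
        match = min(taus, key=lambda t: abs(t - tau))
        grid, vals = self._curve(roi, sex_label, "centiles")[0], None
        vals = np.asarray(self.curves[roi][sex_label]["centiles"][match], dtype=float)
        grid = np.asarray(self.curves[roi][sex_label]["age_grid"], dtype=float)
        return LifespanCurve(roi, sex_label, "centile", grid, vals, tau=match)

    def mean_curve(self, roi, sex_label) -> LifespanCurve:
        grid, vals = self._curve(roi, sex_label, "mean")
        return LifespanCurve(roi, sex_label, "mean", grid, vals)


def assemble_reference(curve_sets: dict, meta: dict,
                       age_span=None) -> ReferenceBundle:
    """Validate fitted curve sets and package them with version metadata."""
    rois = sorted(curve_sets)
    required = {"version"}
    missing = required - set(meta)
    if missing:
        raise ValueError(f"meta is missing required keys: {sorted(missing)}")
    meta = dict(meta)
    meta.setdefault("created", datetime.datetime.now(datetime.timezone.utc)
                    .isoformat(timespec="seconds"))
    meta.setdefault("datasets", [])
    grids = []
    total_viol = 0
    for roi in rois:
        for sex, cs in curve_sets[roi].items():
            grids.append(np.asarray(cs["age_grid"], dtype=float))
            total_viol += int(cs.get("presort_violations", 0))
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("all ROIs must share the same age grid")
    if total_viol:
        warnings.warn(f"{total_viol} centile grid points required pointwise "
                      "reordering to enforce non-crossing", stacklevel=2)
    if age_span is None:
        age_span = (float(grids[0][0]), float(grids[0][-1]))
    meta.setdefault("age_span", list(age_span))
    first_cs = next(iter(curve_sets[rois[0]].values()))
    meta.setdefault("quantile_grid", sorted(first_cs["centiles"]))
    return ReferenceBundle(rois=rois, curves=curve_sets,
                           age_span=tuple(age_span), meta=meta)
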