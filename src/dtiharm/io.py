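"""File formats, provenance logging, and QC plotting.

CSV dialects: the ROI table is wide (subject ID column first, one numeric
column per ROI, matching the combined-measure abbreviations exactly and
case-sensitively); demographics carry id, age, sex, site and an optional
control flag. The reference bundle and site model serialize to JSON at full
double precision. Every harmonization run emits a plain-text provenance log
naming the reference version, the ROI subset, and who ran the tool when.
"""

from __future__ import annotations

import datetime
import getpass
import json
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._rois import DEFAULT_ROIS
from .reference import ReferenceBundle
from .site import SiteHarmonizationModel
from .tables import FeatureTable, CovariateTable, parse_sex


def read_roi_table(path) -> FeatureTable:
    """Read a wide ROI CSV (first column = subject ID, rest numeric).

    Column names not in the default ROI vocabulary are kept but flagged with
    a warning; name matching downstream is case-sensitive exact.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    ids = df[id_col].tolist()
    if len(set(ids)) != len(ids):
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"repeated subject ID {dup!r} in {path}")
    feature_names = list(df.columns[1:])
    unknown = [c for c in feature_names if c not in DEFAULT_ROIS]
    if unknown:
        warnings.warn(f"unrecognized ROI columns kept as-is: {unknown}",
                      stacklevel=2)
    values = np.empty((len(df), len(feature_names)))
    for ci, col in enumerate(feature_names):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise ValueError(f"non-numeric or missing cell at row {row + 2}, "
                             f"column {col!r} in {path}")
        values[:, ci] = numeric.to_numpy(dtype=float)
    return FeatureTable(ids, feature_names, values)


def write_roi_table(features: FeatureTable, path) -> None:
    df = features.to_frame().reset_index()
    df.to_csv(path, index=False, float_format="%.17g")


def read_demographics(path, column_map: dict | None = None) -> CovariateTable:
    """Read a demographics CSV into a CovariateTable.

    column_map may rename {id, age, sex, site, is_control} to the file's
    column names; unmapped extra numeric columns become extras. Sex accepts
    M/F, male/female, or 0/1. Without a control column all rows are controls.
    """
    cmap = {"id": None, "age": "age", "sex": "sex", "site": "site",
            "is_control": "is_control"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    if cmap["id"] is None:  # accept either conventional ID header
        cmap["id"] = "subject_id" if "subject_id" in df.columns else "id"
    for key in ("id", "age", "sex", "site"):
        if cmap[key] not in df.columns:
            raise ValueError(f"demographics file is missing mandatory column "
                             f"{cmap[key]!r} (for {key})")
    df[cmap["id"]] = df[cmap["id"]].astype(str)
    sex = np.array([parse_sex(v) for v in df[cmap["sex"]]])
    if cmap["is_control"] in df.columns:
        ctrl = df[cmap["is_control"]].astype(float).to_numpy() > 0
    else:
        ctrl = np.ones(len(df), dtype=bool)
    used = {cmap[k] for k in cmap}
    extra_cols = [c for c in df.columns if c not in used]
    extras = None
    if extra_cols:
        numeric = df[extra_cols].apply(pd.to_numeric, errors="coerce")
        keep = [c for c in extra_cols if not numeric[c].isna().any()]
        extras = numeric[keep] if keep else None
    return CovariateTable(df[cmap["id"]].tolist(),
                          df[cmap["age"]].to_numpy(dtype=float),
                          sex, df[cmap["site"]].to_numpy(dtype=object),
                          ctrl, extras)


def write_reference_bundle(bundle: ReferenceBundle, path) -> None:
    """Serialize a bundle to JSON at full double precision."""
    curves = {}
    for roi, by_sex in bundle.curves.items():
        curves[roi] = {}
        for sex, cs in by_sex.items():
            curves[roi][sex] = {
                "age_grid": np.asarray(cs["age_grid"]).tolist(),
                "mean": np.asarray(cs["mean"]).tolist(),
                "sd": np.asarray(cs["sd"]).tolist(),
                "centiles": {repr(float(t)): np.asarray(v).tolist()
                             for t, v in cs["centiles"].items()},
            }
    payload = {"meta": dict(bundle.meta), "curves": curves}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_reference_bundle(path) -> ReferenceBundle:
    """Read and validate a reference bundle JSON; errors name the JSON path."""
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("meta", "curves"):
        if key not in payload:
            raise ValueError(f"schema violation at $.{key}: missing")
    meta = payload["meta"]
    if "version" not in meta:
        raise ValueError("schema violation at $.meta.version: missing")
    curves = {}
    for roi, by_sex in payload["curves"].items():
        curves[roi] = {}
        for sex, cs in by_sex.items():
            for key in ("age_grid", "mean", "sd", "centiles"):
                if key not in cs:
                    raise ValueError(f"schema violation at "
                                     f"$.curves.{roi}.{sex}.{key}: missing")
            curves[roi][sex] = {
                "age_grid": np.asarray(cs["age_grid"], dtype=float),
                "mean": np.asarray(cs["mean"], dtype=float),
                "sd": np.asarray(cs["sd"], dtype=float),
                "centiles": {float(t): np.asarray(v, dtype=float)
                             for t, v in cs["centiles"].items()},
            }
    span = meta.get("age_span")
    if span is None:
        any_grid = next(iter(next(iter(curves.values())).values()))["age_grid"]
        span = [float(any_grid[0]), float(any_grid[-1])]
    return ReferenceBundle(rois=sorted(curves), curves=curves,
                           age_span=tuple(span), meta=meta)


def write_site_model(model: SiteHarmonizationModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def read_site_model(path) -> SiteHarmonizationModel:
    with open(path) as fh:
        return SiteHarmonizationModel.from_dict(json.load(fh))


def write_provenance_log(path, reference_version: str, rois: list[str],
                         inputs: list[str], counts: dict,
                         tool_version: str = None) -> None:
    """Plain-text provenance record: who ran what against which reference."""
    from . import __version__
    try:
        user = getpass.getuser()
    except Exception:
        user = os.environ.get("USER", "unknown")
    lines = [
        f"timestamp: {datetime.datetime.now(datetime.timezone.utc).isoformat(timespec='seconds')}",
        f"user: {user}",
        f"tool_version: {tool_version or __version__}",
        f"reference_version: {reference_version}",
        f"rois: {','.join(rois)}",
        f"inputs: {','.join(str(i) for i in inputs)}",
    ]
    for key, val in counts.items():
        lines.append(f"{key}: {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def combine_hemispheres(left: np.ndarray, right: np.ndarray,
                        n_voxels_left, n_voxels_right) -> np.ndarray:
    """Voxel-count-weighted average of per-hemisphere ROI values.

    Helper for upstream tables that still carry lateralized columns; the
    harmonization itself consumes already-combined measures.
    """
    wl = np.asarray(n_voxels_left, dtype=float)
    wr = np.asarray(n_voxels_right, dtype=float)
    return (np.asarray(left) * wl + np.asarray(right) * wr) / (wl + wr)


def render_qc(roi: str, site: str, pre: FeatureTable, post: FeatureTable,
              covars: CovariateTable, bundle: ReferenceBundle,
              out_dir, sex_label: str = "F") -> str | None:
    """Write one QC scatter/line plot: pre vs post data over the reference.

    Best-effort: failures are logged as warnings and never abort
    harmonization. Returns the written path or None.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vi = pre.feature_names.index(roi)
        grid = np.asarray(bundle.curves[roi][sex_label]["age_grid"], dtype=float)
        mean = np.asarray(bundle.curves[roi][sex_label]["mean"], dtype=float)
        sd = np.asarray(bundle.curves[roi][sex_label]["sd"], dtype=float)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.fill_between(grid, mean - 1.6449 * sd, mean + 1.6449 * sd,
                        color="0.85", label="reference 5-95%")
        ax.plot(grid, mean, color="0.4", lw=1.5, label="reference mean")
        order = np.argsort(covars.age)
        ax.plot(covars.age[order], pre.values[order, vi], ".", ms=3,
                color="tab:red", alpha=0.6, label="pre")
        ax.plot(covars.age[order], post.values[order, vi], ".", ms=3,
                color="tab:blue", alpha=0.6, label="post")
        ax.set_xlabel("age (years)")
        ax.set_ylabel(f"{roi} FA")
        ax.set_title(f"{site}: {roi}")
        ax.set_xlim(grid[0], grid[-1])
        ax.legend(fontsize=7)
        out = Path(out_dir) / f"{site}_{roi}_qc.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        return str(out)
    except Exception as exc:  # pragma: no cover - best effort path
        warnings.warn(f"QC plot for {roi} failed: {exc}", stacklevel=2)
        return None


def export_curve_csv(bundle: ReferenceBundle, roi: str, sex_label: str,
                     path) -> None:
    """Curve CSV export: age_grid, mean, sd, one column per centile tau."""
    cs = bundle.curves[roi][sex_label]
    df = pd.DataFrame({"age": np.asarray(cs["age_grid"], dtype=float),
                       "mean": np.asarray(cs["mean"], dtype=float),
                       "sd": np.asarray(cs["sd"], dtype=float)})
    for tau in sorted(cs["centiles"]):
        df[f"q{tau}"] = np.asarray(cs["centiles"][tau], dtype=float)
    df.to_csv(path, index=False, float_format="%.17g")
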