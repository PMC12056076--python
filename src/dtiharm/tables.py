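"""Domain containers: subject x ROI feature matrix and per-subject covariates.

Both types wrap a pandas DataFrame and enforce the structural invariants that
downstream estimators rely on (unique IDs, finite values, aligned rows).
Sex is coded female = 0, male = 1 throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_FEMALE = 0
SEX_MALE = 1

_SEX_ALIASES = {
    "f": SEX_FEMALE, "female": SEX_FEMALE, "0": SEX_FEMALE, "0.0": SEX_FEMALE,
    "m": SEX_MALE, "male": SEX_MALE, "1": SEX_MALE, "1.0": SEX_MALE,
}


def parse_sex(value) -> int:
    """Map M/F, male/female, 0/1 (any case, str or numeric) to the 0/1 coding."""
    key = str(value).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"unparseable sex value: {value!r}")
    return _SEX_ALIASES[key]


@dataclass
class FeatureTable:
    """Subjects x ROI matrix of FA values (dimensionless, nominally in [0, 1])."""

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, v = self.values.shape
        if n != len(self.subject_ids):
            raise ValueError(
                f"row count {n} != number of subject IDs {len(self.subject_ids)}")
        if v != len(self.feature_names):
            raise ValueError(
                f"column count {v} != number of feature names {len(self.feature_names)}")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicated subject IDs")
        if len(set(self.feature_names)) != v:
            raise ValueError("duplicated feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            warnings.warn("FA values outside [0, 1] encountered", stacklevel=2)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.feature_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_features(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.subject_ids, list(names), self.values[:, idx])

    def select_rows(self, row_idx) -> "FeatureTable":
        row_idx = np.asarray(row_idx)
        ids = [self.subject_ids[i] for i in row_idx]
        return FeatureTable(ids, self.feature_names, self.values[row_idx])


@dataclass
class CovariateTable:
    """Per-subject age (years), sex (F=0/M=1), site label, control flag, extras."""

    subject_ids: list[str]
    age: np.ndarray
    sex: np.ndarray
    batch: np.ndarray
    is_control: np.ndarray = None
    extras: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.subject_ids = [str(s) for s in self.subject_ids]
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicated subject IDs")
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        self.batch = np.asarray(self.batch, dtype=object)
        if self.is_control is None:
            self.is_control = np.ones(n, dtype=bool)
        self.is_control = np.asarray(self.is_control, dtype=bool)
        for name, arr in (("age", self.age), ("sex", self.sex),
                          ("batch", self.batch), ("is_control", self.is_control)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} subjects")
        if not np.all(np.isfinite(self.age)) or np.any(self.age <= 0):
            raise ValueError("ages must be finite and > 0")
        if not np.all(np.isin(self.sex, [SEX_FEMALE, SEX_MALE])):
            raise ValueError("sex must be coded 0 (female) / 1 (male)")
        if self.extras is not None and len(self.extras) != n:
            raise ValueError("extras row count mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def batch_levels(self) -> list:
        return sorted(set(self.batch.tolist()), key=str)

    def select_rows(self, row_idx) -> "CovariateTable":
        row_idx = np.asarray(row_idx)
        extras = None if self.extras is None else self.extras.iloc[row_idx].reset_index(drop=True)
        return CovariateTable(
            [self.subject_ids[i] for i in row_idx],
            self.age[row_idx], self.sex[row_idx], self.batch[row_idx],
            self.is_control[row_idx], extras)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "subject_id": self.subject_ids, "age": self.age, "sex": self.sex,
            "site": self.batch, "is_control": self.is_control.astype(int)})
        if self.extras is not None:
            df = pd.concat([df, self.extras.reset_index(drop=True)], axis=1)
        return df


def check_paired(features: FeatureTable, covars: CovariateTable) -> None:
    """Require one-to-one subject alignment between a feature and covariate table."""
    if features.subject_ids != covars.subject_ids:
        raise ValueError("feature and covariate tables are not aligned by subject ID")
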