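"""Core in-memory containers shared across the pipeline.

Every platform matrix travels as an :class:`OmicsMatrix` — a feature-by-sample
pandas DataFrame plus a platform tag and a value-domain contract (methylation
beta values live on [0, 1], count-like expression is non-negative, protein
abundance is real-valued).  Survival and clinical annotations travel as thin
wrappers over DataFrames keyed by patient id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "ValueDomain",
    "OmicsMatrix",
    "SurvivalTable",
    "ClinicalTable",
    "Partition",
    "DOMAIN_OF_PLATFORM",
]

# canonical platform names
PLATFORMS = ("methylation", "protein", "mirna", "mrna", "pathway")
Platform = str

VALUE_DOMAINS = ("unit_interval", "nonnegative", "real")
ValueDomain = str

DOMAIN_OF_PLATFORM: Mapping[str, str] = {
    "methylation": "unit_interval",
    "mrna": "nonnegative",
    "mirna": "nonnegative",
    "protein": "real",
    "pathway": "real",
}


class FormatError(ValueError):
    """A file or table violates the expected dialect."""


class DomainError(ValueError):
    """Values violate the platform's value-domain contract."""


@dataclass
class OmicsMatrix:
    """Feature-by-sample numeric matrix for one molecular platform.

    Parameters
    ----------
    platform : str
        One of ``methylation``, ``protein``, ``mirna``, ``mrna``, ``pathway``.
    values : pandas.DataFrame
        Rows are features, columns are samples.  NaN marks missing values.
    value_domain : str, optional
        ``unit_interval`` / ``nonnegative`` / ``real``.  Defaults to the
        canonical domain of the platform.
    """

    platform: Platform
    values: pd.DataFrame
    value_domain: ValueDomain = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.value_domain is None:
            self.value_domain = DOMAIN_OF_PLATFORM[self.platform]
        if self.value_domain not in VALUE_DOMAINS:
            raise ValueError(f"unknown value domain {self.value_domain!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        self.values = self.values.astype(float).rename_axis(
            index="feature_id", columns=None)
        self._check_domain()

    def _check_domain(self) -> None:
        arr = self.values.to_numpy()
        finite = arr[np.isfinite(arr)]
        if self.value_domain == "unit_interval":
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                r, c = self._first_violation(lambda v: (v < 0) | (v > 1))
                raise DomainError(
                    f"{self.platform}: value {self.values.iat[r, c]} at "
                    f"feature {self.values.index[r]!r}, sample "
                    f"{self.values.columns[c]!r} outside [0, 1]"
                )
        elif self.value_domain == "nonnegative":
            if finite.size and finite.min() < 0.0:
                r, c = self._first_violation(lambda v: v < 0)
                raise DomainError(
                    f"{self.platform}: negative value {self.values.iat[r, c]} at "
                    f"feature {self.values.index[r]!r}, sample "
                    f"{self.values.columns[c]!r}"
                )

    def _first_violation(self, bad):
        arr = self.values.to_numpy()
        mask = np.isfinite(arr) & bad(arr)
        rows, cols = np.nonzero(mask)
        return int(rows[0]), int(cols[0])

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.platform, self.values.loc[list(feature_ids)],
                           self.value_domain)

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.platform, self.values[list(sample_ids)],
                           self.value_domain)


@dataclass
class SurvivalTable:
    """Right-censored overall survival: one row per patient.

    ``event`` is 0 for alive/censored, 1 for death; ``time_days`` is the
    follow-up or survival time in days and must be strictly positive.
    """

    data: pd.DataFrame  # index patient_id, columns event, time_days

    def __post_init__(self) -> None:
        required = {"event", "time_days"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"survival table needs columns {sorted(required)}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate patient ids in survival table")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            bad = sorted(set(ev) - {0, 1})
            raise FormatError(f"event values outside {{0,1}}: {bad[:5]}")
        t = self.data["time_days"].to_numpy(dtype=float)
        if (t <= 0).any():
            raise FormatError("time_days must be strictly positive")
        self.data = self.data.assign(event=self.data["event"].astype(int),
                                     time_days=t)

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def time(self) -> np.ndarray:
        return self.data["time_days"].to_numpy()

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, patient_ids) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(patient_ids)].copy())


@dataclass
class ClinicalTable:
    """Clinical variables per patient with declared kinds.

    ``kinds`` maps each variable name to ``"quantitative"`` or
    ``"categorical"``.  Missing values are NaN/None.
    """

    data: pd.DataFrame  # index patient_id
    kinds: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate patient ids in clinical table")
        for name, kind in self.kinds.items():
            if kind not in ("quantitative", "categorical"):
                raise ValueError(f"variable {name!r} has unknown kind {kind!r}")

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    def variable(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown clinical variable {name!r}")
        return self.data[name]


@dataclass
class Partition:
    """A clustering result: method, cluster count and a label per sample.

    Labels are integers 1..k and every cluster is non-empty.
    """

    method: str
    k: int
    labels: pd.Series  # index sample_id, values 1..k
    quality: float = float("nan")

    def __post_init__(self) -> None:
        lab = self.labels.to_numpy()
        present = set(int(v) for v in np.unique(lab))
        expected = set(range(1, self.k + 1))
        if present != expected:
            raise ValueError(
                f"partition labels {sorted(present)} do not cover 1..{self.k}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index

    def cluster_members(self, c: int) -> pd.Index:
        return self.labels.index[self.labels == c]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()
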