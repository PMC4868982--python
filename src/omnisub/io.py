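"""Reading, validating, filtering and aligning cohort tables.

File dialects
-------------
* Matrix TSV: header row, first column ``feature_id``, remaining columns are
  sample ids; one numeric value per cell, empty/NA for missing.
* Survival TSV: columns ``patient_id``, ``vital_status`` (0 alive/censored,
  1 dead) and ``days`` (positive).
* Sample-type sidecar TSV: columns ``sample_id``, ``sample_type`` with values
  in {primary, recurrent, normal, blood}.
* Clinical TSV: ``patient_id`` plus one column per variable; kinds declared
  separately (or via a ``kind:<name>`` header suffix convention in YAML
  configs).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .containers import (ClinicalTable, FormatError, OmicsMatrix,
                         SurvivalTable)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_survival",
    "read_clinical",
    "read_sample_types",
    "filter_cohort",
    "summarize_clinical",
    "harmonize_samples",
    "impute_missing",
    "EmptyCohortError",
]

SAMPLE_TYPES = ("primary", "recurrent", "normal", "blood")
# TCGA-style barcode sample-type codes
_BARCODE_TYPE = {"01": "primary", "02": "recurrent", "11": "normal",
                 "10": "blood"}


class EmptyCohortError(ValueError):
    """Cohort filtering removed every sample."""


def read_matrix(path: str | Path, platform: str) -> OmicsMatrix:
    """Read a Matrix TSV; the value domain follows from the platform."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    # cells that were non-empty text but failed to parse are format errors
    bad = numeric.isna() & df.notna() & ~df.isin(["NA", "NaN", "nan", ""])
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        raise FormatError(
            f"{path.name}: non-numeric cell at feature {df.index[rows[0]]!r}, "
            f"sample {df.columns[cols[0]]!r}: {df.iat[rows[0], cols[0]]!r}")
    return OmicsMatrix(platform, numeric)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(Path(path), sep="\t", index_label="feature_id")


def read_survival(path: str | Path) -> Tuple[SurvivalTable, int]:
    """Read a Survival TSV; returns the table and the dropped-row count.

    Rows with missing status or days are dropped (and counted); an event
    value outside {0, 1} or non-positive days is a format error.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    try:
        pid = cols["patient_id"]
        status = cols.get("vital_status", cols.get("event"))
        days = cols.get("days", cols.get("time_days"))
        if status is None or days is None:
            raise KeyError
    except KeyError:
        raise FormatError(
            "survival TSV needs columns patient_id, vital_status, days")
    ev = pd.to_numeric(df[status], errors="coerce")
    tm = pd.to_numeric(df[days], errors="coerce")
    keep = ev.notna() & tm.notna()
    n_dropped = int((~keep).sum())
    ev, tm, ids = ev[keep], tm[keep], df[pid][keep]
    if not ev.isin([0, 1]).all():
        bad = sorted(set(ev) - {0, 1})
        raise FormatError(f"vital_status outside {{0,1}}: {bad[:5]}")
    out = pd.DataFrame({"event": ev.astype(int).to_numpy(),
                        "time_days": tm.to_numpy(dtype=float)},
                       index=pd.Index(ids.astype(str), name="patient_id"))
    return SurvivalTable(out), n_dropped


def read_clinical(path: str | Path,
                  kinds: Mapping[str, str] | None = None) -> ClinicalTable:
    """Read a clinical TSV; quantitative variables are parsed numerically."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    kinds = dict(kinds or {})
    for name in df.columns:
        kind = kinds.get(name)
        if kind is None:
            parsed = pd.to_numeric(df[name], errors="coerce")
            kind = "quantitative" if parsed.notna().mean() > 0.5 else "categorical"
            kinds[name] = kind
        if kind == "quantitative":
            df[name] = pd.to_numeric(df[name], errors="coerce")
    return ClinicalTable(df, kinds)


def read_sample_types(path: str | Path) -> Dict[str, str]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if not {"sample_id", "sample_type"}.issubset(df.columns):
        raise FormatError("sidecar TSV needs columns sample_id, sample_type")
    bad = set(df["sample_type"]) - set(SAMPLE_TYPES)
    if bad:
        raise FormatError(f"unknown sample types: {sorted(bad)}")
    return dict(zip(df["sample_id"], df["sample_type"]))


def sample_type_from_barcode(sample_id: str) -> str:
    """Sample type from a TCGA-style barcode (4th field carries the code)."""
    parts = sample_id.split("-")
    if len(parts) >= 4:
        code = parts[3][:2]
        if code in _BARCODE_TYPE:
            return _BARCODE_TYPE[code]
    raise FormatError(f"cannot infer sample type from id {sample_id!r}")


def filter_cohort(matrix: OmicsMatrix, survival: SurvivalTable,
                  sample_type_of: Mapping[str, str] | Callable[[str], str],
                  ) -> Tuple[OmicsMatrix, SurvivalTable]:
    """Apply the cohort inclusion rules and align matrix with survival.

    Retains exactly the samples that are (a) primary tumor, (b) present in
    the survival table and (c) not wholly missing.  Output sample order
    follows the matrix.  Raises :class:`EmptyCohortError` when nothing
    survives.
    """
    if callable(sample_type_of):
        type_of = {s: sample_type_of(s) for s in matrix.sample_ids}
    else:
        type_of = dict(sample_type_of)
    missing = [s for s in matrix.sample_ids if s not in type_of]
    if missing:
        raise FormatError(f"no sample type for samples {missing[:5]}")

    surv_ids = set(survival.patient_ids)
    all_missing = matrix.values.isna().all(axis=0)
    keep = [s for s in matrix.sample_ids
            if type_of[s] == "primary" and s in surv_ids
            and not bool(all_missing[s])]
    if not keep:
        raise EmptyCohortError(
            "no primary-tumor samples with survival remain after filtering")
    return matrix.subset_samples(keep), survival.subset(keep)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * ndigits),
                                           rounding=ROUND_HALF_UP))


def summarize_clinical(table: ClinicalTable, variable: str,
                       ) -> List[Tuple[str, int, float]]:
    """Category counts and percentages for one categorical variable.

    Percentages are over *all* patients — missing values form their own
    ``missing`` category — and are rounded half-up to one decimal, matching
    the printed style of cohort summaries (e.g. 281/599 -> 46.9).
    """
    if variable not in table.data.columns:
        raise KeyError(f"unknown clinical variable {variable!r}")
    if table.kinds.get(variable) == "quantitative":
        raise ValueError(f"variable {variable!r} is quantitative")
    values = table.data[variable]
    total = len(values)
    counts = values.value_counts(dropna=True).to_dict()
    n_missing = int(values.isna().sum())
    rows = [(str(cat), int(cnt), _round_half_up(100.0 * cnt / total))
            for cat, cnt in sorted(counts.items(), key=lambda kv: str(kv[0]))]
    if n_missing:
        rows.append(("missing", n_missing,
                     _round_half_up(100.0 * n_missing / total)))
    return rows


@dataclass
class Harmonized:
    """Per-matrix aligned views plus the pairwise shared-sample sets."""

    aligned: Dict[str, Tuple[OmicsMatrix, SurvivalTable]]
    shared: Dict[Tuple[str, str], List[str]]
    counts: Dict[str, int]


def harmonize_samples(matrices: Mapping[str, OmicsMatrix],
                      survival: SurvivalTable) -> Harmonized:
    """Restrict every matrix to samples with survival; report shared sets.

    Empty pairwise intersections are allowed and simply reported empty.
    """
    if not matrices:
        raise ValueError("harmonize_samples needs at least one matrix")
    surv_ids = set(survival.patient_ids)
    aligned: Dict[str, Tuple[OmicsMatrix, SurvivalTable]] = {}
    for name, m in matrices.items():
        keep = [s for s in m.sample_ids if s in surv_ids]
        aligned[name] = (m.subset_samples(keep), survival.subset(keep))
    names = sorted(aligned)
    shared = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa = set(aligned[a][0].sample_ids)
            sb = set(aligned[b][0].sample_ids)
            shared[(a, b)] = sorted(sa & sb)
    counts = {name: aligned[name][0].n_samples for name in aligned}
    return Harmonized(aligned, shared, counts)


def impute_missing(matrix: OmicsMatrix, max_missing_frac: float = 0.2,
                   ) -> Tuple[OmicsMatrix, Dict[str, int]]:
    """Drop features with too many missing values; median-impute the rest."""
    frac = matrix.values.isna().mean(axis=1)
    kept = matrix.values.loc[frac <= max_missing_frac]
    n_dropped = int((frac > max_missing_frac).sum())
    medians = kept.median(axis=1)
    filled = kept.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    report = {"features_dropped": n_dropped,
              "values_imputed": int(kept.isna().to_numpy().sum())}
    return OmicsMatrix(matrix.platform, filled, matrix.value_domain), report
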