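"""Synthetic multi-platform cohorts with planted subtypes and survival.

The generator emulates the structure of a TCGA-style serous ovarian cancer
cohort: several hundred patients, a handful of molecular platforms with very
different feature counts and value domains, partial per-platform coverage,
a latent subtype assignment, and right-censored overall survival whose hazard
depends on the subtype.  A minority of features per platform carry subtype
signal; everything else is exchangeable noise.

Generative model
----------------
Every platform starts from a latent Gaussian feature-by-sample matrix
``z ~ N(mu_p, 1)``.  Each informative feature is assigned a random non-empty,
proper subset of subtypes in which its latent mean is shifted by
``effect_size`` (in within-group standard deviations); subset patterns, rather
than single-subtype bumps, make informative features discriminate every pair
of subtypes and tie them to survival through the subtype hazards.  The latent
matrix is then pushed through a platform-specific link:

* methylation: logistic transform, beta values in (0, 1);
* mrna / mirna: exponential transform, non-negative and right-skewed
  (count-like);
* protein: identity (real-valued abundance).

Survival times are exponential with the subtype's hazard; censoring times are
an independent exponential whose rate is calibrated by bisection so the
expected censored fraction matches ``censor_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, OmicsMatrix, SurvivalTable

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_survival",
    "write_cohort",
]

DEFAULT_PLATFORM_DIMS = {"mrna": 2000, "methylation": 500, "protein": 100,
                         "mirna": 150}
# latent mean per platform before the link function
_LATENT_MEAN = {"mrna": 3.0, "mirna": 2.0, "methylation": 0.0, "protein": 0.0}


class ConfigError(ValueError):
    """A simulation configuration field violates its contract."""


@dataclass
class SimulationConfig:
    n_patients: int = 600
    k_true: int = 4
    platform_dims: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLATFORM_DIMS))
    frac_informative: float = 0.1
    effect_size: float = 1.5
    hazard_per_subtype: Sequence[float] = (0.004, 0.0023, 0.0013, 0.0008)
    censor_rate: float = 0.47
    platform_coverage: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 2:
            raise ConfigError("k_true: must be >= 2")
        if self.n_patients < 4 * self.k_true:
            raise ConfigError("n_patients: must be >= 4 * k_true")
        if len(self.hazard_per_subtype) != self.k_true:
            raise ConfigError(
                "hazard_per_subtype: needs exactly k_true entries")
        if any(h <= 0 for h in self.hazard_per_subtype):
            raise ConfigError("hazard_per_subtype: rates must be positive")
        if not 0.0 < self.frac_informative < 1.0:
            raise ConfigError("frac_informative: must lie in (0, 1)")
        if not 0.0 < self.censor_rate < 1.0:
            raise ConfigError("censor_rate: must lie in (0, 1)")
        for p in self.platform_dims:
            if p not in _LATENT_MEAN:
                raise ConfigError(f"platform_dims: unknown platform {p!r}")
            if self.platform_dims[p] < 1:
                raise ConfigError(f"platform_dims: {p} needs >= 1 feature")
        for p, frac in self.platform_coverage.items():
            if p not in self.platform_dims:
                raise ConfigError(f"platform_coverage: unknown platform {p!r}")
            if not 0.0 < frac <= 1.0:
                raise ConfigError("platform_coverage: must lie in (0, 1]")


@dataclass
class SyntheticCohort:
    matrices: Dict[str, OmicsMatrix]
    survival: SurvivalTable
    true_labels: pd.Series  # patient_id -> subtype in 1..k_true
    planted_features: Dict[str, List[str]]
    clinical: ClinicalTable
    config: SimulationConfig


def _calibrate_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Censoring-exponential rate c with E[frac censored] == target.

    For T ~ Exp(lam) and independent C ~ Exp(c), P(C < T) = c / (lam + c);
    the population mean of that is monotone increasing in c, so bisection
    on log-spaced brackets converges.
    """
    def frac(c: float) -> float:
        return float(np.mean(c / (hazards + c)))

    lo, hi = 1e-12, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_survival(labels: Mapping[str, int] | pd.Series,
                      hazards: Sequence[float],
                      censor_rate: float,
                      seed: int) -> SurvivalTable:
    """Exponential survival per subtype with independent exponential censoring.

    ``labels`` maps patient id to a 1-based subtype index into ``hazards``.
    Times are reported as whole days (rounded up, so always >= 1).  The
    censoring rate is calibrated so the expected censored fraction equals
    ``censor_rate``; ``censor_rate=0`` disables censoring entirely.
    """
    labels = pd.Series(labels)
    if len(labels) == 0:
        empty = pd.DataFrame({"event": pd.Series(dtype=int),
                              "time_days": pd.Series(dtype=float)})
        empty.index.name = "patient_id"
        return SurvivalTable(empty)
    hazards = np.asarray(hazards, dtype=float)
    if (hazards <= 0).any():
        raise ConfigError("hazard_per_subtype: rates must be positive")
    idx = labels.to_numpy(dtype=int) - 1
    if idx.min() < 0 or idx.max() >= len(hazards):
        raise ConfigError("labels: subtype index out of range of hazards")
    if not 0.0 <= censor_rate < 1.0:
        raise ConfigError("censor_rate: must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    lam = hazards[idx]
    t_event = rng.exponential(1.0 / lam)
    if censor_rate == 0.0:
        time, event = t_event, np.ones(len(labels), dtype=int)
    else:
        c = _calibrate_censor_rate(lam, censor_rate)
        t_cens = rng.exponential(1.0 / c, size=len(labels))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    days = np.maximum(np.ceil(time), 1.0)
    df = pd.DataFrame({"event": event, "time_days": days}, index=labels.index)
    return SurvivalTable(df.rename_axis(index="patient_id"))


def _subtype_patterns(rng: np.random.Generator, n_informative: int,
                      k: int) -> np.ndarray:
    """Random non-empty proper subtype subsets, one 0/1 row per feature."""
    pat = np.zeros((n_informative, k), dtype=float)
    for i in range(n_informative):
        while True:
            row = rng.integers(0, 2, size=k)
            if 0 < row.sum() < k:
                pat[i] = row
                break
    return pat


def _link(platform: str, z: np.ndarray) -> np.ndarray:
    if platform == "methylation":
        return 1.0 / (1.0 + np.exp(-z))
    if platform in ("mrna", "mirna"):
        return np.exp(z)
    return z  # protein: real-valued


def _simulate_clinical(rng: np.random.Generator, labels: pd.Series,
                       k: int) -> ClinicalTable:
    """Two subtype-linked variables plus one null variable of each kind."""
    n = len(labels)
    sub = labels.to_numpy(dtype=int)
    tumor_size = 2.0 + 0.8 * sub + rng.normal(0.0, 1.0, n)  # linked, cm
    age = rng.normal(60.0, 10.0, n)                          # null
    stage_levels = np.array(["II", "III", "IV"])
    # linked categorical: stage distribution drifts with subtype
    probs = np.stack([np.array([0.5, 0.3, 0.2]),
                      np.array([0.2, 0.5, 0.3]),
                      np.array([0.15, 0.35, 0.5])])
    which = np.minimum(sub - 1, 2)
    stage = np.array([stage_levels[rng.choice(3, p=probs[w])] for w in which])
    grade = rng.choice(["G2", "G3"], size=n)                 # null
    df = pd.DataFrame({"tumor_size_cm": tumor_size, "age": age,
                       "clinical_stage": stage, "tumor_grade": grade},
                      index=labels.index)
    df.index.name = "patient_id"
    kinds = {"tumor_size_cm": "quantitative", "age": "quantitative",
             "clinical_stage": "categorical", "tumor_grade": "categorical"}
    return ClinicalTable(df, kinds)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a deterministic multi-platform cohort from ``config``.

    Returns matrices keyed by platform, a survival table over all patients,
    the true subtype labels, the list of planted informative features per
    platform, and a small clinical table with known subtype-linked and null
    variables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_patients, config.k_true

    patients = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    labels = pd.Series(rng.integers(1, k + 1, size=n), index=patients)
    # guarantee every subtype is represented
    for c in range(1, k + 1):
        if not (labels == c).any():
            labels.iloc[rng.integers(0, n)] = c

    matrices: Dict[str, OmicsMatrix] = {}
    planted: Dict[str, List[str]] = {}
    onehot = np.eye(k)[labels.to_numpy(dtype=int) - 1]  # n x k

    for platform, n_feat in config.platform_dims.items():
        n_inf = max(1, int(round(config.frac_informative * n_feat)))
        feat_ids = [f"{platform}_f{j:05d}" for j in range(n_feat)]
        inf_idx = rng.choice(n_feat, size=n_inf, replace=False)
        z = rng.normal(_LATENT_MEAN[platform], 1.0, size=(n_feat, n))
        patterns = _subtype_patterns(rng, n_inf, k)  # n_inf x k
        z[inf_idx] += config.effect_size * (patterns @ onehot.T)
        values = pd.DataFrame(_link(platform, z), index=feat_ids,
                              columns=patients)
        coverage = config.platform_coverage.get(platform, 1.0)
        if coverage < 1.0:
            keep = max(2 * k, int(round(coverage * n)))
            cols = rng.choice(n, size=min(keep, n), replace=False)
            values = values.iloc[:, np.sort(cols)]
        values.index.name = "feature_id"
        matrices[platform] = OmicsMatrix(platform, values)
        planted[platform] = [feat_ids[j] for j in np.sort(inf_idx)]

    surv_seed = int(rng.integers(0, 2**31 - 1))
    clin_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    survival = simulate_survival(labels, config.hazard_per_subtype,
                                 config.censor_rate, surv_seed)
    clinical = _simulate_clinical(clin_rng, labels, k)
    return SyntheticCohort(matrices, survival, labels, planted, clinical,
                           config)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write a cohort as TSV files plus a JSON manifest; returns the manifest.

    One matrix TSV per platform (first column ``feature_id``), a survival TSV
    (``patient_id``, ``vital_status``, ``days``), a clinical TSV, one
    planted-feature list per platform, and ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"platforms": sorted(cohort.matrices), "files": {}}

    for platform, matrix in cohort.matrices.items():
        path = directory / f"{platform}.tsv"
        matrix.values.to_csv(path, sep="\t", index_label="feature_id")
        manifest["files"][f"matrix_{platform}"] = path.name
        ppath = directory / f"planted_{platform}.txt"
        ppath.write_text(
            "\n".join(cohort.planted_features.get(platform, ())) + "\n")
        manifest["files"][f"planted_{platform}"] = ppath.name

    surv = cohort.survival.data.rename(
        columns={"event": "vital_status", "time_days": "days"})
    surv = surv.assign(days=surv["days"].astype(int))
    spath = directory / "survival.tsv"
    surv.to_csv(spath, sep="\t", index_label="patient_id")
    manifest["files"]["survival"] = spath.name

    if len(cohort.clinical.data):
        cpath = directory / "clinical.tsv"
        cohort.clinical.data.to_csv(cpath, sep="\t", index_label="patient_id")
        manifest["files"]["clinical"] = cpath.name
        manifest["clinical_kinds"] = dict(cohort.clinical.kinds)

    lpath = directory / "true_labels.tsv"
    cohort.true_labels.rename("subtype").to_csv(lpath, sep="\t",
                                                index_label="patient_id")
    manifest["files"]["true_labels"] = lpath.name

    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
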