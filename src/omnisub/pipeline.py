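"""End-to-end driver: per-platform subtyping and cross-platform integration.

For each platform the driver filters the cohort to primary-tumor samples
with survival, optionally log-transforms count-like values, Cox-screens
features against survival, sweeps PAM/HC/NMF over a range of cluster counts,
picks the candidate with the best complexity-penalized log-rank score and
characterizes the selected partition (per-cluster Kaplan–Meier medians and —
for expression platforms — 2-fold/0.5-fold subtype gene sets).

The pathway platform is derived from the mRNA matrix through
:mod:`omnisub.pathway` and then treated exactly like a measured platform.
Integration overlaps every platform's partition with a reference partition
(mRNA by default) on shared samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .characterize import (OverlapResult, SubtypeGeneSets, fold_change_sets,
                           overlap_partitions)
from .cluster import SweepRow, screen_k, sweep_frame
from .containers import OmicsMatrix, Partition, SurvivalTable
from .pathway import activity_matrix, read_topologies
from .select import (ModelScoreRow, choose_model, median_survival_per_cluster,
                     score_frame, score_sweep)
from .survival import screen_features, screen_rows_frame

logger = logging.getLogger("omnisub")

__all__ = ["PipelineConfig", "PlatformResult", "subtype_platform",
           "run_platform", "run_integration"]

# count-like platforms are log-transformed before screening and clustering
LOG_TRANSFORM_PLATFORMS = ("mrna", "mirna")


@dataclass
class PipelineConfig:
    matrices: Dict[str, str] = field(default_factory=dict)  # platform -> path
    survival: str = ""
    clinical: Optional[str] = None
    sample_types: Optional[str] = None
    topologies: Optional[str] = None
    annotation: Optional[str] = None
    out_dir: str = "omnisub_out"
    alpha: float = 0.05
    k_min: int = 2
    k_max: int = 9
    methods: Sequence[str] = ("PAM", "HC", "NMF")
    lam: float = 1.0
    seed: int = 0
    transforms: Dict[str, str] = field(default_factory=dict)
    reference_platform: str = "mrna"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PlatformResult:
    platform: str
    selected: ModelScoreRow
    partition: Partition
    score_table: pd.DataFrame
    sweep: List[SweepRow]
    screen_table: pd.DataFrame
    medians: pd.DataFrame
    gene_sets: Optional[SubtypeGeneSets] = None


def apply_transform(matrix: OmicsMatrix, transform: str) -> OmicsMatrix:
    """Per-platform value transform applied before screening/clustering."""
    if transform == "identity":
        return matrix
    if transform == "log2p1":
        return OmicsMatrix(matrix.platform,
                           np.log2(matrix.values + 1.0), "nonnegative")
    raise ValueError(f"unknown transform {transform!r}")


def default_transform(platform: str) -> str:
    return "log2p1" if platform in LOG_TRANSFORM_PLATFORMS else "identity"


def subtype_platform(matrix: OmicsMatrix, survival: SurvivalTable,
                     alpha: float = 0.05, methods: Sequence[str] = ("PAM",
                                                                    "HC",
                                                                    "NMF"),
                     k_range: Sequence[int] = range(2, 10), lam: float = 1.0,
                     seed: int = 0, transform: Optional[str] = None,
                     characterize: bool = False) -> PlatformResult:
    """In-memory per-platform workflow on an already filtered, aligned cohort.

    Returns the selected model, its partition, the full score table, the Cox
    screen table, per-cluster KM medians and (optionally) fold-change gene
    sets computed on the untransformed matrix.
    """
    if transform is None:
        transform = default_transform(matrix.platform)
    work = apply_transform(matrix, transform)
    work, impute_report = cio.impute_missing(work)
    logger.info("%s: screening %d features (%s transform, %s)",
                matrix.platform, work.n_features, transform, impute_report)
    selected_matrix, screen_rows = screen_features(work, survival, alpha=alpha)
    logger.info("%s: %d/%d features prognostic at alpha=%g", matrix.platform,
                selected_matrix.n_features, work.n_features, alpha)
    sweep = screen_k(selected_matrix, survival, methods=methods,
                     k_range=k_range, seed=seed)
    scored = score_sweep(sweep, lam=lam)
    best, ranked = choose_model(scored)
    part = next(r.partition for r in sweep
                if r.method == best.method and r.k == best.N)
    assert part is not None
    medians = median_survival_per_cluster(part, survival)
    gene_sets = None
    if characterize:
        gene_sets = fold_change_sets(matrix.subset_samples(part.sample_ids),
                                     part)
    return PlatformResult(matrix.platform, best, part, score_frame(scored),
                          sweep, screen_rows_frame(screen_rows), medians,
                          gene_sets)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: Dict[str, str] = {}

    def add(self, path: Path) -> None:
        self.entries[str(path.relative_to(self.out_dir))] = _sha256(path)

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.entries, indent=2, sort_keys=True)
                        + "\n")
        return path


def run_platform(config: PipelineConfig, platform: str,
                 ) -> PlatformResult:
    """File-driven per-platform run: read, filter, subtype, write artifacts."""
    t0 = _time.time()
    out_dir = Path(config.out_dir) / platform
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir)

    survival, n_dropped = cio.read_survival(config.survival)
    if n_dropped:
        logger.info("survival: dropped %d incomplete rows", n_dropped)
    if platform == "pathway":
        if config.topologies is None:
            raise ValueError("pathway platform needs a topologies file")
        mrna = cio.read_matrix(config.matrices["mrna"], "mrna")
        topologies = read_topologies(config.topologies)
        matrix, report = activity_matrix(mrna, topologies)
        if report.unavailable:
            logger.info("pathway: %d singular pathways dropped",
                        len(report.unavailable))
    else:
        matrix = cio.read_matrix(config.matrices[platform], platform)

    if config.sample_types:
        type_of = cio.read_sample_types(config.sample_types)
    else:
        type_of = {s: "primary" for s in matrix.sample_ids}
    matrix, survival = cio.filter_cohort(matrix, survival, type_of)

    result = subtype_platform(
        matrix, survival, alpha=config.alpha, methods=config.methods,
        k_range=range(config.k_min, config.k_max + 1), lam=config.lam,
        seed=config.seed,
        transform=config.transforms.get(platform),
        characterize=platform in ("mrna", "mirna"))

    result.screen_table.to_csv(out_dir / "screen.tsv", sep="\t")
    sweep_frame(result.sweep).to_csv(out_dir / "sweep.tsv", sep="\t",
                                     index=False)
    result.score_table.to_csv(out_dir / "model.tsv", sep="\t", index=False)
    result.partition.labels.rename("cluster").to_csv(
        out_dir / "partition.tsv", sep="\t", index_label="sample_id")
    result.medians.to_csv(out_dir / "medians.tsv", sep="\t", index=False)
    if result.gene_sets is not None:
        rows = [(c, "up", g, result.gene_sets.ratios.at[g, c])
                for c in sorted(result.gene_sets.up)
                for g in result.gene_sets.up[c]]
        rows += [(c, "down", g, result.gene_sets.ratios.at[g, c])
                 for c in sorted(result.gene_sets.down)
                 for g in result.gene_sets.down[c]]
        pd.DataFrame(rows, columns=["cluster", "direction", "gene", "ratio"]
                     ).to_csv(out_dir / "subtype_gene_sets.tsv", sep="\t",
                              index=False)
    for name in ("screen.tsv", "sweep.tsv", "model.tsv", "partition.tsv",
                 "medians.tsv"):
        manifest.add(out_dir / name)
    if (out_dir / "subtype_gene_sets.tsv").exists():
        manifest.add(out_dir / "subtype_gene_sets.tsv")
    manifest.write()
    logger.info("%s: %s with N=%d selected in %.1fs", platform,
                result.selected.method, result.selected.N, _time.time() - t0)
    return result


def run_integration(config: PipelineConfig,
                    partitions: Mapping[str, Partition],
                    ) -> Dict[str, OverlapResult]:
    """Overlap every platform's partition with the reference partition."""
    if len(partitions) < 2:
        raise ValueError("integration needs at least 2 partitions")
    ref_name = config.reference_platform
    if ref_name not in partitions:
        raise ValueError(f"reference platform {ref_name!r} has no partition")
    ref = partitions[ref_name]
    out_dir = Path(config.out_dir) / "integration"
    out_dir.mkdir(parents=True, exist_ok=True)
    results: Dict[str, OverlapResult] = {}
    rows = []
    for name, part in partitions.items():
        if name == ref_name:
            continue
        shared = part.labels.index.intersection(ref.labels.index)
        if len(shared) == 0:
            logger.info("integration: %s shares no samples with %s; skipped",
                        name, ref_name)
            continue
        res = overlap_partitions(part, ref)
        results[name] = res
        for (a, b), p in res.pair_p.items():
            rows.append((name, a, ref_name, b,
                         int(res.contingency.at[a, b]), p,
                         res.pair_stars[(a, b)]))
    pd.DataFrame(rows, columns=["platform", "cluster", "reference",
                                "ref_cluster", "count", "p_value", "stars"]
                 ).to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
    return results
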