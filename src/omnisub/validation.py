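"""Self-contained validation experiments for the whole pipeline.

Each function runs one reproducible experiment — an arithmetic check against
published cohort counts, a statistical-calibration simulation, an oracle
comparison against brute force, or an end-to-end recovery run on planted
synthetic cohorts — and returns plain numbers.  They power both the
acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .characterize import matched_starred_pairs, overlap_partitions
from .cluster import SweepRow, nmf_cluster, pam_cluster, standardize_features
from .containers import ClinicalTable, OmicsMatrix
from .io import summarize_clinical
from .pathway import PathwayTopology, pathway_tA
from .pipeline import subtype_platform
from .select import choose_model, score_sweep
from .simulate import SimulationConfig, simulate_cohort
from .survival import cox_score_test, logrank_test, screen_features

__all__ = [
    "clinical_summary_percents",
    "cox_logrank_max_diff",
    "null_screen_fraction",
    "pam_oracle_check",
    "nmf_property_check",
    "ta_oracle_check",
    "model_selection_check",
    "EndToEndRecord",
    "end_to_end_recovery",
]

# published follow-up and first-course-outcome counts for the 599-patient
# serous ovarian cancer cohort; inputs to the percentage arithmetic check
FOLLOWUP_COUNTS = {"alive": 281, "dead": 302}
OUTCOME_COUNTS = {"complete_remission": 332, "partial_remission": 65,
                  "stable_disease": 34, "progressive_disease": 45}
COHORT_SIZE = 599


def _table_from_counts(counts: Dict[str, int], total: int) -> ClinicalTable:
    vals: List[object] = []
    for cat, n in counts.items():
        vals += [cat] * n
    vals += [np.nan] * (total - len(vals))
    df = pd.DataFrame({"v": vals}, index=[f"P{i}" for i in range(total)])
    return ClinicalTable(df, {"v": "categorical"})


def clinical_summary_percents() -> Dict[str, float]:
    """Printed-style percentages recomputed from the published counts."""
    out: Dict[str, float] = {}
    t = _table_from_counts(FOLLOWUP_COUNTS, COHORT_SIZE)
    for cat, _, pct in summarize_clinical(t, "v"):
        out[f"followup_{cat}"] = pct
    t2 = _table_from_counts(OUTCOME_COUNTS, COHORT_SIZE)
    for cat, _, pct in summarize_clinical(t2, "v"):
        out[f"outcome_{cat}"] = pct
    return out


def cox_logrank_max_diff(seed: int = 0, n_reps: int = 20, n: int = 60,
                         ) -> float:
    """Max |Cox score chi2 - 2-group log-rank chi2| over random binary
    covariates with untied event times."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_reps):
        times = rng.permutation(np.arange(1.0, n + 1.0))
        events = rng.integers(0, 2, n)
        events[rng.integers(0, n, 3)] = 1
        idx = pd.Index([f"P{i}" for i in range(n)])
        from .containers import SurvivalTable
        surv = SurvivalTable(pd.DataFrame(
            {"event": events, "time_days": times}, index=idx))
        group = rng.integers(0, 2, n)
        if group.min() == group.max():
            continue
        chi2_score, _ = cox_score_test(
            pd.Series(group.astype(float), index=idx), surv)
        chi2_lr, _, _ = logrank_test(surv, pd.Series(group + 1, index=idx), 2)
        worst = max(worst, abs(chi2_score - chi2_lr))
    return worst


def null_screen_fraction(seed: int = 0, n_seeds: int = 20,
                         n_features: int = 500, n_patients: int = 300,
                         alpha: float = 0.05) -> float:
    """Mean selected fraction of the Cox screen on pure-noise cohorts."""
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_seeds):
        cfg = SimulationConfig(
            n_patients=n_patients, k_true=2,
            platform_dims={"protein": n_features},
            hazard_per_subtype=(0.002, 0.002), frac_informative=0.1,
            effect_size=0.0, censor_rate=0.47,
            seed=int(rng.integers(0, 2**31 - 1)))
        coh = simulate_cohort(cfg)
        m = coh.matrices["protein"]
        try:
            _, rows = screen_features(m, coh.survival, alpha=alpha)
        except Exception:
            rows = []
        fracs.append(np.mean([r.selected for r in rows]) if rows else 0.0)
    return float(np.mean(fracs))


def _brute_force_pam(matrix: OmicsMatrix, k: int) -> float:
    z = standardize_features(matrix).to_numpy().T
    d = squareform(pdist(z))
    best = np.inf
    for medoids in itertools.combinations(range(d.shape[0]), k):
        best = min(best, d[:, medoids].min(axis=1).sum())
    return float(best)


def pam_oracle_check(seed: int = 0, n_instances: int = 20,
                     ) -> Dict[str, float]:
    """BUILD+SWAP vs exhaustive k-medoids on random 6-8 sample instances."""
    rng = np.random.default_rng(seed)
    agree = 0
    never_beats = True
    for i in range(n_instances):
        n = int(rng.integers(6, 9))
        k = int(rng.integers(2, 4))
        df = pd.DataFrame(rng.normal(size=(5, n)),
                          index=[f"g{j}" for j in range(5)],
                          columns=[f"s{j}" for j in range(n)])
        m = OmicsMatrix("protein", df)
        part = pam_cluster(m, k, seed=int(rng.integers(0, 2**31 - 1)))
        opt = _brute_force_pam(m, k)
        if part.quality <= opt + 1e-6:
            agree += 1
        if part.quality < opt - 1e-6:
            never_beats = False
    return {"agreement_frac": agree / n_instances,
            "never_beats_optimum": float(never_beats)}


def nmf_property_check(seed: int = 0, n_seeds: int = 20) -> Dict[str, float]:
    """Monotone objective traces and exact-rank-k reconstruction."""
    rng = np.random.default_rng(seed)
    monotone = 0
    for _ in range(n_seeds):
        v = rng.uniform(0, 5, size=(15, 10))
        m = OmicsMatrix("mrna", pd.DataFrame(
            v, index=[f"g{i}" for i in range(15)],
            columns=[f"s{i}" for i in range(10)]))
        res = nmf_cluster(m, k=3, seed=int(rng.integers(0, 2**31 - 1)),
                          n_restarts=2, max_iter=200)
        tr = res.objective_trace
        if np.all(np.diff(tr) <= 1e-10 * np.maximum(tr[:-1], 1.0)):
            monotone += 1
    w = rng.uniform(0.5, 2, (30, 3))
    h = rng.uniform(0.5, 2, (3, 20))
    v = w @ h
    m = OmicsMatrix("mrna", pd.DataFrame(
        v, index=[f"g{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(20)]))
    res = nmf_cluster(m, k=3, seed=seed, n_restarts=5, max_iter=3000,
                      tol=1e-12)
    rel_err = float(np.linalg.norm(v - res.W @ res.H) ** 2
                    / np.linalg.norm(v) ** 2)
    return {"monotone_frac": monotone / n_seeds,
            "rank_k_relative_error": rel_err}


def ta_oracle_check(seed: int = 0) -> Dict[str, float]:
    """Hand-solved topologies, singularity flagging, linearity deviation."""
    chain = PathwayTopology("chain", ["A", "B"], [("A", "B", 1.0)])
    fork = PathwayTopology("fork", ["A", "B", "C"],
                           [("A", "B", 1.0), ("A", "C", 1.0)])
    cycle = PathwayTopology("cycle", ["A", "B"],
                            [("A", "B", 1.0), ("B", "A", 1.0)])
    chain_err = abs(pathway_tA({"A": 1.0}, chain) - 1.0)
    fork_err = abs(pathway_tA({"A": 1.0}, fork) - 1.0)
    try:
        pathway_tA({"A": 1.0}, cycle)
        cyclic_flagged = 0.0
    except ValueError:
        cyclic_flagged = 1.0
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(20):
        n = int(rng.integers(3, 8))
        genes = [f"G{i}" for i in range(n)]
        edges = [(genes[i], genes[j], float(rng.choice([-1.0, 1.0])))
                 for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.4]
        topo = PathwayTopology("t", genes, edges)
        d1 = {g: float(rng.normal()) for g in genes}
        d2 = {g: float(rng.normal()) for g in genes}
        a, b = float(rng.normal()), float(rng.normal())
        combo = {g: a * d1[g] + b * d2[g] for g in genes}
        dev = abs(pathway_tA(combo, topo)
                  - a * pathway_tA(d1, topo) - b * pathway_tA(d2, topo))
        worst = max(worst, dev)
    return {"chain_abs_error": chain_err, "fork_abs_error": fork_err,
            "cyclic_flagged": cyclic_flagged, "linearity_max_dev": worst}


def model_selection_check(seed: int = 0, n_tables: int = 50,
                          ) -> Dict[str, float]:
    """lambda=0 reduces to min-p; selected N monotone non-increasing in
    lambda on random sweep tables."""
    rng = np.random.default_rng(seed)
    minp_agree = 0
    monotone = 0
    for _ in range(n_tables):
        sweep = [SweepRow("PAM", k, None, 1.0,
                          float(rng.uniform(1e-12, 1)), "ok")
                 for k in range(2, 10)]
        best, _ = choose_model(score_sweep(sweep, lam=0.0))
        if best.N == min(sweep, key=lambda r: r.logrank_p).k:
            minp_agree += 1
        path = [choose_model(score_sweep(sweep, lam=lam))[0].N
                for lam in np.linspace(0.0, 4.0, 17)]
        if all(a >= b for a, b in zip(path, path[1:])):
            monotone += 1
    return {"lambda0_min_p_agreement": minp_agree / n_tables,
            "lambda_path_monotone": monotone / n_tables}


@dataclass
class EndToEndRecord:
    seed: int
    selected_method: str
    selected_n: int
    ari: float
    matched_starred: int
    k_true: int


def end_to_end_recovery(seeds: Sequence[int],
                        platform_dims: Dict[str, int] | None = None,
                        ) -> List[EndToEndRecord]:
    """Full pipeline on planted 4-subtype cohorts at the default study
    conditions (n=600, effect 1.5, hazards spanning 5x, ~47% censoring).

    For each seed, the mRNA and methylation platforms are subtyped
    independently; the record carries the mRNA model selection, its adjusted
    Rand index against the planted labels, and the number of starred
    best-matched cluster pairs between the two platform partitions.
    """
    platform_dims = platform_dims or {"mrna": 2000, "methylation": 500}
    records = []
    for seed in seeds:
        cfg = SimulationConfig(seed=seed, platform_dims=dict(platform_dims))
        coh = simulate_cohort(cfg)
        results = {}
        for plat in platform_dims:
            m = coh.matrices[plat]
            results[plat] = subtype_platform(
                m, coh.survival.subset(m.sample_ids), seed=seed)
        main = results["mrna"]
        truth = coh.true_labels.loc[main.partition.sample_ids]
        ari = float(adjusted_rand_score(truth, main.partition.labels))
        starred = 0
        if "methylation" in results:
            ov = overlap_partitions(results["methylation"].partition,
                                    main.partition)
            starred = matched_starred_pairs(ov)
        records.append(EndToEndRecord(seed, main.selected.method,
                                      main.selected.N, ari, starred,
                                      cfg.k_true))
    return records
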