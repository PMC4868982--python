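"""Complexity-penalized model selection over the cluster sweep.

Each candidate (method, N) carries the k-sample log-rank p-value of its
partition.  The clustering score trades survival separation against model
complexity:

    score = -log10(p) - lambda * (N - 2)

so for a fixed cluster count the score grows as the survival split becomes
more significant, and for a fixed p-value every extra cluster beyond two
costs ``lambda`` score units.  With ``lambda = 0`` selection reduces to
minimum-p.  The raw (p, N) table is always emitted so any alternative
penalty can be recomputed externally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import Partition, SurvivalTable
from .cluster import SweepRow
from .survival import km_estimate

__all__ = [
    "ModelScoreRow",
    "penalized_score",
    "choose_model",
    "score_sweep",
    "median_survival_per_cluster",
]

_METHOD_ORDER = {"PAM": 0, "HC": 1, "NMF": 2}
_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class ModelScoreRow:
    method: str
    N: int
    logrank_p: Optional[float]
    score: Optional[float]
    selected: bool = False


def penalized_score(p: float, N: int, lam: float = 1.0) -> float:
    """Survival-separation score with a per-cluster complexity penalty."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if p > 1 or p < 0:
        raise ValueError("p must lie in [0, 1]")
    if p == 0:
        warnings.warn("p == 0 clamped to the smallest positive float",
                      RuntimeWarning, stacklevel=2)
        p = _TINY_P
    return float(-np.log10(p) - lam * (N - 2))


def score_sweep(rows: List[SweepRow], lam: float = 1.0) -> List[ModelScoreRow]:
    """Score every sweep candidate; failed candidates get no score."""
    out = []
    for r in rows:
        if r.logrank_p is None:
            out.append(ModelScoreRow(r.method, r.k, None, None))
        else:
            out.append(ModelScoreRow(r.method, r.k, r.logrank_p,
                                     penalized_score(r.logrank_p, r.k, lam)))
    return out


def choose_model(rows: List[ModelScoreRow],
                 ) -> Tuple[ModelScoreRow, List[ModelScoreRow]]:
    """Pick the highest-scoring candidate; return it plus the ranked table.

    Ties break toward the smaller cluster count, then PAM < HC < NMF.
    """
    scored = [r for r in rows if r.score is not None]
    if not scored:
        raise ValueError("no candidate has a defined score")
    ranked = sorted(scored, key=lambda r: (-r.score, r.N,
                                           _METHOD_ORDER.get(r.method, 99)))
    for r in rows:
        r.selected = False
    ranked[0].selected = True
    return ranked[0], ranked


def score_frame(rows: List[ModelScoreRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.method, r.N, r.logrank_p, r.score, r.selected) for r in rows],
        columns=["method", "N", "logrank_p", "score", "selected"])


def median_survival_per_cluster(partition: Partition, survival: SurvivalTable,
                                ) -> pd.DataFrame:
    """Kaplan–Meier median survival per cluster: (cluster, n, median_days).

    Medians the curve never reaches (all-censored clusters) are NaN.
    """
    records = []
    for c in range(1, partition.k + 1):
        members = partition.cluster_members(c)
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        curve = km_estimate(survival.subset(members))
        med = np.nan if curve.median_survival is None else curve.median_survival
        records.append((c, len(members), med))
    return pd.DataFrame(records, columns=["cluster", "n", "median_days"])
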