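"""Unsupervised subtype clustering: PAM, hierarchical and NMF, plus the
k-sweep that produces candidate partitions for survival-guided model
selection.

PAM (k-medoids) is implemented directly — greedy BUILD initialization
followed by SWAP steepest-descent to a local optimum of the total
point-to-medoid distance.  Hierarchical clustering delegates to
scipy.cluster.hierarchy.  NMF minimizes the Frobenius reconstruction error
``||V - WH||^2`` by multiplicative updates with random restarts; a sample is
assigned to the cluster of the dominant (argmax) component of its H column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .containers import OmicsMatrix, Partition, SurvivalTable
from .survival import logrank_test

__all__ = [
    "NMFResult",
    "SweepRow",
    "pam_cluster",
    "hc_cluster",
    "nonneg_transform",
    "nmf_cluster",
    "screen_k",
    "standardize_features",
]

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray                  # features x k, non-negative basis
    H: np.ndarray                  # k x samples, non-negative coefficients
    objective_trace: np.ndarray    # per-iteration ||V - WH||^2
    partition: Partition


@dataclass
class SweepRow:
    method: str
    k: int
    partition: Optional[Partition]
    logrank_chi2: Optional[float]
    logrank_p: Optional[float]
    status: str  # "ok" or a failure note


def standardize_features(matrix: OmicsMatrix) -> pd.DataFrame:
    """Feature-wise z-scores; constant features are dropped (no information)."""
    v = matrix.values
    sd = v.std(axis=1, ddof=0)
    keep = sd > 0
    v = v.loc[keep]
    return v.sub(v.mean(axis=1), axis=0).div(sd[keep], axis=0)


def _distance_matrix(matrix: OmicsMatrix, metric: str = "euclidean",
                     ) -> np.ndarray:
    z = standardize_features(matrix).to_numpy().T  # samples x features
    if metric == "correlation":
        return squareform(pdist(z, metric="correlation"))
    return squareform(pdist(z, metric="euclidean"))


def _pam_build(d: np.ndarray, k: int) -> List[int]:
    """Greedy BUILD: first medoid minimizes total distance, each further
    medoid maximizes the drop in total nearest-medoid distance."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum over points of max(nearest - d[:,c], 0)
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, d[:, c])
    return medoids


def _pam_swap(d: np.ndarray, medoids: List[int], max_iter: int = 200,
              ) -> Tuple[List[int], float]:
    """Steepest-descent SWAP refinement; returns medoids and final cost."""
    n = d.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        dm = d[:, medoids]                       # n x k
        order = np.argsort(dm, axis=1)
        d1 = dm[np.arange(n), order[:, 0]]       # nearest medoid distance
        d2 = (dm[np.arange(n), order[:, 1]]
              if len(medoids) > 1 else np.full(n, np.inf))
        nearest_is = np.array(medoids)[order[:, 0]]
        best_delta, best_swap = -1e-12, None
        for mi, m in enumerate(medoids):
            # removing m: points whose nearest is m fall back to d2
            fallback = np.where(nearest_is == m, d2, d1)
            # new cost with candidate x inserted: min(fallback, d[:, x])
            deltas = (np.minimum(fallback[:, None], d) - d1[:, None]).sum(axis=0)
            deltas[medoids] = np.inf
            xi = int(np.argmin(deltas))
            if deltas[xi] < best_delta:
                best_delta, best_swap = float(deltas[xi]), (mi, xi)
        if best_swap is None:
            break
        mi, xi = best_swap
        medoids[mi] = xi
    dm = d[:, medoids]
    cost = float(dm.min(axis=1).sum())
    return medoids, cost


def _labels_from_medoids(d: np.ndarray, medoids: Sequence[int],
                         sample_ids: pd.Index) -> pd.Series:
    assign = np.argmin(d[:, list(medoids)], axis=1) + 1
    # medoids themselves belong to their own cluster even under ties
    for j, m in enumerate(medoids):
        assign[m] = j + 1
    return pd.Series(assign, index=sample_ids)


def pam_cluster(matrix: OmicsMatrix, k: int, seed: int = 0,
                metric: str = "euclidean") -> Partition:
    """Partitioning Around Medoids on standardized Euclidean distances.

    BUILD + SWAP is deterministic up to distance ties; ``seed`` breaks ties
    by jittering the distance matrix below measurement precision.
    """
    n = matrix.n_samples
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside 2..{n}")
    d = _distance_matrix(matrix, metric)
    rng = np.random.default_rng(seed)
    tie_break = rng.uniform(0.0, 1e-9, size=d.shape)
    d = d + (tie_break + tie_break.T) * (d > 0)
    np.fill_diagonal(d, 0.0)
    if k == n:
        labels = pd.Series(np.arange(1, n + 1), index=matrix.sample_ids)
        return Partition("PAM", k, labels, quality=0.0)
    medoids = _pam_build(d, k)
    medoids, cost = _pam_swap(d, medoids)
    labels = _labels_from_medoids(d, medoids, matrix.sample_ids)
    # relabel clusters 1..k in order of first appearance for determinism
    labels = _canonical_labels(labels)
    return Partition("PAM", int(labels.max()), labels, quality=cost)


def _canonical_labels(labels: pd.Series) -> pd.Series:
    remap, nxt = {}, 1
    out = []
    for v in labels:
        if v not in remap:
            remap[v] = nxt
            nxt += 1
        out.append(remap[v])
    return pd.Series(out, index=labels.index)


def hc_cluster(matrix: OmicsMatrix, k: int, linkage_method: str = "average",
               metric: str = "euclidean") -> Partition:
    """Agglomerative clustering cut to exactly k groups.

    Ward linkage requires Euclidean distances; correlation distance is
    available for average/complete linkage.
    """
    n = matrix.n_samples
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside 2..{n}")
    if linkage_method not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    if linkage_method == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    z = standardize_features(matrix).to_numpy().T
    dist = pdist(z, metric="correlation" if metric == "correlation"
                 else "euclidean")
    tree = linkage(dist, method=linkage_method)
    flat = fcluster(tree, t=k, criterion="maxclust")
    if len(set(flat)) != k:
        raise ValueError(f"tree cut produced {len(set(flat))} != {k} clusters")
    labels = _canonical_labels(pd.Series(flat, index=matrix.sample_ids))
    height = float(tree[-(k - 1), 2]) if k > 1 else 0.0
    return Partition("HC", k, labels, quality=height)


def nonneg_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Shift real-valued features to be non-negative (per-feature min-shift).

    Unit-interval and non-negative inputs pass through unchanged.  Constant
    rows become all-zero; NMF drops zero rows before factorization.
    """
    if matrix.value_domain in ("unit_interval", "nonnegative"):
        return matrix
    shifted = matrix.values.sub(matrix.values.min(axis=1), axis=0)
    return OmicsMatrix(matrix.platform, shifted, "nonnegative")


def _nmf_mu(v: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> Tuple[np.ndarray, np.ndarray,
                                                np.ndarray]:
    """One multiplicative-update run; returns W, H and the objective trace."""
    n_feat, n_samp = v.shape
    scale = np.sqrt(max(v.mean(), _EPS) / k)
    w = rng.uniform(_EPS, 1.0, size=(n_feat, k)) * scale
    h = rng.uniform(_EPS, 1.0, size=(k, n_samp)) * scale
    trace = []
    prev = None
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + _EPS)
        w *= (v @ h.T) / (w @ (h @ h.T) + _EPS)
        obj = float(np.linalg.norm(v - w @ h) ** 2)
        trace.append(obj)
        if prev is not None and prev - obj <= tol * max(prev, _EPS):
            break
        prev = obj
    return w, h, np.asarray(trace)


def nmf_cluster(matrix: OmicsMatrix, k: int, seed: int = 0,
                n_restarts: int = 10, max_iter: int = 500,
                tol: float = 1e-5) -> NMFResult:
    """NMF clustering: best of ``n_restarts`` multiplicative-update runs.

    Restarts whose argmax-H assignment leaves an empty cluster are discarded;
    if every restart does, a ValueError is raised.
    """
    if matrix.value_domain not in ("unit_interval", "nonnegative"):
        raise ValueError("nmf_cluster needs a non-negative matrix; "
                         "apply nonneg_transform first")
    v_full = matrix.values.to_numpy()
    if (v_full[np.isfinite(v_full)] < 0).any():
        raise ValueError("negative values in NMF input")
    nonzero = v_full.sum(axis=1) > 0
    v = v_full[nonzero]
    n_feat, n_samp = v.shape
    if not 2 <= k < min(n_feat, n_samp):
        raise ValueError(f"k={k} outside 2..min(n_features, n_samples)-1")
    root = np.random.default_rng(seed)
    best: Tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        w, h, trace = _nmf_mu(v, k, rng, max_iter, tol)
        obj = trace[-1]
        assign = h.argmax(axis=0)
        if len(set(assign)) == k and (best is None or obj < best[0]):
            best = (obj, w, h, trace)
    if best is None:
        raise ValueError(
            f"all {n_restarts} NMF restarts left an empty cluster at k={k}")
    obj, w, h, trace = best
    labels = _canonical_labels(
        pd.Series(h.argmax(axis=0) + 1, index=matrix.sample_ids))
    part = Partition("NMF", k, labels, quality=float(obj))
    w_out = np.zeros((matrix.n_features, k))
    w_out[np.nonzero(nonzero)[0]] = w
    return NMFResult(w_out, h, trace, part)


def screen_k(matrix: OmicsMatrix, survival: SurvivalTable,
             methods: Iterable[str] = ("PAM", "HC", "NMF"),
             k_range: Iterable[int] = range(2, 10), seed: int = 0,
             ) -> List[SweepRow]:
    """Run every (method, k) candidate and attach its log-rank p-value.

    Failures (e.g. empty NMF clusters) are recorded with status and excluded
    from model selection rather than raised.
    """
    k_range = list(k_range)
    methods = list(methods)
    if matrix.n_samples < 2 * max(k_range):
        raise ValueError("need n_samples >= 2 * max(k_range)")
    nn = None
    rows: List[SweepRow] = []
    for method in methods:
        for k in k_range:
            try:
                if method == "PAM":
                    part = pam_cluster(matrix, k, seed=seed)
                elif method == "HC":
                    part = hc_cluster(matrix, k)
                elif method == "NMF":
                    if nn is None:
                        nn = nonneg_transform(matrix)
                    part = nmf_cluster(nn, k, seed=seed).partition
                else:
                    raise ValueError(f"unknown method {method!r}")
                chi2, _, p = logrank_test(survival, part.labels, k)
                rows.append(SweepRow(method, k, part, chi2, p, "ok"))
            except (ValueError, ArithmeticError) as exc:
                rows.append(SweepRow(method, k, None, None, None,
                                     f"failed: {exc}"))
    return rows


def sweep_frame(rows: List[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.method, r.k, r.logrank_chi2, r.logrank_p, r.status)
         for r in rows],
        columns=["method", "k", "logrank_chi2", "logrank_p", "status"])
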