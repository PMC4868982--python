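"""Per-sample pathway activity from expression: logFC then net accumulation.

Gene-level change for a sample is the log2 fold change of that gene against
its cohort-average expression (with a pseudocount).  Those changes are then
propagated through a signed, weighted pathway topology in the style of
signaling-pathway impact analysis: the perturbation factor of each gene is
its own change plus the weighted, fan-out-normalized perturbations of its
upstream regulators,

    PF(g_i) = dE(g_i) + sum_j beta_{j->i} * PF(g_j) / n_downstream(g_j),

a linear system ``(I - M) PF = dE``.  The pathway's activity for the sample
is the net total accumulation ``tA = sum_g (PF(g) - dE(g))``.  Pathways whose
propagation system is numerically singular are marked unavailable and carry
no activity row.  The resulting pathway-by-sample activity matrix is treated
downstream exactly like any measured platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

__all__ = [
    "PathwayTopology",
    "read_topologies",
    "compute_logfc",
    "pathway_tA",
    "activity_matrix",
]

COND_LIMIT = 1e12  # condition-number threshold for declaring singularity


@dataclass
class PathwayTopology:
    pathway_id: str
    genes: List[str]
    edges: List[Tuple[str, str, float]]  # (source, target, signed weight)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.pathway_id}: duplicate genes")
        gene_set = set(self.genes)
        for src, dst, _ in self.edges:
            if src not in gene_set or dst not in gene_set:
                raise ValueError(
                    f"{self.pathway_id}: edge {src}->{dst} leaves gene set")

    @property
    def n_downstream(self) -> Dict[str, int]:
        out = {g: 0 for g in self.genes}
        for src, _, _ in self.edges:
            out[src] += 1
        return out

    def propagation_matrix(self) -> np.ndarray:
        """M with M[i, j] = beta_{j->i} / n_downstream(j)."""
        index = {g: i for i, g in enumerate(self.genes)}
        nds = self.n_downstream
        m = np.zeros((len(self.genes), len(self.genes)))
        for src, dst, beta in self.edges:
            m[index[dst], index[src]] += beta / nds[src]
        return m


def read_topologies(edges_path: str | Path,
                    membership_path: str | Path | None = None,
                    ) -> List[PathwayTopology]:
    """Read topologies from an edge-list TSV.

    Edge TSV columns: ``pathway_id, source_gene, target_gene, beta``.  An
    optional membership TSV (``pathway_id, gene``) adds edge-free genes.
    """
    edf = pd.read_csv(Path(edges_path), sep="\t", dtype={"beta": float})
    need = {"pathway_id", "source_gene", "target_gene", "beta"}
    if not need.issubset(edf.columns):
        raise ValueError(f"edge TSV needs columns {sorted(need)}")
    members: Dict[str, List[str]] = {}
    if membership_path is not None:
        mdf = pd.read_csv(Path(membership_path), sep="\t")
        for pid, gene in zip(mdf["pathway_id"], mdf["gene"]):
            members.setdefault(str(pid), []).append(str(gene))
    topologies = []
    all_ids = list(dict.fromkeys(list(edf["pathway_id"].astype(str))
                                 + list(members)))
    for pid in all_ids:
        sub = edf[edf["pathway_id"].astype(str) == pid]
        edges = [(str(s), str(t), float(b)) for s, t, b in
                 zip(sub["source_gene"], sub["target_gene"], sub["beta"])]
        genes = list(dict.fromkeys(
            [g for e in edges for g in e[:2]] + members.get(pid, [])))
        topologies.append(PathwayTopology(pid, genes, edges))
    return topologies


def compute_logfc(matrix: OmicsMatrix, pseudocount: float = 1.0,
                  ) -> pd.DataFrame:
    """Per-sample log2 fold change of each gene against its cohort mean.

    ``logFC(g, s) = log2((x(g, s) + eps) / (mean_s' x(g, s') + eps))``; the
    pseudocount keeps all-zero genes at logFC 0 and is applied to numerator
    and denominator alike so doubling every value leaves logFC unchanged
    only in the eps -> 0 limit.
    """
    v = matrix.values
    if (v.to_numpy() < 0).any():
        raise ValueError("compute_logfc expects non-negative expression")
    mean = v.mean(axis=1)
    return np.log2(v.add(pseudocount, axis=0).div(mean + pseudocount, axis=0))


def _solve_propagation(topology: PathwayTopology,
                       ) -> Tuple[np.ndarray | None, bool]:
    """(I - M) factor for a topology; (None, False) when singular."""
    m = topology.propagation_matrix()
    a = np.eye(len(topology.genes)) - m
    if a.size == 0:
        return a, True
    if np.linalg.cond(a) > COND_LIMIT:
        return None, False
    return a, True


def pathway_tA(delta_e: Mapping[str, float], topology: PathwayTopology,
               ) -> float:
    """Net total accumulation for one sample on one pathway.

    Genes absent from ``delta_e`` enter with change 0.  Raises ValueError if
    the propagation system is singular (cond > 1e12); callers batching many
    pathways should use :func:`activity_matrix`, which marks such pathways
    unavailable instead.
    """
    a, ok = _solve_propagation(topology)
    if not ok:
        raise ValueError(f"pathway {topology.pathway_id}: singular "
                         "propagation system")
    if not topology.genes:
        return 0.0
    de = np.array([float(delta_e.get(g, 0.0)) for g in topology.genes])
    pf = np.linalg.solve(a, de)
    return float(np.sum(pf - de))


@dataclass
class ActivityReport:
    available: List[str] = field(default_factory=list)
    unavailable: List[str] = field(default_factory=list)
    unresolved_gene_frac: Dict[str, float] = field(default_factory=dict)


def activity_matrix(expression: OmicsMatrix,
                    topologies: Sequence[PathwayTopology],
                    pseudocount: float = 1.0,
                    ) -> Tuple[OmicsMatrix, ActivityReport]:
    """Pathway-by-sample tA matrix for a whole cohort.

    Each available pathway contributes one row; singular pathways are listed
    in the report.  Genes missing from the expression matrix get change 0 and
    their fraction per pathway is reported.
    """
    logfc = compute_logfc(expression, pseudocount)
    report = ActivityReport()
    rows, ids = [], []
    for topo in topologies:
        a, ok = _solve_propagation(topo)
        if not ok:
            report.unavailable.append(topo.pathway_id)
            continue
        measured = [g for g in topo.genes if g in logfc.index]
        report.unresolved_gene_frac[topo.pathway_id] = (
            1.0 - len(measured) / len(topo.genes) if topo.genes else 0.0)
        de = np.zeros((len(topo.genes), expression.n_samples))
        idx = {g: i for i, g in enumerate(topo.genes)}
        for g in measured:
            de[idx[g]] = logfc.loc[g].to_numpy()
        if len(topo.genes):
            pf = np.linalg.solve(a, de)
            ta = (pf - de).sum(axis=0)
        else:
            ta = np.zeros(expression.n_samples)
        rows.append(ta)
        ids.append(topo.pathway_id)
        report.available.append(topo.pathway_id)
    if not rows:
        raise ValueError("every pathway propagation system is singular")
    values = pd.DataFrame(np.vstack(rows), index=ids,
                          columns=expression.sample_ids)
    values.index.name = "feature_id"
    return OmicsMatrix("pathway", values, "real"), report
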