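"""Subtype characterization and cross-platform integration.

Characterization works on the linear expression scale: a gene is
subtype-specific up-regulated in cluster c when its within-cluster mean is at
least ``up``-fold (default 2) the mean over all *other* clusters, and
down-regulated below ``down``-fold (default 0.5).  Heatmap row ordering
groups features by the cluster they are up-regulated in (best ratio wins),
descending ratio within each block, with features up nowhere moved to the
tail.

Integration compares two partitions on their shared samples: an overall
chi-square test of independence on the k_A x k_B contingency table plus a
per-pair 2x2 chi-square (cluster a vs rest, cluster b vs rest) star-coded at
0.05 / 0.01 / 0.001.  Clinical association uses one-way ANOVA for
quantitative variables and the chi-square independence test for categorical
ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable, OmicsMatrix, Partition

__all__ = [
    "SubtypeGeneSets",
    "OverlapResult",
    "fold_change_sets",
    "order_rows_for_heatmap",
    "marker_profile",
    "read_gmt",
    "enrich_gene_set",
    "overlap_partitions",
    "matched_starred_pairs",
    "clinical_association",
    "stars",
]


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class SubtypeGeneSets:
    up: Dict[int, List[str]]                 # cluster -> up-regulated genes
    down: Dict[int, List[str]]
    ratios: pd.DataFrame                     # gene x cluster fold ratios

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, len(self.up[c]), len(self.down[c])) for c in sorted(self.up)],
            columns=["cluster", "n_up", "n_down"])


def fold_change_sets(matrix: OmicsMatrix, partition: Partition,
                     up: float = 2.0, down: float = 0.5,
                     epsilon: float | None = None) -> SubtypeGeneSets:
    """One-vs-rest fold-change gene sets per cluster on the linear scale.

    ``ratio(g, c) = (mean_c(g) + eps) / (mean_rest(g) + eps)``; eps defaults
    to the smallest positive value of the matrix (0 if none), guarding
    against division by zero without distorting well-expressed genes.
    """
    if partition.k < 2:
        raise ValueError("fold_change_sets needs at least 2 clusters")
    v = matrix.values[partition.sample_ids]
    if epsilon is None:
        pos = v.to_numpy()[v.to_numpy() > 0]
        epsilon = float(pos.min()) if pos.size else 0.0
    ratios = {}
    lab = partition.labels
    for c in range(1, partition.k + 1):
        in_c = v.loc[:, lab == c].mean(axis=1)
        rest = v.loc[:, lab != c].mean(axis=1)
        ratios[c] = (in_c + epsilon) / (rest + epsilon)
    rdf = pd.DataFrame(ratios)
    up_sets = {c: rdf.index[rdf[c] >= up].tolist() for c in rdf.columns}
    down_sets = {c: rdf.index[rdf[c] <= down].tolist() for c in rdf.columns}
    return SubtypeGeneSets(up_sets, down_sets, rdf)


def order_rows_for_heatmap(matrix: OmicsMatrix, partition: Partition,
                           sets: SubtypeGeneSets,
                           ) -> Tuple[List[str], Dict[int, Tuple[int, int]]]:
    """Feature order for a subtype heatmap plus cluster-block boundaries.

    Features up-regulated in several clusters join the block with the highest
    ratio; features up nowhere keep their original order in a tail block
    (key 0 in the boundary map).
    """
    rdf = sets.ratios
    assigned: Dict[str, int] = {}
    for gene in matrix.feature_ids:
        ups = [c for c in rdf.columns if gene in set(sets.up[c])]
        if ups:
            assigned[gene] = max(ups, key=lambda c: (rdf.at[gene, c], -c))
    order: List[str] = []
    blocks: Dict[int, Tuple[int, int]] = {}
    for c in sorted(sets.up):
        members = [g for g in assigned if assigned[g] == c]
        members.sort(key=lambda g: -rdf.at[g, c])
        if members:
            blocks[c] = (len(order), len(order) + len(members))
        order.extend(members)
    tail = [g for g in matrix.feature_ids if g not in assigned]
    if tail:
        blocks[0] = (len(order), len(order) + len(tail))
    order.extend(tail)
    return order, blocks


def marker_profile(matrix: OmicsMatrix, partition: Partition,
                   genes: Sequence[str]) -> pd.DataFrame:
    """Mean expression of selected genes per cluster (genes x clusters)."""
    unknown = [g for g in genes if g not in matrix.feature_ids]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown}")
    v = matrix.values.loc[list(genes), partition.sample_ids]
    out = {c: v.loc[:, partition.labels == c].mean(axis=1)
           for c in range(1, partition.k + 1)}
    return pd.DataFrame(out)


def read_gmt(path: str | Path) -> Dict[str, Set[str]]:
    """Parse a GMT file: one line per term — name, description, genes."""
    sets: Dict[str, Set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def enrich_gene_set(genes: Set[str], universe: Set[str],
                    annotation: Mapping[str, Set[str]],
                    alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each annotation term.

    One-sided upper-tail p per term (terms empty after intersection with the
    universe are skipped); ``significant`` uses the raw p < alpha rule.
    """
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("genes must be a subset of the universe")
    n_univ, n_genes = len(universe), len(genes)
    records = []
    for term, members in annotation.items():
        in_univ = members & universe
        if not in_univ:
            continue
        overlap = len(in_univ & genes)
        # P(X >= overlap), X ~ Hypergeom(N=n_univ, K=|term|, n=|genes|)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, len(in_univ),
                                     n_genes))
        records.append((term, overlap, len(in_univ), p, p < alpha))
    return pd.DataFrame(records, columns=["term", "overlap", "term_size",
                                          "p_value", "significant"])


@dataclass
class OverlapResult:
    contingency: pd.DataFrame              # k_A x k_B counts
    pair_p: Dict[Tuple[int, int], float]
    pair_stars: Dict[Tuple[int, int], str]
    pair_enriched: Dict[Tuple[int, int], bool]
    chi2: float
    p_value: float
    low_count: bool = False


def _chi2_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """2x2 chi-square without continuity correction: n(ad-bc)^2 / margins."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def overlap_partitions(part_a: Partition, part_b: Partition,
                       exact: bool = False) -> OverlapResult:
    """Contingency test between two partitions on their shared samples.

    Overall chi-square independence test on the full table; per-pair 2x2
    chi-square (no continuity correction) star-coded at 0.05/0.01/0.001.
    ``exact=True`` switches the per-pair test to the hypergeometric
    (Fisher) exact test, recommended when ``low_count`` is flagged —
    i.e. >20% of expected cells fall below 5.
    """
    shared = part_a.labels.index.intersection(part_b.labels.index)
    if len(shared) == 0:
        raise ValueError("partitions share no samples")
    la = part_a.labels.loc[shared]
    lb = part_b.labels.loc[shared]
    if la.nunique() < 2 or lb.nunique() < 2:
        raise ValueError("need >= 2 clusters per side among shared samples")
    table = pd.crosstab(la, lb)
    table = table.reindex(index=range(1, part_a.k + 1),
                          columns=range(1, part_b.k + 1), fill_value=0)
    obs = table.to_numpy()
    # drop empty rows/cols for the overall test (clusters absent from the
    # shared set carry no information)
    sub = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    chi2, p, _, expected = stats.chi2_contingency(sub, correction=False)
    low = bool((expected < 5).mean() > 0.2)
    n = obs.sum()
    pair_p, pair_stars, pair_enriched = {}, {}, {}
    for ai in table.index:
        for bi in table.columns:
            x = int(table.at[ai, bi])
            row = int(table.loc[ai].sum())
            col = int(table[bi].sum())
            cells = (x, row - x, col - x, n - row - col + x)
            if exact:
                pp = float(stats.fisher_exact(
                    [cells[:2], cells[2:]]).pvalue)
            else:
                _, pp = _chi2_2x2(*cells)
            pair_p[(ai, bi)] = pp
            pair_stars[(ai, bi)] = stars(pp)
            # direction: does the pair co-occur more than expected?
            pair_enriched[(ai, bi)] = x * n > row * col
    return OverlapResult(table, pair_p, pair_stars, pair_enriched,
                         float(chi2), float(p), low)


def matched_starred_pairs(result: OverlapResult) -> int:
    """Starred, positively associated cluster pairs under best matching.

    Clusters of independently computed partitions carry arbitrary labels, so
    the "diagonal" is recovered by maximum-overlap assignment (Hungarian on
    the contingency table); a matched pair counts when its 2x2 test is
    starred *and* the pair co-occurs above expectation.
    """
    from scipy.optimize import linear_sum_assignment

    table = result.contingency
    ri, ci = linear_sum_assignment(-table.to_numpy())
    count = 0
    for i, j in zip(ri, ci):
        key = (table.index[i], table.columns[j])
        if result.pair_stars[key] != "ns" and result.pair_enriched[key]:
            count += 1
    return count


def clinical_association(clinical: ClinicalTable, partition: Partition,
                         ) -> pd.DataFrame:
    """Per-variable association with the partition.

    Quantitative variables: one-way ANOVA across clusters (missing dropped).
    Categorical variables: chi-square independence on cluster x category.
    Variables with a single observed level (or group) are skipped with a note.
    """
    shared = clinical.patient_ids.intersection(partition.labels.index)
    lab = partition.labels.loc[shared]
    records = []
    for name in clinical.data.columns:
        kind = clinical.kinds.get(name, "categorical")
        values = clinical.data.loc[shared, name]
        ok = values.notna()
        v, g = values[ok], lab[ok]
        note = ""
        if kind == "quantitative":
            groups = [v[g == c].to_numpy(dtype=float)
                      for c in sorted(g.unique())]
            groups = [grp for grp in groups if len(grp) > 0]
            if len(groups) < 2:
                records.append((name, "anova", np.nan, np.nan, "skipped: "
                                "fewer than 2 non-missing groups"))
                continue
            f, p = stats.f_oneway(*groups)
            records.append((name, "anova", float(f), float(p), note))
        else:
            if v.nunique() < 2:
                records.append((name, "chi2", np.nan, np.nan,
                                "skipped: single observed level"))
                continue
            table = pd.crosstab(g, v)
            chi2, p, _, expected = stats.chi2_contingency(table,
                                                          correction=False)
            if (expected < 5).mean() > 0.2:
                note = "low-count"
            records.append((name, "chi2", float(chi2), float(p), note))
    out = pd.DataFrame(records, columns=["variable", "test", "statistic",
                                         "p_value", "note"])
    out["stars"] = [stars(p) if np.isfinite(p) else ""
                    for p in out["p_value"]]
    return out
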