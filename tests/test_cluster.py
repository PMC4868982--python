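"""PAM, hierarchical and NMF clustering plus the k-sweep."""

import itertools

import numpy as np
import pandas as pd
import pytest

from omnisub.containers import OmicsMatrix
from omnisub.cluster import (hc_cluster, nmf_cluster, nonneg_transform,
                             pam_cluster, screen_k, standardize_features)
from sklearn.metrics import adjusted_rand_score


def random_matrix(n_feat, n_samp, seed, platform="protein"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n_feat, n_samp)),
                      index=[f"g{i}" for i in range(n_feat)],
                      columns=[f"s{i}" for i in range(n_samp)])
    return OmicsMatrix(platform, df)


def brute_force_pam_cost(matrix, k):
    """Exhaustive k-medoids optimum on standardized Euclidean distances."""
    from scipy.spatial.distance import pdist, squareform
    z = standardize_features(matrix).to_numpy().T
    d = squareform(pdist(z))
    n = d.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = d[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return best


class TestPAM:
    def test_k_equals_n_zero_cost(self, two_blob_matrix):
        part = pam_cluster(two_blob_matrix, k=6, seed=0)
        assert part.k == 6 and part.quality == 0.0
        assert part.sizes().tolist() == [1] * 6

    def test_two_blobs_match_brute_force(self, two_blob_matrix):
        part = pam_cluster(two_blob_matrix, k=2, seed=0)
        assert sorted(part.sizes().tolist()) == [3, 3]
        assert part.quality == pytest.approx(
            brute_force_pam_cost(two_blob_matrix, 2), rel=1e-6)

    def test_sample_order_invariance(self):
        m = random_matrix(10, 20, seed=1)
        part1 = pam_cluster(m, k=3, seed=5)
        rng = np.random.default_rng(2)
        perm = rng.permutation(20)
        m2 = OmicsMatrix("protein", m.values.iloc[:, perm])
        part2 = pam_cluster(m2, k=3, seed=5)
        joined = pd.concat([part1.labels.rename("a"),
                            part2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_k_too_large(self, two_blob_matrix):
        with pytest.raises(ValueError):
            pam_cluster(two_blob_matrix, k=7, seed=0)

    def test_swap_never_beats_exhaustive(self):
        for seed in range(5):
            m = random_matrix(5, 7, seed=seed)
            part = pam_cluster(m, k=3, seed=seed)
            opt = brute_force_pam_cost(m, 3)
            assert part.quality >= opt - 1e-6


def naive_average_linkage(d):
    """O(n^3) agglomeration oracle: returns the list of merged cluster sets."""
    clusters = [{i} for i in range(d.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i]
                                for b in clusters[j]])
                if dist < best[0] - 1e-12:
                    best = (dist, (i, j))
        i, j = best[1]
        merges.append(clusters[i] | clusters[j])
        clusters = [c for idx, c in enumerate(clusters)
                    if idx not in (i, j)] + [merges[-1]]
    return merges


class TestHC:
    @pytest.mark.parametrize("linkage", ["average", "complete", "ward"])
    def test_two_blobs_perfect_split(self, two_blob_matrix, linkage):
        part = hc_cluster(two_blob_matrix, k=2, linkage_method=linkage)
        left = set(part.labels[part.labels == part.labels.iloc[0]].index)
        assert left in ({"s0", "s1", "s2"}, {"s3", "s4", "s5"})

    def test_matches_naive_agglomeration(self):
        """Partitions at every k agree with a brute-force average-linkage
        agglomeration on small instances."""
        from scipy.spatial.distance import pdist, squareform
        for seed in range(3):
            m = random_matrix(6, 8, seed=seed)
            d = squareform(pdist(standardize_features(m).to_numpy().T))
            merges = naive_average_linkage(d)
            for k in range(2, 8):
                part = hc_cluster(m, k=k, linkage_method="average")
                # rebuild the naive partition at k clusters
                clusters = [{i} for i in range(8)]
                for merged in merges[:8 - k]:
                    clusters = [c for c in clusters if not c <= merged]
                    clusters.append(merged)
                naive = np.empty(8, dtype=int)
                for ci, c in enumerate(clusters):
                    for i in c:
                        naive[i] = ci
                assert adjusted_rand_score(naive, part.labels) == 1.0

    def test_two_samples(self):
        m = random_matrix(4, 2, seed=0)
        part = hc_cluster(m, k=2)
        assert part.sizes().tolist() == [1, 1]


class TestNonnegTransform:
    def test_nonnegative_passthrough(self):
        m = random_matrix(3, 4, seed=0)
        m = OmicsMatrix("mrna", m.values.abs())
        out = nonneg_transform(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_min_shift(self):
        df = pd.DataFrame([[-2.0, 0.0, 3.0]], index=["g0"],
                          columns=["a", "b", "c"])
        out = nonneg_transform(OmicsMatrix("protein", df))
        np.testing.assert_allclose(out.values.to_numpy(), [[0.0, 2.0, 5.0]])
        assert out.value_domain == "nonnegative"

    def test_constant_row_becomes_zero(self):
        df = pd.DataFrame([[4.0, 4.0, 4.0], [1.0, 2.0, 3.0]],
                          index=["g0", "g1"], columns=list("abc"))
        out = nonneg_transform(OmicsMatrix("protein", df))
        assert (out.values.loc["g0"] == 0.0).all()


class TestNMF:
    def test_block_diagonal_separation(self):
        rng = np.random.default_rng(3)
        v = np.zeros((20, 12))
        v[:10, :6] = rng.uniform(1, 2, (10, 6))
        v[10:, 6:] = rng.uniform(1, 2, (10, 6))
        m = OmicsMatrix("mrna", pd.DataFrame(
            v, index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(12)]))
        res = nmf_cluster(m, k=2, seed=0, n_restarts=3)
        labels = res.partition.labels
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[6]

    def test_objective_trace_non_increasing(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = rng.uniform(0, 5, size=(15, 10))
            m = OmicsMatrix("mrna", pd.DataFrame(
                v, index=[f"g{i}" for i in range(15)],
                columns=[f"s{i}" for i in range(10)]))
            res = nmf_cluster(m, k=3, seed=seed, n_restarts=2, max_iter=200)
            tr = res.objective_trace
            assert np.all(np.diff(tr) <= 1e-10 * np.maximum(tr[:-1], 1.0))

    def test_exact_rank_k_reconstruction(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(0.5, 2, (30, 3))
        h = rng.uniform(0.5, 2, (3, 20))
        v = w @ h
        m = OmicsMatrix("mrna", pd.DataFrame(
            v, index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(20)]))
        res = nmf_cluster(m, k=3, seed=1, n_restarts=5, max_iter=3000,
                          tol=1e-12)
        err = float(np.linalg.norm(v - res.W @ res.H) ** 2)
        assert err < 1e-6 * np.linalg.norm(v) ** 2

    def test_negative_input_rejected(self):
        m = random_matrix(5, 6, seed=0)  # real-valued protein
        with pytest.raises(ValueError):
            nmf_cluster(m, k=2, seed=0)

    def test_best_restart_is_best(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 3, (12, 9))
        m = OmicsMatrix("mrna", pd.DataFrame(
            v, index=[f"g{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(9)]))
        multi = nmf_cluster(m, k=2, seed=7, n_restarts=6)
        singles = [nmf_cluster(m, k=2, seed=7, n_restarts=1).partition.quality]
        assert multi.partition.quality <= min(singles) + 1e-9


class TestScreenK:
    def test_full_sweep_row_count(self, small_cohort):
        m = small_cohort.matrices["protein"]
        surv = small_cohort.survival.subset(m.sample_ids)
        rows = screen_k(m, surv, k_range=range(2, 10), seed=0)
        assert len(rows) == 24
        ok = [r for r in rows if r.status == "ok"]
        assert all(r.logrank_p is not None for r in ok)

    def test_single_method_single_k(self, small_cohort):
        m = small_cohort.matrices["protein"]
        surv = small_cohort.survival.subset(m.sample_ids)
        rows = screen_k(m, surv, methods=["PAM"], k_range=[2], seed=0)
        assert len(rows) == 1 and rows[0].method == "PAM" and rows[0].k == 2

    def test_too_few_samples(self, two_blob_matrix):
        from omnisub.containers import SurvivalTable
        surv = SurvivalTable(pd.DataFrame(
            {"event": [1] * 6, "time_days": [1.0, 2, 3, 4, 5, 6]},
            index=two_blob_matrix.sample_ids))
        with pytest.raises(ValueError):
            screen_k(two_blob_matrix, surv, k_range=range(2, 10))
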