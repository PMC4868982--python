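"""Subtype gene sets, heatmap ordering, enrichment, overlap, clinical tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from omnisub.containers import ClinicalTable, OmicsMatrix, Partition
from omnisub.characterize import (clinical_association, enrich_gene_set,
                                  fold_change_sets, marker_profile,
                                  matched_starred_pairs,
                                  order_rows_for_heatmap, overlap_partitions,
                                  read_gmt)


def matrix_from(rows, genes, samples):
    return OmicsMatrix("mrna", pd.DataFrame(
        np.asarray(rows, dtype=float), index=genes, columns=samples))


def partition_of(labels, samples):
    s = pd.Series(labels, index=samples)
    return Partition("PAM", int(s.max()), s)


class TestFoldChangeSets:
    def test_up_down_assignment(self):
        samples = list("abcdef")
        part = partition_of([1, 1, 1, 2, 2, 2], samples)
        m = matrix_from([[10, 10, 10, 4, 4, 4],     # ratio 2.5 -> up in 1
                         [5, 5, 5, 5, 5, 5],        # ratio 1 -> neither
                         [2, 2, 2, 8, 8, 8]],       # up in 2, down in 1
                        ["g_up", "g_flat", "g_dn"], samples)
        sets = fold_change_sets(m, part, epsilon=0.0)
        assert sets.up[1] == ["g_up"] and sets.down[1] == ["g_dn"]
        assert sets.up[2] == ["g_dn"] and sets.down[2] == ["g_up"]
        assert "g_flat" not in sets.up[1] + sets.down[1]

    def test_zero_rest_mean_uses_pseudocount(self):
        samples = list("abcd")
        part = partition_of([1, 1, 2, 2], samples)
        m = matrix_from([[1, 1, 0, 0]], ["g"], samples)
        sets = fold_change_sets(m, part, epsilon=0.01)
        assert sets.up[1] == ["g"]
        assert np.isfinite(sets.ratios.at["g", 1])

    def test_single_cluster_rejected(self):
        samples = list("ab")
        part = partition_of([1, 1], samples)
        with pytest.raises(ValueError):
            fold_change_sets(matrix_from([[1, 2]], ["g"], samples), part)

    def test_threshold_one_partitions_non_tied_genes(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(10)]
        part = partition_of([1] * 5 + [2] * 5, samples)
        m = matrix_from(rng.uniform(1, 5, (20, 10)),
                        [f"g{i}" for i in range(20)], samples)
        sets = fold_change_sets(m, part, up=1.0, down=1.0, epsilon=0.0)
        for c in (1, 2):
            both = set(sets.up[c]) & set(sets.down[c])
            neither = (set(m.feature_ids) - set(sets.up[c])
                       - set(sets.down[c]))
            # continuous data: ties have probability zero
            assert not both or all(sets.ratios.at[g, c] == 1.0 for g in both)
            assert not neither


class TestHeatmapOrder:
    def test_blocks_and_tie_rule(self):
        samples = list("abcdef")
        part = partition_of([1, 1, 2, 2, 3, 3], samples)
        m = matrix_from([[9, 9, 1, 1, 1, 1],
                         [1, 1, 9, 9, 1, 1],
                         [1, 1, 1, 1, 9, 9],
                         [2, 2, 2, 2, 2, 2]],
                        ["u1", "u2", "u3", "flat"], samples)
        sets = fold_change_sets(m, part, epsilon=0.0)
        order, blocks = order_rows_for_heatmap(m, part, sets)
        assert order == ["u1", "u2", "u3", "flat"]
        assert blocks[1] == (0, 1) and blocks[3] == (2, 3)
        assert blocks[0] == (3, 4)  # tail block

    def test_multi_cluster_gene_joins_best_ratio_block(self):
        # a large silent cluster lets one gene be >2-fold up in both small
        # clusters; the block with the larger ratio wins
        samples = [f"s{i}" for i in range(8)]
        part = partition_of([1] * 6 + [2, 3], samples)
        m = matrix_from([[0, 0, 0, 0, 0, 0, 3.0, 4.0]], ["g"], samples)
        sets = fold_change_sets(m, part, epsilon=0.1)
        assert "g" in sets.up[2] and "g" in sets.up[3]
        assert sets.ratios.at["g", 3] > sets.ratios.at["g", 2]
        order, blocks = order_rows_for_heatmap(m, part, sets)
        assert blocks[3] == (0, 1)

    def test_no_gene_up_keeps_original_order(self):
        samples = list("abcd")
        part = partition_of([1, 1, 2, 2], samples)
        m = matrix_from(np.ones((3, 4)), ["x", "y", "z"], samples)
        sets = fold_change_sets(m, part, epsilon=0.0)
        order, blocks = order_rows_for_heatmap(m, part, sets)
        assert order == ["x", "y", "z"] and list(blocks) == [0]


class TestMarkerProfile:
    def test_means_and_invariance(self):
        samples = list("abcd")
        part = partition_of([1, 1, 2, 2], samples)
        m = matrix_from([[1, 3, 5, 7], [2, 2, 2, 2]], ["g1", "g2"], samples)
        prof = marker_profile(m, part, ["g1", "g2"])
        assert prof.at["g1", 1] == 2.0 and prof.at["g1", 2] == 6.0
        assert (prof.loc["g2"] == 2.0).all()
        m2 = OmicsMatrix("mrna", m.values[["b", "a", "d", "c"]])
        pd.testing.assert_frame_equal(marker_profile(m2, part, ["g1", "g2"]),
                                      prof)

    def test_unknown_gene_listed(self):
        samples = list("ab")
        part = partition_of([1, 2], samples)
        m = matrix_from([[1, 2]], ["g"], samples)
        with pytest.raises(KeyError, match="nope"):
            marker_profile(m, part, ["g", "nope"])


class TestEnrichment:
    def test_exact_term_match_closed_form(self):
        universe = {f"u{i}" for i in range(1000)}
        term = {f"u{i}" for i in range(10)}
        out = enrich_gene_set(term, universe, {"T": term})
        p = out.loc[0, "p_value"]
        assert p == pytest.approx(1.0 / comb(1000, 10), rel=1e-9)
        assert p < 1e-15 and bool(out.loc[0, "significant"])

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        universe = [f"u{i}" for i in range(500)]
        terms = {f"T{j}": set(rng.choice(universe, 25, replace=False))
                 for j in range(20)}
        hits = total = 0
        for _ in range(200):
            genes = set(rng.choice(universe, 40, replace=False))
            out = enrich_gene_set(genes, set(universe), terms)
            hits += int(out["significant"].sum())
            total += len(out)
        assert 0.02 < hits / total < 0.08

    def test_disjoint_term_skipped(self):
        out = enrich_gene_set({"a"}, {"a", "b"}, {"T": {"zz"}})
        assert len(out) == 0

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            enrich_gene_set(set(), set(), {"T": {"a"}})

    def test_read_gmt(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\tdesc\tg1\tg2\tg3\nT2\tother\tg9\n")
        sets = read_gmt(p)
        assert sets == {"T1": {"g1", "g2", "g3"}, "T2": {"g9"}}


class TestOverlap:
    def test_identical_partitions_closed_form(self):
        samples = [f"S{i}" for i in range(20)]
        part = partition_of([1] * 10 + [2] * 10, samples)
        other = Partition("HC", 2, part.labels.copy())
        res = overlap_partitions(part, other)
        # 2x2 chi-square closed form: n(ad-bc)^2 / margins = 20
        assert res.pair_p[(1, 1)] == pytest.approx(
            float(stats.chi2.sf(20.0, 1)), rel=1e-9)
        assert res.pair_stars[(1, 1)] == "***"
        assert res.pair_enriched[(1, 1)]
        assert matched_starred_pairs(res) == 2

    def test_relabeling_preserves_pair_p(self):
        rng = np.random.default_rng(2)
        samples = [f"S{i}" for i in range(60)]
        a = partition_of(rng.integers(1, 4, 60), samples)
        b = partition_of(rng.integers(1, 4, 60), samples)
        res = overlap_partitions(a, b)
        remap = {1: 2, 2: 3, 3: 1}
        b2 = partition_of(b.labels.map(remap).to_numpy(), samples)
        res2 = overlap_partitions(a, b2)
        for (ai, bi), p in res.pair_p.items():
            assert res2.pair_p[(ai, remap[bi])] == pytest.approx(p, rel=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(80)]
        a = partition_of(rng.integers(1, 4, 80), samples)
        b = partition_of(rng.integers(1, 3, 80), samples)
        r1 = overlap_partitions(a, b)
        r2 = overlap_partitions(b, a)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_null_star_rate(self):
        """Independent partitions: per-pair p roughly uniform, ~5% starred."""
        rng = np.random.default_rng(4)
        starred = total = 0
        all_p = []
        for _ in range(30):
            samples = [f"S{i}" for i in range(500)]
            a = partition_of(rng.integers(1, 5, 500), samples)
            b = partition_of(rng.integers(1, 5, 500), samples)
            res = overlap_partitions(a, b)
            for key, p in res.pair_p.items():
                all_p.append(p)
                starred += res.pair_stars[key] != "ns"
                total += 1
        assert 0.02 < starred / total < 0.09
        assert stats.kstest(all_p, "uniform").pvalue > 0.001

    def test_exact_flag_uses_fisher(self):
        samples = [f"S{i}" for i in range(12)]
        a = partition_of([1] * 6 + [2] * 6, samples)
        b = partition_of([1] * 5 + [2] * 7, samples)
        res = overlap_partitions(a, b, exact=True)
        expected = stats.fisher_exact([[5, 1], [0, 6]]).pvalue
        assert res.pair_p[(1, 1)] == pytest.approx(expected, rel=1e-12)

    def test_disjoint_samples_rejected(self):
        a = partition_of([1, 2], ["x", "y"])
        b = partition_of([1, 2], ["p", "q"])
        with pytest.raises(ValueError):
            overlap_partitions(a, b)


class TestClinicalAssociation:
    def test_anova_hand_computed(self):
        """Groups {1,2,3} vs {4,5,6}: F = 13.5 on df (1, 4)."""
        samples = list("abcdef")
        part = partition_of([1, 1, 1, 2, 2, 2], samples)
        clin = ClinicalTable(
            pd.DataFrame({"v": [1.0, 2, 3, 4, 5, 6]}, index=samples),
            {"v": "quantitative"})
        out = clinical_association(clin, part).set_index("variable")
        assert out.at["v", "statistic"] == pytest.approx(13.5)
        f, p = stats.f_oneway([1, 2, 3], [4, 5, 6])
        assert out.at["v", "p_value"] == pytest.approx(p)

    def test_single_level_skipped(self):
        samples = list("abcd")
        part = partition_of([1, 1, 2, 2], samples)
        clin = ClinicalTable(pd.DataFrame({"v": ["x"] * 4}, index=samples),
                             {"v": "categorical"})
        out = clinical_association(clin, part)
        assert "skipped" in out.loc[0, "note"]

    def test_null_categorical_calibration(self):
        """A cluster-independent categorical variable is non-significant in
        most simulations."""
        rng = np.random.default_rng(5)
        ok = 0
        n_sims = 100
        samples = [f"S{i}" for i in range(600)]
        for _ in range(n_sims):
            part = partition_of(rng.integers(1, 5, 600), samples)
            clin = ClinicalTable(
                pd.DataFrame({"v": rng.choice(list("xyz"), 600)},
                             index=samples), {"v": "categorical"})
            out = clinical_association(clin, part)
            ok += out.loc[0, "p_value"] > 0.05
        assert ok >= 0.9 * n_sims

    def test_known_positive_and_negative(self, small_cohort):
        part = Partition("PAM", 3, small_cohort.true_labels)
        out = clinical_association(small_cohort.clinical,
                                   part).set_index("variable")
        assert out.at["tumor_size_cm", "p_value"] < 0.01
        assert out.at["clinical_stage", "p_value"] < 0.05
        assert out.at["age", "p_value"] > 0.001
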