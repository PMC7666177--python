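"""Branch DE, Tukey/Fisher oracles, biclustering and the resistance
pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import pseudotree as pt
from pseudotree.preprocess import ExpressionMatrix


def _expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        "log_cpm",
    )


class TestReferenceBranch:
    def test_highest_control_fraction_wins(self):
        b = np.array([1] * 10 + [2] * 10 + [3] * 10)
        ctrl = np.array([True] * 9 + [False] * 1 + [True] * 2 + [False] * 8 + [True] * 1 + [False] * 9)
        assert pt.select_reference_branch(b, ctrl) == 1

    def test_tie_broken_by_size(self):
        b = np.array([1] * 30 + [2] * 10)
        ctrl = np.array([True] * 15 + [False] * 15 + [True] * 5 + [False] * 5)
        assert pt.select_reference_branch(b, ctrl) == 1

    def test_all_controls_gives_largest_branch(self):
        b = np.array([1] * 5 + [2] * 9)
        ctrl = np.ones(14, dtype=bool)
        assert pt.select_reference_branch(b, ctrl) == 2

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError):
            pt.select_reference_branch(np.array([1, 2]), np.array([False, False]))


class TestStudentizedRange:
    def test_matches_independent_oracle(self):
        q = np.array([0.5, 1.0, 2.0, 3.0, 4.5, 6.0, 8.0])
        for k, df in [(2, 8), (3, 30), (4, 57), (6, 294)]:
            mine = pt.studentized_range_sf(q, k, df)
            oracle = stats.studentized_range.sf(q, k, df)
            assert np.abs(mine - oracle).max() < 1e-9

    def test_two_groups_equal_pooled_t(self, rng):
        for df in (10, 57, 200):
            tvals = rng.uniform(0.1, 5.0, 20)
            mine = pt.studentized_range_sf(np.sqrt(2.0) * tvals, 2, df)
            oracle = 2.0 * stats.t.sf(tvals, df)
            assert np.abs(mine - oracle).max() < 1e-8


class TestBranchAnovaTukey:
    def test_two_branch_tukey_equals_pooled_ttest(self, rng):
        X = rng.normal(size=(40, 30))
        b = np.array([1] * 14 + [2] * 16)
        table = pt.branch_anova_tukey(_expr(X), b, reference=1)
        tt = stats.ttest_ind(X[:, 14:], X[:, :14], axis=1, equal_var=True)
        np.testing.assert_allclose(table["tukey_p"].to_numpy(), tt.pvalue, atol=1e-8)

    def test_planted_program_sensitivity(self, rng):
        n_per, m = 25, 200
        b = np.repeat([1, 2, 3], n_per)
        X = rng.normal(size=(m, 3 * n_per))
        planted = np.arange(60)
        X[np.ix_(planted, np.where(b == 2)[0])] += 1.5
        table = pt.branch_anova_tukey(_expr(X), b, reference=1, fdr=0.05)
        hits = table[(table.branch == 2) & table.significant]["gene"]
        sens = len(set(hits) & {f"g{i}" for i in planted}) / len(planted)
        assert sens >= 0.8

    def test_null_fdr_controlled(self, rng):
        fdps = []
        b = np.repeat([1, 2, 3], 15)
        for _ in range(30):
            X = rng.normal(size=(150, 45))
            table = pt.branch_anova_tukey(_expr(X), b, reference=1, fdr=0.05)
            fdps.append(1.0 if table["significant"].any() else 0.0)
        assert np.mean(fdps) <= 0.15

    def test_small_branch_excluded_with_warning(self, rng):
        X = rng.normal(size=(5, 21))
        b = np.array([1] * 10 + [2] * 10 + [3])
        with pytest.warns(UserWarning, match="excluded"):
            table = pt.branch_anova_tukey(_expr(X), b, reference=1)
        assert set(table["branch"]) == {2}

    def test_zero_variance_degenerate_rule(self):
        X = np.vstack([[1.0] * 4 + [2.0] * 4, [3.0] * 8])
        b = np.array([1] * 4 + [2] * 4)
        table = pt.branch_anova_tukey(_expr(X), b, reference=1)
        g0 = table[table.gene == "g0"].iloc[0]
        g1 = table[table.gene == "g1"].iloc[0]
        assert g0["degenerate"] and g0["tukey_p"] == 0.0
        assert g1["degenerate"] and g1["tukey_p"] == 1.0

    def test_direction_consistent_with_sign(self, rng):
        X = rng.normal(size=(30, 40))
        b = np.repeat([1, 2], 20)
        table = pt.branch_anova_tukey(_expr(X), b, reference=1)
        assert (
            (table["direction"] == "up") == (table["mean_diff"] > 0)
        ).all()
        assert (table["adjusted_p"] >= table["tukey_p"] - 1e-12).all()


class TestDirectionSets:
    def test_single_up_gene(self):
        table = pd.DataFrame(
            {
                "gene": ["gA", "gB"],
                "branch": [2, 3],
                "direction": ["up", "down"],
                "adjusted_p": [0.01, 0.5],
            }
        )
        out = pt.direction_gene_sets(table, fdr=0.05)
        assert out == {(2, "up"): ["gA"]}

    def test_no_significant_genes_empty_mapping(self):
        table = pd.DataFrame(
            {"gene": ["g"], "branch": [2], "direction": ["up"], "adjusted_p": [0.9]}
        )
        assert pt.direction_gene_sets(table) == {}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pt.direction_gene_sets(pd.DataFrame())


class TestFisherEnrichment:
    def test_hand_enumeration_case(self):
        # universe 8, set 4, query 4, overlap 3:
        # p = [C(4,3)C(4,1) + C(4,4)C(4,0)] / C(8,4) = 17/70
        universe = [f"u{i}" for i in range(8)]
        gene_set = universe[:4]
        query = universe[:3] + [universe[5]]
        out = pt.fisher_enrichment(query, {"s": gene_set}, universe)
        np.testing.assert_allclose(out["p"].iloc[0], 17 / 70, atol=1e-12)

    def test_disjoint_query_depletion_direction(self):
        universe = [f"u{i}" for i in range(20)]
        out = pt.fisher_enrichment(universe[10:14], {"s": universe[:10]}, universe)
        assert out["p"].iloc[0] >= 0.5

    def test_query_equals_set_is_minimal_p(self):
        universe = [f"u{i}" for i in range(12)]
        gene_set = universe[:5]
        M, K, n = 12, 5, 5
        full = pt.fisher_enrichment(gene_set, {"s": gene_set}, universe)["p"].iloc[0]
        # enumeration over all achievable overlaps for these margins
        for a in range(max(0, n + K - M), min(n, K) + 1):
            p_a = stats.hypergeom.sf(a - 1, M, K, n)
            assert full <= p_a + 1e-12

    def test_matches_exact_enumeration_all_small_universes(self):
        # brute-force oracle: survival probabilities from exact binomial
        # coefficients for every table with universe size <= 40
        for M in range(1, 41):
            for K in range(0, M + 1, max(1, M // 4)):
                for n in range(0, M + 1, max(1, M // 4)):
                    denom = math.comb(M, n)
                    lo = max(0, n + K - M)
                    hi = min(n, K)
                    pmf = {
                        a: math.comb(K, a) * math.comb(M - K, n - a) / denom
                        for a in range(lo, hi + 1)
                    }
                    for a in range(lo, hi + 1):
                        exact = sum(pmf[j] for j in range(a, hi + 1))
                        sf = stats.hypergeom.sf(a - 1, M, K, n)
                        assert abs(sf - exact) < 1e-10

    def test_query_outside_universe_dropped_with_warning(self):
        universe = ["a", "b", "c", "d"]
        with pytest.warns(UserWarning, match="dropped"):
            out = pt.fisher_enrichment(["a", "zzz"], {"s": ["a", "b"]}, universe)
        assert out["query_size"].iloc[0] == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            pt.fisher_enrichment(["a"], {"s": ["a"]}, [])


class TestBranchMeansAndBicluster:
    def test_constant_gene_flagged_zero_row(self):
        X = np.vstack([[5.0] * 6, [1, 2, 3, 4, 5, 6]])
        out = pt.branch_mean_matrix(_expr(X), np.array([1, 1, 1, 2, 2, 2]))
        assert out.attrs["constant_genes"] == ["g0"]
        np.testing.assert_allclose(out.loc["g0"], 0.0)

    def test_single_sample_branch_value(self):
        X = np.array([[0.0, 2.0, 4.0]])
        out = pt.branch_mean_matrix(_expr(X), np.array([1, 1, 2]))
        z = (4.0 - 2.0) / np.std([0, 2, 4])
        np.testing.assert_allclose(out.loc["g0", 2], z)

    def test_block_structure_visible_and_recovered(self, rng):
        b = np.repeat([1, 2], 15)
        X = rng.normal(size=(40, 30), scale=0.2)
        X[:20, :15] += 3.0   # block A high in branch 1
        X[20:, 15:] += 3.0   # block B high in branch 2
        bm = pt.branch_mean_matrix(_expr(X), b)
        assert (bm.iloc[:20, 0] > bm.iloc[:20, 1]).all()
        labels, border, gorder = pt.bicluster(bm, n_gene_clusters=2)
        truth = np.array([0] * 20 + [1] * 20)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_cluster_and_permutation_invariance(self, rng):
        bm = pd.DataFrame(rng.normal(size=(25, 4)), index=[f"g{i}" for i in range(25)])
        labels1, _, _ = pt.bicluster(bm, n_gene_clusters=1)
        assert set(labels1) == {1}
        labels4, _, _ = pt.bicluster(bm, n_gene_clusters=4)
        perm = rng.permutation(25)
        labels4p, _, _ = pt.bicluster(bm.iloc[perm], n_gene_clusters=4)
        assert adjusted_rand_score(labels4[perm], labels4p) == 1.0


class TestResistance:
    def test_quantile_hand_case(self):
        # 10 evenly spaced pseudotimes 0.0..0.9: the type-7 0.8-quantile is
        # 0.72, so the two controls (0.8 and 0.9) are both strictly above
        ptime = np.arange(10) / 10.0
        ctrl = np.zeros(10, dtype=bool)
        ctrl[[8, 9]] = True
        out = pt.resistant_individuals(ptime, ctrl, quantile=0.8)
        assert out == [8, 9]
        np.testing.assert_allclose(np.quantile(ptime, 0.8), 0.72)

    def test_all_cases_high_gives_empty_with_warning(self):
        ptime = np.linspace(0, 1, 10)
        ctrl = np.array([True] * 5 + [False] * 5)
        with pytest.warns(UserWarning, match="resistant"):
            out = pt.resistant_individuals(ptime, ctrl, quantile=0.8)
        assert out == []

    def test_resistant_de_recovers_planted_cluster(self, rng):
        n, m = 200, 400
        X = rng.normal(size=(m, n))
        flags = np.zeros(n, dtype=bool)
        flags[:9] = True
        planted = np.arange(50)
        X[np.ix_(planted, np.where(flags)[0])] += 2.0
        up, down, table = pt.resistant_de(_expr(X), flags)
        sens = len(set(up) & {f"g{i}" for i in planted}) / 50
        assert sens >= 0.9

    def test_resistant_de_null_controlled(self, rng):
        any_hit = []
        flags = np.zeros(60, dtype=bool)
        flags[:10] = True
        for _ in range(30):
            X = rng.normal(size=(200, 60))
            up, down, _ = pt.resistant_de(_expr(X), flags)
            any_hit.append(1.0 if (up or down) else 0.0)
        assert np.mean(any_hit) <= 0.15

    def test_too_small_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            pt.resistant_de(_expr(rng.normal(size=(5, 6))), [True] + [False] * 5)


class TestOverlapUpset:
    def test_exclusive_counts(self):
        pair, excl = pt.overlap_upset(
            {"A": ["1", "2"], "B": ["2", "3"]}, [str(i) for i in range(1, 10)]
        )
        assert excl[("A",)] == 1 and excl[("B",)] == 1 and excl[("A", "B")] == 1

    def test_identical_lists_maximal_overlap(self):
        uni = [str(i) for i in range(30)]
        pair, _ = pt.overlap_upset({"A": uni[:8], "B": uni[:8]}, uni)
        assert pair["overlap"].iloc[0] == 8
        assert pair["p"].iloc[0] < 1e-6

    def test_disjoint_lists_null_direction(self):
        uni = [str(i) for i in range(1000)]
        pair, _ = pt.overlap_upset({"A": uni[:20], "B": uni[500:520]}, uni)
        assert pair["p"].iloc[0] > 0.3

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            pt.overlap_upset({"A": ["zzz"]}, ["a"])
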