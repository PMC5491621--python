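"""ANOVA/Duncan, PCA, hierarchical bi-clustering, k-means, Venn counting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.stats import f_oneway, studentized_range

from berrychron import (
    SampleGrouping,
    anova_oneway,
    duncan_letters,
    group_specific_features,
    hierarchical_bicluster,
    kmeans_restarts,
    pca,
)
from berrychron.quantify import StageSeries, stage_average

from conftest import make_design, make_matrix


def sample_series(values, stages=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    stages = stages or [f"S{i + 1}" for i in range(values.shape[1])]
    ids = [f"f{i + 1}" for i in range(values.shape[0])]
    return StageSeries(pd.DataFrame(values, index=ids, columns=stages))


class TestAnova:
    def test_matches_scipy_oracle_on_random_tables(self, rng):
        design = make_design(4, 3)
        for _ in range(25):
            vals = rng.normal(10, 2, 12)
            res = anova_oneway(pd.Series(vals, index=design.samples), design)
            groups = [vals[i * 3 : (i + 1) * 3] for i in range(4)]
            F_ref, p_ref = f_oneway(*groups)
            assert res.F == pytest.approx(F_ref, abs=1e-10, rel=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10, rel=1e-10)

    def test_hand_computed_sum_of_squares(self):
        design = make_design(3, 3)
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        # groups (1,2,3),(4,5,6),(7,8,9): SSb=54, SSw=6, F=(54/2)/(6/6)=27
        res = anova_oneway(pd.Series(vals, index=design.samples), design)
        assert res.F == pytest.approx(27.0, abs=1e-10)
        assert res.mse == pytest.approx(1.0, abs=1e-12)

    def test_all_identical_flat(self):
        design = make_design(3, 3)
        res = anova_oneway(pd.Series(np.full(9, 2.5), index=design.samples), design)
        assert res.F == 0.0 and res.p == 1.0 and res.degenerate

    def test_perfect_separation_flagged(self):
        design = make_design(2, 3)
        vals = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        res = anova_oneway(pd.Series(vals, index=design.samples), design)
        assert math.isinf(res.F) and res.p == 0.0 and res.degenerate

    def test_requires_replication(self):
        design = make_design(3, 1)
        with pytest.raises(ValueError, match="replicates"):
            anova_oneway(pd.Series([1.0, 2.0, 3.0], index=design.samples), design)


def duncan_oracle(means, n, mse, df_e, alpha=0.05):
    """Independent step-down multiple-range implementation (iterative,
    significance matrix) used as oracle for the recursive letter builder."""
    labels = list(means.index)
    k = len(labels)
    order = np.argsort(-means.to_numpy())
    m = means.to_numpy()[order]
    sep = np.zeros((k, k), dtype=bool)  # sep[i,j]: i..j significantly separated
    stack = [(0, k - 1)]
    homog = []
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        p = j - i + 1
        alpha_p = 1 - (1 - alpha) ** (p - 1)
        rp = studentized_range.ppf(1 - alpha_p, p, df_e) * math.sqrt(mse / n)
        if m[i] - m[j] <= rp:
            homog.append((i, j))
        else:
            stack.extend([(i, j - 1), (i + 1, j)])
    homog += [(i, i) for i in range(k)]
    maximal = [
        (i, j)
        for (i, j) in set(homog)
        if not any(a <= i and j <= b and (a, b) != (i, j) for a, b in set(homog))
    ]
    letters = {lab: set() for lab in labels}
    for idx, (i, j) in enumerate(sorted(maximal)):
        for pos in range(i, j + 1):
            letters[labels[order[pos]]].add(idx)
    return letters


class TestDuncan:
    def test_equal_means_share_letter(self):
        means = pd.Series([5.0, 5.0, 5.0], index=list("xyz"))
        letters = duncan_letters(means, 3, mse=1.0, df_e=6)
        assert set(letters.values()) == {"a"}

    def test_far_apart_means_distinct_letters(self):
        means = pd.Series([100.0, 0.0], index=["hi", "lo"])
        letters = duncan_letters(means, 3, mse=0.5, df_e=4)
        assert letters["hi"] != letters["lo"]
        assert not set(letters["hi"]) & set(letters["lo"])

    def test_huge_mse_collapses_to_one_letter(self):
        means = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        letters = duncan_letters(means, 3, mse=1e9, df_e=8)
        assert set(letters.values()) == {"a"}

    def test_tiny_mse_all_distinct(self):
        means = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        letters = duncan_letters(means, 3, mse=1e-12, df_e=8)
        assert len(set(letters.values())) == 4

    def test_matches_independent_recursion_on_fixtures(self, rng):
        for _ in range(15):
            k = int(rng.integers(3, 7))
            means = pd.Series(rng.normal(0, 2, k), index=[f"g{i}" for i in range(k)])
            mse = float(rng.uniform(0.1, 4.0))
            letters = duncan_letters(means, 3, mse=mse, df_e=2 * k)
            oracle = duncan_oracle(means, 3, mse, 2 * k)
            for a in means.index:
                for b in means.index:
                    shared = bool(set(letters[a]) & set(letters[b]))
                    shared_oracle = bool(oracle[a] & oracle[b])
                    assert shared == shared_oracle, (a, b, letters, oracle)

    def test_df_below_one_rejected(self):
        means = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="df_e"):
            duncan_letters(means, 3, mse=1.0, df_e=0)


class TestPca:
    def test_variance_explained_sums_to_100(self, rng):
        res = pca(pd.DataFrame(rng.normal(0, 1, (10, 6))))
        assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-8)

    def test_known_eigenvalue_share(self, rng):
        # covariance diag(2,1): PC1 share -> 2/3 at large n
        X = rng.multivariate_normal([0, 0], [[2, 0], [0, 1]], size=20000)
        res = pca(pd.DataFrame(X))
        assert res.variance_explained[0] / 100 == pytest.approx(2 / 3, abs=0.02)

    def test_components_orthogonal(self, rng):
        res = pca(pd.DataFrame(rng.normal(0, 1, (8, 5))))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_feature_permutation_leaves_scores_invariant(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (7, 6)), columns=[f"f{i}" for i in range(6)])
        perm = ["f3", "f0", "f5", "f1", "f4", "f2"]
        a, b = pca(X), pca(X[perm])
        assert np.allclose(np.abs(a.scores), np.abs(b.scores), atol=1e-10)

    def test_duplicated_features_preserve_score_geometry(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (6, 4)))
        doubled = pd.concat([X, X.add_suffix("_dup", axis=1)], axis=1)
        a, b = pca(X), pca(doubled)
        # scores scale by sqrt(2); relative geometry identical
        ratio = np.abs(b.scores.to_numpy()[:, :3]) / np.abs(a.scores.to_numpy()[:, :3])
        assert np.allclose(ratio, math.sqrt(2), atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca(pd.DataFrame(np.ones((5, 3))))


class TestBicluster:
    def test_identical_columns_merge_at_zero(self, rng):
        col = rng.normal(0, 1, 6)
        mat = pd.DataFrame({"a": col, "b": col, "c": col + 10})
        res = hierarchical_bicluster(mat, k_groups=2)
        assert res.col_linkage[0, 2] == pytest.approx(0.0)

    def test_pair_versus_singleton_grouping(self, rng):
        col = rng.normal(0, 1, 6)
        mat = pd.DataFrame({"a": col, "b": col + 0.01, "c": col + 50})
        res = hierarchical_bicluster(mat, k_groups=2)
        g = res.grouping.membership
        assert g["a"] == g["b"] != g["c"]

    def test_single_group_cut(self, rng):
        mat = pd.DataFrame(rng.normal(0, 1, (5, 4)))
        res = hierarchical_bicluster(mat, k_groups=1)
        assert set(res.grouping.membership.index) == {0, 1, 2, 3}
        assert res.grouping.membership.nunique() == 1

    def test_too_many_groups_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(0, 1, (5, 3)))
        with pytest.raises(ValueError, match="k_groups"):
            hierarchical_bicluster(mat, k_groups=4)


class TestKmeans:
    def test_exact_cover_zero_distance(self):
        profiles = np.array([[0, 0, 0, 0.0], [5, 5, 5, 5.0], [0, 9, 0, 9.0]])
        series = sample_series(np.repeat(profiles, 4, axis=0))
        model = kmeans_restarts(series, k=3, restarts=10, seed=0)
        assert model.total_distance == pytest.approx(0.0, abs=1e-12)

    def test_separated_blobs_recovered(self, rng):
        a = rng.normal(0, 0.05, (10, 5))
        b = rng.normal(8, 0.05, (10, 5))
        series = sample_series(np.vstack([a, b]))
        model = kmeans_restarts(series, k=2, restarts=5, seed=1)
        labels = model.assignments.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_best_distance_nonincreasing_in_restarts(self, rng):
        series = sample_series(rng.normal(0, 1, (40, 6)))
        dists = [
            kmeans_restarts(series, k=5, restarts=r, seed=7).total_distance
            for r in (1, 3, 10, 30)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))

    def test_invalid_k_rejected(self, rng):
        series = sample_series(rng.normal(0, 1, (4, 5)))
        with pytest.raises(ValueError, match="k"):
            kmeans_restarts(series, k=0)
        with pytest.raises(ValueError, match="k"):
            kmeans_restarts(series, k=10)

    def test_deterministic_given_seed(self, rng):
        series = sample_series(rng.normal(0, 1, (30, 6)))
        m1 = kmeans_restarts(series, k=4, restarts=8, seed=3)
        m2 = kmeans_restarts(series, k=4, restarts=8, seed=3)
        assert m1.total_distance == m2.total_distance
        assert m1.assignments.tolist() == m2.assignments.tolist()
        assert m1.best_restart_seed == m2.best_restart_seed


class TestVenn:
    def grouping(self):
        # stages S1..S6 into 3 groups of 2
        return SampleGrouping(3, pd.Series([1, 1, 2, 2, 3, 3],
                                           index=[f"S{i + 1}" for i in range(6)]))

    def build(self, detect):
        """detect: feature -> set of groups where it is fully present."""
        design = make_design(6, 3)
        rows = []
        for groups in detect.values():
            row = []
            for stage_idx in range(6):
                g = stage_idx // 2 + 1
                # fully present in the first stage of each detected group
                present = g in groups and stage_idx % 2 == 0
                row.extend([1.0, 1.0, 1.0] if present else [1.0, 0.0, 1.0])
            rows.append(row)
        m = make_matrix(rows, design, kind="protein", feature_ids=list(detect))
        return m, design

    def test_common_and_specific_regions(self):
        detect = {"all": {1, 2, 3}, "only1": {1}, "only2": {2}, "g13": {1, 3}, "none": set()}
        m, design = self.build(detect)
        venn = group_specific_features(m, design, self.grouping())
        assert venn.common == 1
        assert venn.specific(1) == 1 and venn.specific(2) == 1 and venn.specific(3) == 0
        assert venn.counts[(1, 3)] == 1
        assert venn.undetected == ["none"]

    def test_matches_exhaustive_enumeration(self, rng):
        import itertools

        names, detect = [], {}
        for i, combo in enumerate(itertools.product([0, 1], repeat=3)):
            for rep in range(3):
                name = f"f{i}_{rep}"
                names.append(name)
                detect[name] = {g + 1 for g in range(3) if combo[g]}
        m, design = self.build(detect)
        venn = group_specific_features(m, design, self.grouping())
        for key, count in venn.counts.items():
            expected = sum(1 for d in detect.values() if d == set(key))
            assert count == expected, key
        assert len(venn.undetected) == 3
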