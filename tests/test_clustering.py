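import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mirconcord as mc
from mirconcord.clustering import EmptyMatrixError

from conftest import make_table


# ---------------------------------------------------------------------------
# independent brute-force Ward oracle


def _ess(X, members):
    sub = X[list(members)]
    return float(((sub - sub.mean(axis=0)) ** 2).sum())


def brute_ward_partitions(X):
    """Greedy Ward agglomeration by exhaustive evaluation of the ESS increase.

    Returns the sequence of partitions (each a set of frozensets) after
    every merge.
    """
    clusters = [frozenset([i]) for i in range(X.shape[0])]
    partitions = []
    while len(clusters) > 1:
        best, best_cost = None, np.inf
        for a, b in itertools.combinations(clusters, 2):
            cost = _ess(X, a | b) - _ess(X, a) - _ess(X, b)
            if cost < best_cost:
                best, best_cost = (a, b), cost
        a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        partitions.append(frozenset(clusters))
    return partitions


def linkage_partitions(Z, n):
    """Partition sequence implied by a scipy linkage matrix."""
    nodes = {i: frozenset([i]) for i in range(n)}
    partitions = []
    for step, (left, right, _, _) in enumerate(Z):
        merged = nodes.pop(int(left)) | nodes.pop(int(right))
        nodes[n + step] = merged
        partitions.append(frozenset(nodes.values()))
    return partitions


@pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (7, 4)])
def test_ward_agrees_with_brute_force_oracle(n, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    Z = mc.ward_dendrogram(X)
    assert linkage_partitions(Z, n) == brute_ward_partitions(X)


# ---------------------------------------------------------------------------
# expression matrix


class TestExpressionMatrix:
    def _table(self, missing=()):
        rows = []
        for p in ("A", "B"):
            for s in ("s1", "s2", "s3", "s4"):
                for j in range(4):
                    ct = np.nan if (p, s, f"m{j}") in missing else 20.0 + j + hash((s,)) % 3
                    rows.append((p, "r1", s, f"m{j}", 1, ct))
        return make_table(rows)

    def test_no_missing_data_matrix_unchanged(self):
        mats = mc.build_expression_matrices(self._table(), zscore=False)
        m = mats["A"]
        assert not m.imputed.to_numpy().any()
        assert len(m.mirnas) == 4

    def test_row_exceeding_threshold_removed(self):
        # m0 missing 2 of 8 pooled cells = 25% > 15%
        missing = {("A", "s1", "m0"), ("A", "s2", "m0")}
        mats = mc.build_expression_matrices(self._table(missing), zscore=False)
        assert "m0" not in mats["A"].mirnas
        assert "m0" not in mats["B"].mirnas  # pooled filter removes it everywhere

    def test_row_mean_imputation(self):
        missing = {("A", "s2", "m0")}  # 1/8 pooled = 12.5% <= 15%: kept, imputed
        mats = mc.build_expression_matrices(self._table(missing), zscore=False)
        m = mats["A"]
        row = m.values.loc["m0"]
        observed = [row[s] for s in ("s1", "s3", "s4")]
        assert row["s2"] == pytest.approx(np.mean(observed))
        assert m.imputed.loc["m0", "s2"] and m.imputed.to_numpy().sum() == 1

    def test_hand_imputation_example(self):
        rows = [("A", "r1", "s1", "m", 1, 1.0), ("A", "r1", "s3", "m", 1, 3.0),
                ("A", "r1", "s2", "m", 1, np.nan)]
        for j, s in enumerate(("s1", "s2", "s3")):  # second miRNA, complete
            rows.append(("A", "r1", s, "m2", 1, 5.0 + j))
        mats = mc.build_expression_matrices(
            make_table(rows), missing_threshold=0.5, zscore=False
        )
        row = mats["A"].values.loc["m"]
        assert row["s2"] == pytest.approx(2.0)  # mean of 1 and 3

    def test_all_rows_filtered_is_error(self):
        rows = [("A", "r1", "s1", "m", 1, np.nan), ("A", "r1", "s2", "m", 1, np.nan)]
        with pytest.raises(EmptyMatrixError):
            mc.build_expression_matrices(make_table(rows), missing_threshold=0.9)


# ---------------------------------------------------------------------------
# dendrogram / Mojena / k-means


def _planted(n_groups=4, per=8, sep=6.0, sd=1.0, seed=0, d=4):
    rng = np.random.default_rng(seed)
    centers = sep * np.eye(d)[:n_groups]
    X = np.vstack([rng.normal(c, sd, size=(per, d)) for c in centers])
    labels = np.repeat(np.arange(1, n_groups + 1), per)
    return X, labels


class TestDendrogram:
    def test_two_rows_single_merge_height(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        Z = mc.ward_dendrogram(X)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)  # Euclidean distance of the pair

    def test_heights_non_decreasing(self):
        X, _ = _planted(seed=5)
        Z = mc.ward_dendrogram(X)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_close_pair_merges_first(self):
        X = np.array([[0.0], [0.1], [10.0]])
        Z = mc.ward_dendrogram(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_identical_rows_merge_at_zero_height(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        Z = mc.ward_dendrogram(X)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            mc.ward_dendrogram(np.array([[1.0, 2.0]]))


class TestMojena:
    def test_four_separated_groups_give_k4(self):
        X, _ = _planted(sep=10.0, sd=0.3, seed=1)
        Z = mc.ward_dendrogram(X)
        heights = Z[:, 2]
        bound = heights.mean() + 1.25 * heights.std(ddof=1)
        assert (np.sort(heights)[-3:] > bound).all()  # top 3 fusions flagged
        assert mc.mojena_k(Z) == 4

    def test_identical_points_give_k1(self):
        X = np.ones((6, 3))
        assert mc.mojena_k(mc.ward_dendrogram(X)) == 1

    def test_n2_degenerate_defined(self):
        Z = mc.ward_dendrogram(np.array([[0.0], [1.0]]))
        assert mc.mojena_k(Z) in (1, 2)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_monotone_in_constant(self, c1, c2):
        X, _ = _planted(seed=2)
        Z = mc.ward_dendrogram(X)
        lo, hi = sorted([c1, c2])
        assert mc.mojena_k(Z, hi) <= mc.mojena_k(Z, lo)


class TestAssignClusters:
    def test_k1_single_cluster(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        res = mc.assign_clusters(pd.DataFrame(X), 1)
        assert res.k == 1 and set(res.assignment) == {1}

    def test_k_equals_n(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        res = mc.assign_clusters(pd.DataFrame(X), 5)
        assert sorted(res.assignment) == [1, 2, 3, 4, 5]

    def test_k_out_of_range(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            mc.assign_clusters(pd.DataFrame(X), 4)

    def test_well_separated_groups_recovered(self):
        X, labels = _planted(sep=8.0, sd=0.5, seed=3)
        res = mc.assign_clusters(pd.DataFrame(X), 4)
        truth = mc.ClusterResult("truth", 4, pd.Series(labels), {})
        cc = mc.cluster_concordance(truth, res)
        assert cc.misassigned_pct == 0.0

    def test_deterministic(self):
        X, _ = _planted(seed=4)
        r1 = mc.assign_clusters(pd.DataFrame(X), 4)
        r2 = mc.assign_clusters(pd.DataFrame(X), 4)
        assert (r1.assignment == r2.assignment).all()


class TestMojenaWardKMeansEstimator:
    def test_sklearn_api_and_recovery(self):
        from sklearn.base import clone

        X, labels = _planted(sep=8.0, sd=0.5, seed=6)
        est = mc.MojenaWardKMeans()
        assert clone(est).get_params() == est.get_params()
        fitted = est.fit(X)
        assert fitted.n_clusters_ == 4
        assert len(np.unique(fitted.labels_)) == 4
        truth = mc.ClusterResult("t", 4, pd.Series(labels), {})
        got = mc.ClusterResult("e", 4, pd.Series(fitted.labels_ + 1), {})
        assert mc.cluster_concordance(truth, got).misassigned_pct == 0.0

    def test_fixed_n_clusters_overrides_mojena(self):
        X, _ = _planted(seed=7)
        est = mc.MojenaWardKMeans(n_clusters=2).fit(X)
        assert est.n_clusters_ == 2


class TestClusterConcordance:
    def _result(self, labels, platform="P"):
        idx = [f"m{i}" for i in range(len(labels))]
        return mc.ClusterResult(platform, len(set(labels)),
                                pd.Series(labels, index=idx), {})

    def test_self_concordance(self):
        r = self._result([1, 1, 2, 2, 3])
        assert mc.cluster_concordance(r, r).misassigned_pct == 0.0

    def test_label_permutation_invariance(self):
        a = self._result([1, 1, 2, 2, 3, 3])
        b = self._result([3, 3, 1, 1, 2, 2])
        assert mc.cluster_concordance(a, b).misassigned_pct == 0.0

    @given(st.lists(st.integers(1, 4), min_size=4, max_size=12),
           st.permutations([1, 2, 3, 4]))
    def test_relabeling_never_changes_score(self, labels, perm):
        a = self._result(labels)
        b = self._result([perm[l - 1] for l in labels])
        base = mc.cluster_concordance(a, a).misassigned_pct
        assert mc.cluster_concordance(a, b).misassigned_pct == pytest.approx(base)

    def test_single_moved_mirna_over_36(self):
        labels = [1 + i // 9 for i in range(36)]  # 4 clusters of 9
        moved = labels.copy()
        moved[0] = 2
        a, b = self._result(labels), self._result(moved)
        cc = mc.cluster_concordance(a, b)
        assert cc.misassigned_pct == pytest.approx(100.0 / 36.0, abs=1e-6)
        assert round(cc.misassigned_pct, 2) == 2.78

    def test_literal_mode_requires_two_shared(self):
        a = self._result([1, 1, 2, 2])
        b = self._result([1, 2, 2, 1])  # no comparison cluster shares 2 with ref
        cc = mc.cluster_concordance(a, b, mode="literal")
        assert cc.misassigned_pct == 100.0

    def test_empty_intersection_is_error(self):
        a = self._result([1, 1, 2])
        b = mc.ClusterResult("Q", 2, pd.Series([1, 2], index=["x1", "x2"]), {})
        with pytest.raises(ValueError):
            mc.cluster_concordance(a, b)


def test_planted_partition_full_pipeline_recovery():
    """Matrix -> Ward -> Mojena -> k-means recovers 4 planted groups."""
    ok = 0
    for seed in range(100):
        X, labels = _planted(n_groups=4, per=6, sep=6.0, sd=1.0, seed=seed)
        est = mc.MojenaWardKMeans().fit(X)
        if est.n_clusters_ != 4:
            continue
        truth = mc.ClusterResult("t", 4, pd.Series(labels), {})
        got = mc.ClusterResult("e", 4, pd.Series(est.labels_ + 1), {})
        if mc.cluster_concordance(truth, got).misassigned_pct == 0.0:
            ok += 1
    assert ok >= 95
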