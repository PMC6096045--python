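"""Preprocessing, Ward linkage, gap statistic, stability, agreement and
rank-sum testing, each against a closed form or brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from glomcluster.cluster_pipeline import (
    ClusterLabels,
    PreprocessSpec,
    cluster_distance_summary,
    compare_clusterings,
    gap_statistic,
    jaccard_stability,
    pairwise_tests,
    preprocess,
    select_k,
    ward_cluster,
)


def blobs(centers, n_per, sd=0.1, seed=0, d=None):
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if d is not None and centers.shape[1] < d:
        centers = np.hstack([centers, np.zeros((len(centers), d - centers.shape[1]))])
    X, y = [], []
    for i, c in enumerate(centers):
        X.append(rng.normal(c, sd, size=(n_per, centers.shape[1])))
        y += [i + 1] * n_per
    return np.vstack(X), np.array(y)


class TestPreprocess:
    def test_asinh_spot_value_and_scaling(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0, 5.0], "b": [1.0, 2.0, 3.0, 4.0]})
        X = preprocess(df, PreprocessSpec(asinh_columns=frozenset(["a"])))
        assert np.arcsinh(1.0) == pytest.approx(0.881374, abs=1e-6)
        assert abs(X.mean(axis=0)).max() < 1e-12
        assert np.allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"dead": [0.0, 0.0, 0.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="dead"):
            preprocess(df, PreprocessSpec())


class TestWard:
    def test_two_separated_clouds_split_perfectly(self):
        X, y = blobs([[0, 0], [10, 10]], 20, seed=1)
        lab = ward_cluster(X, 2)
        assert (lab.labels[:20] == lab.labels[0]).all()
        assert (lab.labels[20:] == lab.labels[20]).all()
        assert lab.labels[0] != lab.labels[20]

    def test_k_equals_n_gives_singletons(self):
        X = np.arange(6, dtype=float).reshape(-1, 1) * 10
        lab = ward_cluster(X, 6)
        assert sorted(lab.labels) == [1, 2, 3, 4, 5, 6]

    def test_merge_heights_match_hand_computed_ward(self):
        """1-D set {0,1,10,11}: pairs merge at height 1; the final merge's
        Ward (D2) height is sqrt(2·ΔSSE) with ΔSSE = 100."""
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        lab = ward_cluster(X, 2)
        assert lab.labels.tolist() == [1, 1, 2, 2]
        heights = sorted(lab.linkage_matrix[:, 2])
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(1.0)
        assert heights[2] == pytest.approx(np.sqrt(200.0))

    def test_ward_d_variant_same_cut_monotone_heights(self):
        X, _ = blobs([[0, 0], [8, 0], [0, 8]], 10, seed=2)
        d2 = ward_cluster(X, 3, method="ward.D2")
        d1 = ward_cluster(X, 3, method="ward.D")
        assert (d1.labels == d2.labels).all()

    def test_invalid_k_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            ward_cluster(X, 0)


class TestGap:
    def test_single_gaussian_selects_one(self):
        hits = 0
        for seed in range(10):
            X = np.random.default_rng(seed).normal(size=(60, 3))
            curve = gap_statistic(X, k_max=6, B=30, seed=seed)
            hits += select_k(curve) == 1
        assert hits >= 9

    def test_three_separated_blobs_select_three(self):
        hits = 0
        for seed in range(10):
            X, _ = blobs([[0, 0], [10, 0], [0, 10]], 20, sd=0.1, seed=seed)
            curve = gap_statistic(X, k_max=8, B=30, seed=seed)
            hits += select_k(curve) == 3
        assert hits >= 9

    def test_feature_permutation_invariance(self):
        X, _ = blobs([[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8]], 15, seed=3)
        c1 = gap_statistic(X, k_max=6, B=30, seed=0)
        c2 = gap_statistic(X[:, [2, 0, 1]], k_max=6, B=30, seed=0)
        assert select_k(c1) == select_k(c2)

    def test_rotation_keeps_selection_on_well_separated_blobs(self):
        """The uniform reference box is axis-aligned, so the gap value is
        not strictly rotation invariant; on clearly separated clusters the
        selected k must nevertheless survive a rigid rotation."""
        from scipy.spatial.transform import Rotation
        X, _ = blobs([[0, 0, 0], [10, 0, 0], [0, 10, 0]], 20, seed=9, d=3)
        R = Rotation.from_euler("xyz", [30, 45, 60], degrees=True).as_matrix()
        k1 = select_k(gap_statistic(X, k_max=7, B=30, seed=0))
        k2 = select_k(gap_statistic(X @ R.T, k_max=7, B=30, seed=0))
        assert k1 == k2 == 3

    def test_bad_arguments_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            gap_statistic(X, k_max=1)
        with pytest.raises(ValueError):
            gap_statistic(X, k_max=3, B=5)


class TestStability:
    def test_distant_blobs_highly_stable(self):
        X, _ = blobs([[0, 0], [10, 10]], 15, seed=4)
        lab = ward_cluster(X, 2)
        rep = jaccard_stability(X, lab, n_boot=60, seed=0)
        assert all(v > 0.95 for v in rep.jaccard.values())

    def test_uniform_cloud_forced_to_5_is_unstable(self):
        X = np.random.default_rng(5).uniform(size=(80, 2))
        lab = ward_cluster(X, 5)
        rep = jaccard_stability(X, lab, n_boot=60, seed=0)
        assert np.mean(list(rep.jaccard.values())) < 0.75

    def test_jaccard_in_unit_interval(self):
        X = np.random.default_rng(6).normal(size=(30, 2))
        rep = jaccard_stability(X, ward_cluster(X, 3), n_boot=20, seed=0)
        assert all(0.0 <= v <= 1.0 for v in rep.jaccard.values())


def _bruteforce_ari(a, b):
    """Pair-counting adjusted Rand index over all n(n-1)/2 pairs."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a, same_b = a[i] == a[j], b[i] == b[j]
            if same_a and same_b:
                ss += 1
            elif same_a:
                sd += 1
            elif same_b:
                ds += 1
            else:
                dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = 0.5 * ((ss + sd) + (ss + ds))
    return (ss - expected) / (maximum - expected)


class TestAgreement:
    def _labels(self, arr, method="ward.D2"):
        return ClusterLabels([str(i) for i in range(len(arr))], np.asarray(arr), method)

    def test_identical_labelings(self):
        a = self._labels([1, 1, 2, 2, 3, 3])
        rep = compare_clusterings(a, a)
        assert rep.ari == pytest.approx(1.0)
        assert (rep.per_class["sensitivity"] == 100.0).all()
        assert (rep.per_class["specificity"] == 100.0).all()

    def test_all_in_one_vs_split_is_zero(self):
        a = self._labels([1] * 8)
        b = self._labels([1, 1, 2, 2, 3, 3, 4, 4])
        assert compare_clusterings(a, b).ari == pytest.approx(0.0, abs=1e-12)

    def test_ari_matches_pair_counting_oracle(self):
        # contingency [[5,1,0],[0,4,1],[1,0,5]]
        a = [1] * 6 + [2] * 5 + [3] * 6
        b = [1] * 5 + [2] + [2] * 4 + [3] + [1] + [3] * 5
        rep = compare_clusterings(self._labels(a), self._labels(b))
        assert rep.ari == pytest.approx(_bruteforce_ari(a, b), abs=1e-12)

    def test_mismatched_cells_rejected(self):
        a = self._labels([1, 2])
        b = ClusterLabels(["x", "y"], np.array([1, 2]))
        with pytest.raises(ValueError):
            compare_clusterings(a, b)


class TestDistanceSummary:
    def test_coincident_points_within_zero_between_d(self):
        X = np.array([[0.0, 0.0]] * 3 + [[3.0, 4.0]] * 3)
        lab = ClusterLabels([str(i) for i in range(6)], np.array([1, 1, 1, 2, 2, 2]))
        tbl = cluster_distance_summary(X, lab)
        assert tbl.loc[1, 1] == pytest.approx(0.0)
        assert tbl.loc[1, 2] == pytest.approx(5.0)

    def test_matches_bruteforce_double_loop_and_symmetry(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        y = rng.integers(1, 4, size=20)
        y[:3] = [1, 2, 3]
        lab = ClusterLabels([str(i) for i in range(20)], y)
        tbl = cluster_distance_summary(X, lab)
        for ci in np.unique(y):
            for cj in np.unique(y):
                vals = [np.linalg.norm(X[i] - X[j])
                        for i in np.flatnonzero(y == ci)
                        for j in np.flatnonzero(y == cj) if i != j]
                if ci == cj:
                    vals = [np.linalg.norm(X[i] - X[j])
                            for i in np.flatnonzero(y == ci)
                            for j in np.flatnonzero(y == cj) if i < j]
                expected = np.mean(vals) if vals else np.nan
                assert tbl.loc[ci, cj] == pytest.approx(expected)
        assert np.allclose(tbl.to_numpy(), tbl.to_numpy().T, equal_nan=True)

    def test_singleton_cluster_within_is_missing(self):
        X = np.array([[0.0], [1.0], [5.0]])
        lab = ClusterLabels(["a", "b", "c"], np.array([1, 1, 2]))
        tbl = cluster_distance_summary(X, lab)
        assert np.isnan(tbl.loc[2, 2])


class TestPairwiseTests:
    def test_bh_closed_form(self):
        from statsmodels.stats.multitest import multipletests
        _, q, *_ = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_shifted_clusters_strongly_significant(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        tbl = pd.DataFrame({"p": x})
        lab = ClusterLabels([str(i) for i in range(20)],
                            np.array([1] * 10 + [2] * 10))
        res = pairwise_tests(tbl, lab)
        assert (res["q_value"] < 0.001).all()

    def test_small_cluster_pairs_skipped(self):
        tbl = pd.DataFrame({"p": [1.0, 2.0, 3.0, 10.0]})
        lab = ClusterLabels(["a", "b", "c", "d"], np.array([1, 1, 1, 2]))
        res = pairwise_tests(tbl, lab)
        assert res["q_value"].isna().all()

    def test_single_cluster_rejected(self):
        tbl = pd.DataFrame({"p": [1.0, 2.0]})
        lab = ClusterLabels(["a", "b"], np.array([1, 1]))
        with pytest.raises(ValueError):
            pairwise_tests(tbl, lab)
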