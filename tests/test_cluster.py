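"""Cluster-number inference: K-means correctness, gap statistic,
silhouette exactness, selection logic, per-cluster metrics."""

import numpy as np
import pytest
from scipy.stats import chi2

from cellpattern import (
    FieldGeometry,
    PointPattern,
    cluster_metrics,
    elbow_select,
    gap_statistic,
    generate_blobs,
    kmeans,
    select_k,
    silhouette,
    within_variation,
)
from cellpattern.synthetic import random_separated_blobs

from _oracles import brute_force_silhouette, brute_force_within


def relabel_match(a, b):
    """True when two labelings induce the same partition."""
    mapping = {}
    for x, y in zip(a, b):
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)


class TestKmeans:
    def test_k1_centroid_is_mean(self, rng):
        pts = rng.normal(50, 10, (40, 2))
        field = FieldGeometry(100, 100, 1.0)
        res = kmeans(np.clip(pts, 0, 100), 1, seed=0)
        np.testing.assert_allclose(res.centroids[0], np.clip(pts, 0, 100).mean(axis=0))
        expected = ((np.clip(pts, 0, 100) - res.centroids[0]) ** 2).sum()
        assert res.totW == pytest.approx(expected)

    def test_k_equals_n_gives_zero_within(self, rng):
        pts = rng.uniform(0, 100, (12, 2))
        res = kmeans(pts, 12, seed=1)
        assert res.totW == pytest.approx(0.0, abs=1e-18)

    def test_k_greater_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="k must satisfy"):
            kmeans(rng.uniform(0, 1, (5, 2)), 6, seed=0)

    def test_recovers_planted_blobs(self, clust_a_pattern):
        res = kmeans(clust_a_pattern, 4, seed=3)
        assert relabel_match(res.labels, clust_a_pattern.labels)

    def test_deterministic_given_seed(self, clust_a_pattern):
        a = kmeans(clust_a_pattern, 4, seed=11)
        b = kmeans(clust_a_pattern, 4, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.totW == b.totW

    def test_totw_consistent_with_parts(self, clust_a_pattern):
        res = kmeans(clust_a_pattern, 5, seed=2)
        assert res.totW == pytest.approx(res.per_cluster_W.sum())
        assert (res.per_cluster_W >= 0).all()


class TestWithinVariation:
    def test_two_point_hand_example(self):
        per, tot = within_variation(
            np.array([[0.0, 0.0], [2.0, 0.0]]), np.array([0, 0]), np.array([[1.0, 0.0]])
        )
        assert tot == pytest.approx(2.0)

    def test_moving_centroids_to_means_never_increases(self, rng):
        pts = rng.uniform(0, 100, (50, 2))
        labels = rng.integers(0, 3, 50)
        bad_centroids = rng.uniform(0, 100, (3, 2))
        _, tot_bad = within_variation(pts, labels, bad_centroids)
        means = np.array([pts[labels == c].mean(axis=0) for c in range(3)])
        _, tot_mean = within_variation(pts, labels, means)
        assert tot_mean <= tot_bad

    def test_matches_brute_force_random_instances(self, rng):
        for _ in range(100):
            pts = rng.uniform(0, 50, (20, 2))
            labels = rng.integers(0, 4, 20)
            centroids = rng.uniform(0, 50, (4, 2))
            per, tot = within_variation(pts, labels, centroids)
            per_o, tot_o = brute_force_within(pts, labels, centroids)
            np.testing.assert_allclose(per, per_o, atol=1e-9)
            assert abs(tot - tot_o) < 1e-9

    def test_out_of_range_label_rejected(self, rng):
        with pytest.raises(ValueError, match="out of range"):
            within_variation(rng.uniform(0, 1, (5, 2)), np.array([0, 0, 1, 2, 3]), np.zeros((2, 2)))


class TestElbow:
    def test_totw_decreasing_and_elbow_at_four(self, clust_a_pattern):
        totw, k_elbow, flagged = elbow_select(clust_a_pattern, kmax=8, seed=4)
        assert not flagged
        assert (np.diff(totw) < 0).all()
        assert k_elbow == 4

    def test_single_blob_flagged_or_low_k(self):
        field = FieldGeometry(1000, 1000, 2.0)
        p = generate_blobs([(500.0, 500.0)], 150, 40.0, field, seed=9)
        totw, k_elbow, flagged = elbow_select(p, kmax=6, seed=5)
        assert flagged  # featureless curvature profile: low confidence

    def test_kmax_validation(self, clust_a_pattern):
        with pytest.raises(ValueError, match="kmax"):
            elbow_select(clust_a_pattern, kmax=2, seed=0)


class TestGapStatistic:
    def test_uniform_data_gap_near_zero(self):
        field = FieldGeometry(1000, 1000, 2.0)
        rng = np.random.default_rng(21)
        pts = rng.uniform(0, 1000, (300, 2))
        rep = gap_statistic(pts, kmax=5, B=20, seed=8)
        assert np.abs(rep.gap).max() < 0.15

    def test_clust_a_selects_four_with_peak(self, clust_a_pattern):
        rep = gap_statistic(clust_a_pattern, kmax=8, B=50, seed=6)
        assert rep.selected_K == 4
        assert rep.k_values[rep.gap.argmax()] == 4

    def test_small_B_same_selection_larger_s(self, clust_a_pattern):
        small = gap_statistic(clust_a_pattern, kmax=6, B=2, seed=13)
        big = gap_statistic(clust_a_pattern, kmax=6, B=50, seed=13)
        assert small.selected_K == big.selected_K == 4
        # sqrt(1+1/B) factor alone makes s larger at B=2 for comparable sd
        assert np.sqrt(1 + 1 / 2) > np.sqrt(1 + 1 / 50)
        assert small.s.shape == big.s.shape

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gap_statistic(np.tile([[5.0, 5.0]], (10, 1)), kmax=3, B=5, seed=0)


class TestSilhouette:
    def test_two_singleton_clusters_coefs_one(self):
        rep = silhouette(np.array([[0.0, 0.0], [10.0, 0.0]]), np.array([0, 1]))
        # singleton convention: y undefined -> coef 0
        np.testing.assert_allclose(rep.coef, [0.0, 0.0])

    def test_perfectly_tight_pair_clusters(self):
        pts = np.array([[0, 0], [0, 0], [10, 0], [10, 0]], dtype=float)
        rep = silhouette(pts, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(rep.coef, 1.0)
        assert rep.mean_width == pytest.approx(1.0)

    def test_edge_cell_coef_zero(self):
        # cell 0 equidistant in mean to its own and the other cluster
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [-2.0, 0.0], [1.0, 5.0]])
        labels = np.array([0, 0, 1, 1])
        rep = silhouette(pts, labels)
        i = 0
        assert rep.coef[i] == pytest.approx((rep.x[i] - rep.y[i]) / max(rep.x[i], rep.y[i]))

    def test_matches_brute_force_random_instances(self, rng):
        for _ in range(100):
            pts = rng.uniform(0, 30, (20, 2))
            labels = rng.integers(0, 3, 20)
            if len(np.unique(labels)) < 2:
                continue
            rep = silhouette(pts, labels)
            np.testing.assert_allclose(rep.coef, brute_force_silhouette(pts, labels), atol=1e-9)

    def test_matches_sklearn(self, clust_a_pattern):
        from sklearn.metrics import silhouette_samples

        labels = clust_a_pattern.labels
        rep = silhouette(clust_a_pattern, labels)
        np.testing.assert_allclose(
            rep.coef, silhouette_samples(clust_a_pattern.points, labels), atol=1e-9
        )

    def test_coefs_bounded(self, rng):
        pts = rng.uniform(0, 100, (60, 2))
        labels = rng.integers(0, 4, 60)
        rep = silhouette(pts, labels)
        assert (rep.coef >= -1 - 1e-12).all() and (rep.coef <= 1 + 1e-12).all()

    def test_planted_labels_beat_random_shuffles(self, clust_a_pattern, rng):
        planted = silhouette(clust_a_pattern, clust_a_pattern.labels).mean_width
        for _ in range(100):
            shuffled = rng.permutation(clust_a_pattern.labels)
            assert silhouette(clust_a_pattern, shuffled).mean_width < planted

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette(rng.uniform(0, 1, (5, 2)), np.zeros(5, dtype=int))

    def test_permutation_invariance(self, clust_a_pattern):
        labels = clust_a_pattern.labels
        perm = (labels + 1) % 4
        a = silhouette(clust_a_pattern, labels)
        b = silhouette(clust_a_pattern, perm)
        np.testing.assert_allclose(sorted(a.per_cluster_mean), sorted(b.per_cluster_mean))
        assert a.mean_width == pytest.approx(b.mean_width)


class TestSelectK:
    def test_clust_a_selects_four_above_threshold(self, clust_a_pattern):
        cl, sil, diag = select_k(clust_a_pattern, kmax=8, seed=14)
        assert cl.k == 4
        assert sil.mean_width >= 0.35
        assert diag["quality"] == "ok"

    def test_silhouette_maximum_agrees_with_gap(self, clust_a_pattern):
        _, _, diag = select_k(clust_a_pattern, kmax=8, seed=15)
        widths = {
            k: silhouette(clust_a_pattern, kmeans(clust_a_pattern, k, seed=100 + k).labels).mean_width
            for k in range(2, 9)
        }
        assert max(widths, key=widths.get) == diag["gap_candidate"] == 4

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            select_k(rng.uniform(0, 1, (3, 2)), kmax=3, seed=0)

    def test_recovery_over_seeded_blob_patterns(self):
        """Planted k in 2..6 with separation >= 10 sd is recovered."""
        field = FieldGeometry(2000, 2000, 2.0)
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            k_true = 2 + seed % 5
            p = random_separated_blobs(k_true, field, sd=60.0, n_per_blob=150, seed=seed)
            _, _, diag = select_k(p, kmax=8, seed=5000 + seed)
            hits += diag["selected_k"] == k_true
        assert hits >= 0.9 * n_runs


class TestClusterMetrics:
    def test_isotropic_cluster_area_closed_form(self):
        """Large isotropic Gaussian cluster: area -> pi * q * s^2."""
        field = FieldGeometry(4000, 4000, 2.0)
        s = 80.0
        p = generate_blobs([(2000.0, 2000.0), (300.0, 300.0)], 4000, s, field, seed=3)
        cl = kmeans(p, 2, seed=0)
        m = cluster_metrics(p, cl, coverage=0.95)
        q = chi2.ppf(0.95, 2)
        expected_mm2 = np.pi * q * s**2 / 1e6
        for c in range(2):
            assert m.ellipse_area[c] == pytest.approx(expected_mm2, rel=0.1)

    def test_scaling_by_two_quarters_density(self, clust_a_pattern):
        cl = kmeans(clust_a_pattern, 4, seed=1)
        m1 = cluster_metrics(clust_a_pattern, cl)
        doubled = clust_a_pattern.points * 2.0
        m2 = cluster_metrics(doubled, cl)
        np.testing.assert_allclose(m2.ellipse_area, m1.ellipse_area * 4.0, rtol=1e-9)
        np.testing.assert_allclose(m2.density, m1.density / 4.0, rtol=1e-9)

    def test_outlier_fraction_near_one_minus_coverage(self):
        field = FieldGeometry(4000, 4000, 2.0)
        p = generate_blobs([(2000.0, 2000.0)], 5000, 60.0, field, seed=8)
        labels = np.zeros(p.n, dtype=int)
        from cellpattern.cluster import ClusteringResult, within_variation as wv

        centroids = p.points.mean(axis=0, keepdims=True)
        per, tot = wv(p.points, labels, centroids)
        cl = ClusteringResult(labels, centroids, per, tot, 1, 1, 0)
        for cov in (0.90, 0.95):
            m = cluster_metrics(p, cl, coverage=cov)
            frac = m.outlier_flags.mean()
            assert abs(frac - (1 - cov)) < 0.02

    def test_tiny_cluster_area_undefined(self):
        pts = np.array([[0, 0], [1, 0], [50, 50], [51, 50], [50, 51], [52, 52]], dtype=float)
        labels = np.array([0, 0, 1, 1, 1, 1])
        from cellpattern.cluster import ClusteringResult

        centroids = np.array([pts[labels == c].mean(axis=0) for c in range(2)])
        cl = ClusteringResult(labels, centroids, np.zeros(2), 0.0, 2, 1, 0)
        with pytest.warns(UserWarning, match="< 3 cells"):
            m = cluster_metrics(pts, cl)
        assert np.isnan(m.ellipse_area[0]) and np.isnan(m.density[0])
        assert np.isfinite(m.ellipse_area[1])
        assert m.n_cells.sum() == 6

    def test_counts_partition_cells(self, clust_a_pattern):
        cl = kmeans(clust_a_pattern, 4, seed=2)
        m = cluster_metrics(clust_a_pattern, cl)
        assert m.n_cells.sum() == clust_a_pattern.n
        np.testing.assert_allclose(m.density, m.n_cells / m.ellipse_area)


class TestModelInterface:
    def test_model_fit_summary(self, clust_a_pattern):
        from cellpattern import CellClusterModel

        res = CellClusterModel(clust_a_pattern).fit(kmax=6, seed=3)
        assert res.selected_k == 4
        assert res.quality == "ok"
        text = res.summary()
        assert "selected K" in text and "mean silhouette" in text
        d = res.to_dict()
        assert d["selected_k"] == 4
        assert sum(c["n_cells"] for c in d["per_cluster"]) == 800

    def test_from_dataframe(self, clust_a_pattern):
        from cellpattern import CellClusterModel

        df = clust_a_pattern.to_dataframe()
        model = CellClusterModel.from_dataframe(df)
        assert model.points.shape == (800, 2)
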