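"""K-means sweep, validity indices, CD selection and templates."""

import numpy as np
import pytest

from ktops.clustering import (ClusteringError, CDCell, ValidationScores,
                              build_templates_and_flag_outliers, cd_index,
                              davies_bouldin_index, dunn_from_matrix,
                              kmeans_fit, kmeans_sweep, pca_projection,
                              silhouette_from_matrix, validation_indices)
from ktops.config import ClusterConfig
from ktops.distances import VALIDATION_METRICS, centroid, pairwise
from ktops.features import FeatureMatrix
from ktops.preprocess import SpikeEvent


def _blobs(rng, centers, n, scale=0.1):
    pts = np.concatenate([c + scale * rng.standard_normal((n, len(c)))
                          for c in centers])
    labels = np.repeat(np.arange(len(centers)), n)
    return pts, labels


# -- O(n^2) brute-force oracles (independent of the implementation) --------

def naive_silhouette(d, labels):
    n = d.shape[0]
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(np.mean([d[i, j] for j in range(n) if labels[j] == lab])
                for lab in set(labels) if lab != labels[i])
        vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals))


def naive_dunn(d, labels):
    labs = sorted(set(labels))
    inter = min(d[i, j] for i in range(len(labels))
                for j in range(len(labels))
                if labels[i] != labels[j])
    intra = max((d[i, j] for i in range(len(labels))
                 for j in range(len(labels))
                 if i != j and labels[i] == labels[j]), default=0.0)
    return inter / intra if intra > 0 else np.inf


def naive_db(x, labels, metric):
    labs = sorted(set(labels))
    cents = [centroid(x[labels == lab], metric) for lab in labs]
    s = [np.mean([pairwise(p[None, :], cents[i][None, :], metric)[0, 0]
                  for p in x[labels == lab]])
         for i, lab in enumerate(labs)]
    out = []
    for i in range(len(labs)):
        worst = max((s[i] + s[j]) / pairwise(cents[i][None, :],
                                             cents[j][None, :], metric)[0, 0]
                    for j in range(len(labs)) if j != i)
        out.append(worst)
    return float(np.mean(out))


class TestKMeans:
    def test_k_range_follows_sqrt_rule(self):
        rng = np.random.default_rng(0)
        x, _ = _blobs(rng, [[0, 0], [10, 10]], 8)   # s = 16 -> K in 2..4
        fm = FeatureMatrix(values=x, weights=np.ones(2))
        cfg = ClusterConfig(validation_subsample=16)
        results = kmeans_sweep(fm, cfg, seed=0)
        ks = sorted({r.k for r in results})
        assert ks == [2, 3, 4]

    @pytest.mark.parametrize("distance", ["sqeuclidean", "cityblock",
                                          "cosine", "correlation"])
    def test_separated_blobs_recovered(self, distance):
        rng = np.random.default_rng(1)
        x, truth = _blobs(rng, [[10, 0, 0], [0, 10, 0], [0, 0, 10]], 40)
        res = kmeans_fit(x, 3, distance, seed=3, replicates=5)
        # nearest-center oracle: zero misassignments up to relabeling
        for lab in range(3):
            assert len(set(res.labels[truth == lab])) == 1
        assert len(set(res.labels)) == 3

    def test_degenerate_inputs_rejected(self):
        fm = FeatureMatrix(values=np.ones((10, 3)), weights=np.ones(3))
        with pytest.raises(ClusteringError):
            kmeans_sweep(fm, ClusterConfig(), seed=0)
        fm2 = FeatureMatrix(values=np.zeros((3, 3)), weights=np.ones(3))
        with pytest.raises(ClusteringError):
            kmeans_sweep(fm2, ClusterConfig(), seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x, _ = _blobs(rng, [[0, 0], [5, 5]], 30)
        a = kmeans_fit(x, 2, "sqeuclidean", seed=9)
        b = kmeans_fit(x, 2, "sqeuclidean", seed=9)
        assert np.array_equal(a.labels, b.labels)


class TestValidityIndices:
    def test_perfect_separation_silhouette(self):
        x = np.array([[0.0, 0], [0, 0], [10, 10], [10, 10]])
        labels = np.array([0, 0, 1, 1])
        s = validation_indices(x, labels, "euclidean")
        assert s.silhouette == pytest.approx(1.0)
        assert s.davies_bouldin == pytest.approx(0.0)

    def test_dunn_closed_form(self):
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        d = pairwise(x, x, "euclidean")
        assert dunn_from_matrix(d, labels) == pytest.approx(9.0)

    def test_random_labels_silhouette_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((500, 4))
        labels = rng.integers(0, 3, size=500)
        s = validation_indices(x, labels, "euclidean")
        assert abs(s.silhouette) < 0.1

    @pytest.mark.parametrize("metric", VALIDATION_METRICS)
    def test_matches_brute_force(self, metric):
        rng = np.random.default_rng(4)
        x, labels = _blobs(rng, [[2, 0, 1], [-1, 2, 0], [0, -2, -1]], 20,
                           scale=0.8)
        d = pairwise(x, x, metric)
        assert silhouette_from_matrix(d, labels) == pytest.approx(
            naive_silhouette(d, labels), rel=1e-9)
        assert dunn_from_matrix(d, labels) == pytest.approx(
            naive_dunn(d, labels), rel=1e-9)
        assert davies_bouldin_index(x, labels, metric) == pytest.approx(
            naive_db(x, labels, metric), rel=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x, labels = _blobs(rng, [[3, 0], [-3, 0]], 25)
        perm = rng.permutation(x.shape[0])
        for metric in ("euclidean", "cityblock"):
            a = validation_indices(x, labels, metric)
            b = validation_indices(x[perm], labels[perm], metric)
            assert a.silhouette == pytest.approx(b.silhouette)
            assert a.davies_bouldin == pytest.approx(b.davies_bouldin)
            assert a.dunn == pytest.approx(b.dunn)


def _cell(k, s, db, d, dist="sqeuclidean", metric="euclidean"):
    return CDCell(distance=dist, metric=metric, k=k,
                  scores=ValidationScores(s, db, d))


class TestCDIndex:
    def test_hand_normalized_three_cells(self):
        cells = [_cell(2, 0.2, 1.5, 0.1), _cell(3, 0.5, 1.0, 0.5),
                 _cell(4, 0.8, 0.5, 0.9)]
        scored, best = cd_index(cells)
        assert [c.cd for c in scored] == pytest.approx([0.0, 0.5, 1.0])
        assert best.k == 4

    def test_joint_extreme_cell_reaches_one(self):
        cells = [_cell(2, 0.9, 0.2, 1.2), _cell(3, 0.1, 1.0, 0.3),
                 _cell(4, 0.4, 0.6, 0.6)]
        scored, best = cd_index(cells)
        assert best.cd == pytest.approx(1.0)
        assert best.k == 2
        assert all(0.0 <= c.cd <= 1.0 for c in scored)

    def test_constant_index_gets_half(self):
        cells = [_cell(2, 0.5, 1.0, 0.1), _cell(3, 0.5, 0.8, 0.4)]
        with pytest.warns(UserWarning):
            scored, _ = cd_index(cells)
        assert all(c.p_s == pytest.approx(0.5) for c in scored)

    def test_tie_broken_by_smaller_k(self):
        cells = [_cell(3, 0.5, 1.0, 0.5), _cell(2, 0.5, 1.0, 0.5)]
        with pytest.warns(UserWarning):
            _, best = cd_index(cells)
        assert best.k == 2


class TestTemplates:
    def _events(self, n, amp=1.0):
        out = []
        for _ in range(n):
            fd = amp * np.concatenate([np.zeros(5), [-1, -2, -1], np.zeros(5)])
            out.append(SpikeEvent(peak_index=6, window_fd=fd,
                                  window_sd=np.gradient(fd), pre_samples=6,
                                  post_samples=6, thr_at_detection=0.5))
        return out

    def test_singleton_cluster_flagged_outlier(self):
        events = self._events(43)
        labels = np.zeros(43, dtype=int)
        labels[-1] = 1
        from ktops.clustering import ClusteringResult
        res = ClusteringResult(labels=labels, k=2, distance="sqeuclidean",
                               centroids=np.zeros((2, 1)), inertia=0.0,
                               replicate_seed=0)
        tl = build_templates_and_flag_outliers(events, res, thr=0.5)
        assert [t.is_outlier for t in tl] == [False, True]

    def test_healthy_clusters_not_flagged(self):
        events = self._events(40)
        labels = np.repeat([0, 1], 20)
        from ktops.clustering import ClusteringResult
        res = ClusteringResult(labels=labels, k=2, distance="sqeuclidean",
                               centroids=np.zeros((2, 1)), inertia=0.0,
                               replicate_seed=0)
        tl = build_templates_and_flag_outliers(events, res, thr=0.5)
        assert not any(t.is_outlier for t in tl)

    def test_template_of_identical_events_is_the_event(self):
        events = self._events(10)
        from ktops.clustering import ClusteringResult
        res = ClusteringResult(labels=np.zeros(10, dtype=int), k=1,
                               distance="sqeuclidean",
                               centroids=np.zeros((1, 1)), inertia=0.0,
                               replicate_seed=0)
        tl = build_templates_and_flag_outliers(events, res, thr=0.5)
        assert np.allclose(tl[0].template_fd, events[0].window_fd)


class TestPCA:
    def test_rank_one_explains_everything(self):
        rng = np.random.default_rng(6)
        u = rng.standard_normal(30)
        x = np.outer(u, [1.0, 2.0, 3.0])
        fm = FeatureMatrix(values=x, weights=np.ones(3))
        scores = pca_projection(fm, 2)
        assert np.allclose(scores[:, 1], 0, atol=1e-9)

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((50, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        for data in (x, x @ q):
            c = data - data.mean(axis=0)
            s = np.linalg.svd(c, compute_uv=False)
            if data is x:
                ref = s
        assert np.allclose(np.linalg.svd(x @ q - (x @ q).mean(0),
                                         compute_uv=False), ref)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((50, 24))
        fm = FeatureMatrix(values=x, weights=np.ones(24))
        scores = pca_projection(fm, 3)
        c = x - x.mean(axis=0)
        w, v = np.linalg.eigh(np.cov(c, rowvar=False))
        ref = c @ v[:, ::-1][:, :3]
        for j in range(3):  # eigenvector sign is arbitrary
            assert (np.allclose(scores[:, j], ref[:, j], atol=1e-8)
                    or np.allclose(scores[:, j], -ref[:, j], atol=1e-8))
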