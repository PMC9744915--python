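"""Clustering, cycle-consistent matching and consensus scoring, checked
against brute-force enumeration on small constructed configurations."""

import itertools

import numpy as np
import pytest

from lesiontrace.embedding_net import EmbeddingBatch
from lesiontrace.cluster_match import (
    ClusterAssignment,
    UNASSIGNED,
    assign_pseudo_labels,
    cosine_similarity,
    cycle_consistent_match,
    domain_consensus_score,
    optimize_target_k,
    source_class_assignment,
    spherical_kmeans,
    _score_match,
)


def _norm(x):
    x = np.asarray(x, dtype=np.float64)
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def _assignment(centers, labels):
    centers = _norm(centers)
    return ClusterAssignment(
        labels=np.asarray(labels), centers=centers, k=len(centers), objective=0.0
    )


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, 2.0, -3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_units_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_evaluation(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        expected = float(np.dot(a, b) / (np.sqrt(np.dot(a, a)) * np.sqrt(np.dot(b, b))))
        assert cosine_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


def _two_cloud_data(rng, n_per=10, dim=4):
    a = _norm(np.array([1.0, 0, 0, 0]) + 0.05 * rng.normal(size=(n_per, dim)))
    b = _norm(np.array([-1.0, 0.2, 0, 0]) + 0.05 * rng.normal(size=(n_per, dim)))
    return np.vstack([a, b])


def _pairwise_objective(x, labels, k):
    total = 0.0
    for c in range(k):
        pts = x[np.asarray(labels) == c]
        if len(pts):
            total += ((pts[:, None] - pts[None]) ** 2).sum() / len(pts)
    return total


class TestSphericalKmeans:
    def test_k_equals_n_gives_zero_objective(self, rng):
        x = _norm(rng.normal(size=(6, 3)))
        out = spherical_kmeans(EmbeddingBatch(x, l2_normalized=True), k=6, seed=0)
        assert out.objective == pytest.approx(0.0, abs=1e-12)
        assert len(set(out.labels.tolist())) == 6

    def test_k_one_center_is_normalized_mean_direction(self, rng):
        x = _norm(np.abs(rng.normal(size=(8, 3))))
        out = spherical_kmeans(EmbeddingBatch(x, l2_normalized=True), k=1, seed=0)
        np.testing.assert_allclose(out.centers[0], _norm(x.mean(0)), atol=1e-12)

    def test_k_exceeding_n_rejected(self, rng):
        x = _norm(rng.normal(size=(3, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            spherical_kmeans(EmbeddingBatch(x, l2_normalized=True), k=4)

    def test_lloyd_objective_history_non_increasing(self, rng):
        x = _norm(rng.normal(size=(60, 5)))
        out = spherical_kmeans(EmbeddingBatch(x, l2_normalized=True), k=4, seed=1)
        hist = np.array(out.objective_history)
        assert np.all(np.diff(hist) <= 1e-10)

    def test_deterministic_given_seed(self, rng):
        x = _norm(rng.normal(size=(30, 4)))
        a = spherical_kmeans(EmbeddingBatch(x, l2_normalized=True), k=3, seed=5)
        b = spherical_kmeans(EmbeddingBatch(x, l2_normalized=True), k=3, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_partition_matches_exhaustive_minimum_small_n(self, rng):
        """On 6 points from two separated clouds, k=2 recovers the partition
        minimizing the within-cluster pairwise squared deviation."""
        x = _two_cloud_data(rng, n_per=3)
        out = spherical_kmeans(EmbeddingBatch(x, l2_normalized=True), k=2, seed=0)
        best_obj, best_partition = np.inf, None
        for assignment in itertools.product([0, 1], repeat=6):
            if len(set(assignment)) < 2:
                continue
            obj = _pairwise_objective(x, assignment, 2)
            if obj < best_obj:
                best_obj, best_partition = obj, assignment
        assert out.objective == pytest.approx(best_obj, rel=1e-10)
        got = np.asarray(out.labels)
        want = np.asarray(best_partition)
        assert np.array_equal(got, want) or np.array_equal(got, 1 - want)

    def test_two_separated_clouds_recovered(self, rng):
        x = _two_cloud_data(rng, n_per=10)
        out = spherical_kmeans(EmbeddingBatch(x, l2_normalized=True), k=2, seed=0)
        assert len(set(out.labels[:10].tolist())) == 1
        assert len(set(out.labels[10:].tolist())) == 1
        assert out.labels[0] != out.labels[10]


class TestCycleConsistentMatch:
    def test_identical_centers_identity_pairing(self):
        c = _norm(np.eye(3))
        pairs = cycle_consistent_match(
            _assignment(c, [0, 1, 2]), _assignment(c, [0, 1, 2])
        )
        assert pairs == [(0, 0), (1, 1), (2, 2)]

    def test_near_axis_centers_pair_by_brute_force(self):
        src = _norm([[1.0, 0.0], [0.0, 1.0]])
        tgt = _norm([[0.99, 0.1], [0.1, 0.99]])
        pairs = cycle_consistent_match(
            _assignment(src, [0, 1]), _assignment(tgt, [0, 1])
        )
        sims = src @ tgt.T
        expected = [
            (c, int(np.argmax(sims[c])))
            for c in range(2)
            if int(np.argmax(sims[:, np.argmax(sims[c])])) == c
        ]
        assert pairs == expected == [(0, 0), (1, 1)]

    def test_non_mutual_target_left_unmatched(self):
        src = _norm([[1.0, 0.0], [0.0, 1.0]])
        # target 2 is near source 0 but source 0 is nearer target 0
        tgt = _norm([[0.999, 0.01], [0.01, 0.999], [0.9, 0.3]])
        pairs = cycle_consistent_match(
            _assignment(src, [0, 1]), _assignment(tgt, [0, 1, 2])
        )
        assert (0, 0) in pairs and (1, 1) in pairs
        assert all(k != 2 for _, k in pairs)

    def test_symmetric_under_domain_swap(self, rng):
        a = _assignment(rng.normal(size=(3, 4)), [0, 1, 2])
        b = _assignment(rng.normal(size=(4, 4)), [0, 1, 2, 3])
        fwd = set(cycle_consistent_match(a, b))
        rev = set((c, k) for k, c in cycle_consistent_match(b, a))
        assert fwd == rev


class TestConsensusScore:
    def test_perfect_consensus(self):
        src_c = _norm(np.eye(2))
        tgt_c = _norm(np.eye(2))
        s, t, m = domain_consensus_score(
            (0, 0), src_c[[0, 0]], tgt_c[[0, 0, 0]], src_c, tgt_c
        )
        assert (s, t, m) == (1.0, 1.0, 1.0)

    def test_hand_counted_indicator_fraction(self):
        """4 source samples, one nearest to the wrong target center -> 0.75."""
        tgt_c = _norm([[1.0, 0.0], [0.0, 1.0]])
        src_c = tgt_c.copy()
        src_samples = _norm([[1, 0.1], [1, -0.1], [0.9, 0.2], [0.1, 1.0]])
        tgt_samples = _norm([[1, 0.0]])
        s, t, m = domain_consensus_score((0, 0), src_samples, tgt_samples, src_c, tgt_c)
        assert s == pytest.approx(0.75)
        assert t == pytest.approx(1.0)
        assert m == pytest.approx((0.75 + 1.0) / 2)

    def test_mean_of_views_exact(self, rng):
        src_c = _norm(rng.normal(size=(3, 5)))
        tgt_c = _norm(rng.normal(size=(3, 5)))
        s, t, m = domain_consensus_score(
            (0, 0), rng.normal(size=(6, 5)), rng.normal(size=(4, 5)), src_c, tgt_c
        )
        assert 0.0 <= s <= 1.0 and 0.0 <= t <= 1.0
        assert m == (s + t) / 2

    def test_empty_cluster_rejected(self):
        c = _norm(np.eye(2))
        with pytest.raises(ValueError, match="empty"):
            domain_consensus_score((0, 0), np.zeros((0, 2)), c[[0]], c, c)


class TestOptimizeTargetK:
    def _label_embeddings(self, labels, n_classes, noise, rng):
        # one-hot-ish embeddings: class structure is explicit
        x = np.eye(n_classes)[labels] + noise * rng.normal(size=(len(labels), n_classes))
        return EmbeddingBatch(_norm(x + 1e-9), l2_normalized=True)

    def test_recovers_true_common_class_count(self, rng):
        src_labels = np.repeat(np.arange(4), 12)
        tgt_labels = np.repeat(np.arange(3), 12)  # 3 common classes
        src_emb = self._label_embeddings(src_labels, 4, 0.05, rng)
        tgt_emb = self._label_embeddings(tgt_labels, 4, 0.05, rng)
        src = source_class_assignment(src_emb, src_labels, 4)
        best_k, tgt, match = optimize_target_k(src, src_emb, tgt_emb, list(range(2, 7)), seed=0)
        assert best_k == 3
        assert len(match.pairs) == 3

    def test_single_k_grid_returned(self, rng):
        src_labels = np.repeat(np.arange(3), 8)
        emb = self._label_embeddings(src_labels, 3, 0.02, rng)
        src = source_class_assignment(emb, src_labels, 3)
        k, _, _ = optimize_target_k(src, emb, emb, [3], seed=0)
        assert k == 3

    def test_tie_prefers_smaller_k(self, rng):
        """Two k values with perfect consensus: the smaller k must win."""
        src_labels = np.repeat(np.arange(2), 10)
        src_emb = self._label_embeddings(src_labels, 2, 0.0, rng)
        src = source_class_assignment(src_emb, src_labels, 2)
        tgt_emb = self._label_embeddings(np.repeat(np.arange(2), 10), 2, 0.0, rng)
        # k=2 gives consensus 1.0; larger k splits ties but cannot beat 1.0
        k, _, _ = optimize_target_k(src, src_emb, tgt_emb, [2, 4], seed=0)
        assert k == 2

    def test_identity_pairing_on_one_hot_class_means(self):
        """Zero-shift one-hot class-mean embeddings match identically."""
        n_classes = 4
        labels = np.repeat(np.arange(n_classes), 5)
        emb = EmbeddingBatch(np.eye(n_classes)[labels], l2_normalized=True)
        src = source_class_assignment(emb, labels, n_classes)
        match = _score_match(src, src, emb.vectors, emb.vectors)
        assert {(p.source_cluster, p.target_cluster) for p in match.pairs} == {
            (i, i) for i in range(n_classes)
        }
        assert all(p.consensus_score == 1.0 for p in match.pairs)


class TestPseudoLabels:
    def _setup(self, rng, n_tgt_clusters=3, unmatched=()):
        labels = np.repeat(np.arange(n_tgt_clusters), 7)
        emb = EmbeddingBatch(_norm(np.eye(n_tgt_clusters)[labels] + 0.01), l2_normalized=True)
        src_labels = labels.copy()
        src = source_class_assignment(emb, src_labels, n_tgt_clusters)
        tgt = spherical_kmeans(emb, n_tgt_clusters, seed=0)
        match = _score_match(src, tgt, emb.vectors, emb.vectors)
        return match, tgt

    def test_all_matched_zero_unassigned(self, rng):
        match, tgt = self._setup(rng)
        out = assign_pseudo_labels(match, tgt, {i: f"class_{i}" for i in range(3)})
        assert out.n_unassigned == 0
        assert set(out.labels) <= {"class_0", "class_1", "class_2"}

    def test_unmatched_cluster_cells_all_unassigned(self):
        centers = _norm([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        tgt = ClusterAssignment(
            labels=np.array([0] * 5 + [1] * 5 + [2] * 7),
            centers=centers, k=3, objective=0.0,
        )
        src = ClusterAssignment(
            labels=np.array([0] * 5 + [1] * 5),
            centers=centers[:2], k=2, objective=0.0,
        )
        emb = centers[tgt.labels]
        src_emb = centers[src.labels]
        match = _score_match(src, tgt, src_emb, emb)
        out = assign_pseudo_labels(match, tgt, {0: "A", 1: "B"})
        assert out.n_unassigned == 7
        assert all(l == UNASSIGNED for l in np.asarray(out.labels)[tgt.labels == 2])

    def test_perfect_matching_recovers_ground_truth(self, rng):
        match, tgt = self._setup(rng)
        out = assign_pseudo_labels(match, tgt, {i: f"class_{i}" for i in range(3)})
        truth = np.repeat([f"class_{i}" for i in range(3)], 7)
        # clusters may be permuted; accuracy must still be perfect because
        # matching follows the class-aligned centers
        assert np.mean(np.asarray(out.labels) == truth) == 1.0
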