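"""Verification-protocol oracles: cosine/Euclidean equivalence, pair
sampling, ROC against the Mann-Whitney statistic, fold-thresholded accuracy,
Top-k, distance summaries and the 2-D projection."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from floramet import (
    EmbeddingBatch,
    cosine_similarity,
    cross_validate_verification,
    distance_stats,
    make_verification_pairs,
    project_2d,
    roc_auc,
    topk_accuracy,
    verify_pairs,
)
from floramet.data import DatasetManifest, ImageRecord


def fake_manifest(per_class_counts):
    records = []
    for lab, n in enumerate(per_class_counts):
        for i in range(n):
            records.append(ImageRecord(f"/x/{lab}/{i}.png", lab, f"c{lab}i{i}"))
    return DatasetManifest(records, n_classes=len(per_class_counts))


class TestCosineSimilarity:
    def test_trivial_values(self):
        v = np.array([1.0, 0.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity(v, np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_hand_case_and_distance_identity(self):
        g, p = np.array([1.0, 0.0]), np.array([0.6, 0.8])
        s = cosine_similarity(g, p)
        assert s == pytest.approx(0.6)
        assert np.sum((g - p) ** 2) == pytest.approx(2 - 2 * s)

    def test_identity_holds_generally(self, rng):
        F = rng.normal(size=(30, 8))
        F /= np.linalg.norm(F, axis=1, keepdims=True)
        for i, j in itertools.combinations(range(10), 2):
            s = cosine_similarity(F[i], F[j])
            assert np.sum((F[i] - F[j]) ** 2) == pytest.approx(2 - 2 * s, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestMakeVerificationPairs:
    def test_totals(self):
        m = fake_manifest([200] * 26)
        pairs = make_verification_pairs(m, 2600, 2600, seed=0)
        assert len(pairs) == 5200
        assert sum(p.same_class for p in pairs) == 2600
        labels = m.labels
        seen = set()
        for p in pairs:
            key = (min(p.gallery_index, p.probe_index),
                   max(p.gallery_index, p.probe_index))
            assert key not in seen, "duplicate unordered pair"
            seen.add(key)
            assert p.same_class == (labels[p.gallery_index] == labels[p.probe_index])

    def test_empty_request(self):
        assert make_verification_pairs(fake_manifest([3, 3]), 0, 0, 1) == []

    def test_exhaustive_tiny_case(self):
        m = fake_manifest([2, 2])
        pairs = make_verification_pairs(m, 2, 4, seed=3)
        pos = {(p.gallery_index, p.probe_index) for p in pairs if p.same_class}
        neg = {(p.gallery_index, p.probe_index) for p in pairs if not p.same_class}
        assert pos == {(0, 1), (2, 3)}
        assert neg == {(0, 2), (0, 3), (1, 2), (1, 3)}

    def test_over_request_raises(self):
        m = fake_manifest([2, 2])
        with pytest.raises(ValueError):
            make_verification_pairs(m, 3, 0, 0)
        with pytest.raises(ValueError):
            make_verification_pairs(m, 0, 5, 0)

    def test_deterministic(self):
        m = fake_manifest([10, 10, 10])
        assert make_verification_pairs(m, 20, 20, 7) == make_verification_pairs(
            m, 20, 20, 7
        )


class TestVerifyPairs:
    @pytest.fixture()
    def separated(self, rng):
        """Two tight clusters: within-class s > 0.9, cross-class s < 0."""
        a = np.array([1.0, 0.0])
        b = np.array([-1.0, 0.0])
        F = np.vstack([
            [a + rng.normal(0, 0.01, 2) for _ in range(5)],
            [b + rng.normal(0, 0.01, 2) for _ in range(5)],
        ])
        F /= np.linalg.norm(F, axis=1, keepdims=True)
        emb = EmbeddingBatch(F, np.repeat([0, 1], 5))
        m = fake_manifest([5, 5])
        pairs = make_verification_pairs(m, 10, 10, 2)
        return emb, pairs

    def test_degenerate_thresholds(self, separated):
        emb, pairs = separated
        dec_all, _ = verify_pairs(emb, pairs, -1.0)
        assert dec_all.all()
        dec_none, _ = verify_pairs(emb, pairs, 1.0)  # strict inequality
        assert not dec_none.any()

    def test_zero_threshold_recovers_flags(self, separated):
        emb, pairs = separated
        dec, scores = verify_pairs(emb, pairs, 0.0)
        flags = np.array([p.same_class for p in pairs])
        assert np.array_equal(dec, flags)
        assert scores[flags].min() > 0.9
        assert scores[~flags].max() < 0.0

    def test_out_of_range_index(self, separated):
        emb, pairs = separated
        small = EmbeddingBatch(emb.features[:3], emb.labels[:3])
        with pytest.raises(IndexError):
            verify_pairs(small, pairs, 0.0)


def mann_whitney_auc(scores, labels):
    """Brute-force normalized U statistic with the tie convention."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_null_scores_near_half(self, rng):
        n = 4000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        r = roc_auc(scores, labels)
        assert abs(r.auc - 0.5) < 3 / np.sqrt(n)

    def test_constant_scores_half_by_tie_convention(self):
        r = roc_auc(np.ones(10), np.repeat([0, 1], 5))
        assert r.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_mann_whitney(self, seed):
        r = np.random.default_rng(seed)
        scores = np.round(r.normal(size=40), 1)  # coarse grid forces ties
        labels = r.integers(0, 2, size=40)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        got = roc_auc(scores, labels).auc
        assert got == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4))


class TestCrossValidate:
    def test_separable_scores_all_folds_perfect(self):
        for seed in (0, 1, 99):
            scores = np.concatenate([np.full(50, 0.9), np.full(50, 0.1)])
            labels = np.repeat([1, 0], 50)
            rep = cross_validate_verification(scores, labels, 10, seed)
            assert np.all(rep.accuracies == 1.0)
            assert rep.mean_accuracy == 1.0

    def test_constant_scores_balanced_is_half(self):
        rep = cross_validate_verification(
            np.ones(100), np.repeat([0, 1], 50), 10, seed=4
        )
        assert np.allclose(rep.accuracies, 0.5)

    def test_planted_flip_rate_recovered(self, rng):
        """Threshold-separable scores with 5% flipped labels: mean accuracy
        ~0.95, matching an exhaustive threshold search on the full set."""
        n = 1000
        labels = np.repeat([1, 0], n // 2)
        scores = np.where(labels == 1, 0.8, 0.2) + rng.normal(0, 0.05, n)
        flip = rng.choice(n, size=n // 20, replace=False)
        labels = labels.copy()
        labels[flip] = 1 - labels[flip]
        rep = cross_validate_verification(scores, labels, 10, seed=0)
        assert rep.mean_accuracy == pytest.approx(0.95, abs=0.02)
        # exhaustive oracle over all thresholds on the pooled data
        best = max(
            ((scores > t) == labels.astype(bool)).mean()
            for t in np.concatenate(([-1e9, 1e9], scores))
        )
        assert rep.mean_accuracy <= best + 0.01

    def test_fold_count_bounds(self):
        with pytest.raises(ValueError):
            cross_validate_verification(np.ones(5), np.array([0, 1, 0, 1, 0]), 10, 0)


class TestTopkAccuracy:
    def test_full_coverage_and_perfect(self, rng):
        logits = rng.normal(size=(20, 6))
        labels = rng.integers(0, 6, size=20)
        assert topk_accuracy(logits, labels, 6) == 1.0
        onehot = np.eye(6)[labels]
        assert topk_accuracy(onehot, labels, 1) == 1.0

    def test_constructed_top2(self):
        logits = np.array([
            [0.9, 0.5, 0.1],   # true 1 -> in top-2
            [0.1, 0.2, 0.9],   # true 0 -> not in top-2
            [0.5, 0.4, 0.6],   # true 0 -> in top-2
        ])
        labels = np.array([1, 0, 0])
        assert topk_accuracy(logits, labels, 2) == pytest.approx(2 / 3)

    def test_tie_break_lowest_class_index(self):
        logits = np.zeros((1, 4))
        assert topk_accuracy(logits, np.array([0]), 1) == 1.0
        assert topk_accuracy(logits, np.array([3]), 1) == 0.0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            topk_accuracy(np.zeros((2, 3)), np.zeros(2, dtype=int), 0)
        with pytest.raises(ValueError):
            topk_accuracy(np.zeros((2, 3)), np.zeros(2, dtype=int), 4)


class TestDistanceStats:
    def test_identical_embeddings_all_zero(self):
        emb = EmbeddingBatch(np.ones((6, 3)), np.repeat([0, 1], 3))
        s = distance_stats(emb)
        assert np.all(s.intra == 0) and np.all(s.inter == 0)

    def test_two_point_configuration(self):
        F = np.array([[0.0, 0.0]] * 3 + [[1.0, 0.0]] * 3)
        s = distance_stats(EmbeddingBatch(F, np.repeat([0, 1], 3)))
        assert s.intra[4] == 0.0  # max intra
        assert s.inter_median == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        F = rng.normal(size=(15, 4))
        y = rng.integers(0, 3, size=15)
        s = distance_stats(EmbeddingBatch(F, y))
        intra, inter = [], []
        for i in range(15):
            for j in range(i + 1, 15):
                d = float(np.linalg.norm(F[i] - F[j]))
                (intra if y[i] == y[j] else inter).append(d)
        q = [0, 25, 50, 75, 100]
        assert np.allclose(s.intra, np.percentile(intra, q))
        assert np.allclose(s.inter, np.percentile(inter, q))
        assert np.all(np.diff(s.intra) >= 0) and np.all(np.diff(s.inter) >= 0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            distance_stats(EmbeddingBatch(np.ones((1, 2)), np.array([0])))
        with pytest.raises(ValueError):
            distance_stats(EmbeddingBatch(np.ones((3, 2)), np.zeros(3, dtype=int)))
        with pytest.raises(ValueError):  # all singleton classes
            distance_stats(EmbeddingBatch(np.ones((3, 2)), np.arange(3)))


@pytest.fixture(scope="module")
def clusters():
    r = np.random.default_rng(0)
    F = np.vstack([
        r.normal(0, 0.05, size=(30, 8)),
        r.normal(5, 0.05, size=(30, 8)),
    ])
    return EmbeddingBatch(F, np.repeat([0, 1], 30))


class TestProject2d:

    def test_shape_and_determinism(self, clusters):
        a = project_2d(clusters, seed=3)
        b = project_2d(clusters, seed=3)
        assert a.shape == (60, 2)
        assert np.array_equal(a, b)

    def test_separated_clusters_high_silhouette(self, clusters, tmp_path):
        pts = project_2d(clusters, seed=1, out_path=tmp_path / "scatter.png")
        assert silhouette_score(pts, clusters.labels) > 0.8
        assert (tmp_path / "scatter.png").exists()

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            project_2d(EmbeddingBatch(np.ones((3, 4)), np.arange(3)), seed=0)


def test_pdist_path_equals_pairwise_cosine_identity(rng):
    """Unit rows: squared pdist equals 2 - 2s for every pair, to 1e-9."""
    F = rng.normal(size=(12, 6))
    F /= np.linalg.norm(F, axis=1, keepdims=True)
    d2 = pdist(F) ** 2
    k = 0
    for i in range(12):
        for j in range(i + 1, 12):
            s = cosine_similarity(F[i], F[j])
            assert d2[k] == pytest.approx(2 - 2 * s, abs=1e-9)
            k += 1
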