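"""SMOTE interpolation, ENN editing (vs brute-force neighbor tables),
and the composed SMOTEENN contracts."""

import numpy as np
import pytest

from admixer.resampling import (
    enn_filter,
    knn_indices,
    smote_oversample,
    smoteenn_resample,
)


def brute_force_knn(X, query, k, exclude_self=False):
    d = [float(np.linalg.norm(row - query)) for row in X]
    order = sorted(range(len(X)), key=lambda i: (d[i], i))
    if exclude_self:
        for i in order:
            if d[i] == 0.0:
                order.remove(i)  # drop only the first zero-distance hit
                break
    return order[:k]


class TestKnn:
    def test_nearest_by_inspection(self):
        X = np.array([[0.0], [1.0], [10.0]])
        assert knn_indices(X, np.array([0.4]), 1).tolist() == [0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            X = rng.random((20, 2))
            q = rng.random(2)
            assert knn_indices(X, q, 3).tolist() == brute_force_knn(X, q, 3)

    def test_exclude_self_drops_identical_point(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        out = knn_indices(X, X[0], 2, exclude_self=True)
        assert 0 not in out.tolist()

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError, match="k="):
            knn_indices(np.zeros((3, 1)), np.zeros(1), 3)


class TestSmote:
    def test_class_at_target_untouched(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        y = np.array([0, 0, 0, 1, 1, 1])
        X2, y2, created, prov = smote_oversample(X, y, [3, 3], seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)
        assert created == {} and prov == []

    def test_two_point_class_interpolates_on_segment(self):
        a, b = np.array([0.0, 0.0]), np.array([2.0, 4.0])
        X = np.vstack([a, b, [10.0, 10.0], [11.0, 11.0], [12.0, 12.0]])
        y = np.array([0, 0, 1, 1, 1])
        X2, y2, created, prov = smote_oversample(X, y, [5, 3], k_smote=5, seed=1)
        lo, hi = created[0]
        for row in X2[lo:hi]:
            # row = a + u (b - a): collinear and inside the segment
            u = row[0] / 2.0
            assert 0.0 <= u <= 1.0
            assert row[1] == pytest.approx(4.0 * u)

    def test_synthetic_rows_inside_parent_bounding_box(self):
        rng = np.random.default_rng(9)
        X = rng.random((30, 4))
        y = np.array([0] * 10 + [1] * 20)
        X2, _, created, prov = smote_oversample(X, y, [20, 20], seed=3)
        lo, _ = created[0]
        for j, p in enumerate(prov):
            row = X2[lo + j]
            pa, pb = X[p.base_index], X[p.neighbor_index]
            assert np.all(row >= np.minimum(pa, pb) - 1e-12)
            assert np.all(row <= np.maximum(pa, pb) + 1e-12)

    def test_originals_preserved_verbatim(self):
        rng = np.random.default_rng(2)
        X = rng.random((15, 3))
        y = np.array([0] * 5 + [1] * 10)
        X2, _, _, _ = smote_oversample(X, y, [10, 10], seed=0)
        assert np.array_equal(X2[:15], X)

    def test_singleton_class_growth_rejected(self):
        X = np.array([[0.0], [5.0], [6.0]])
        y = np.array([0, 1, 1])
        with pytest.raises(ValueError, match="interpolate"):
            smote_oversample(X, y, [3, 2], seed=0)


def brute_force_enn_keep(X, y, k=3):
    """Keep iff the sample's label matches at least k/2 of its k nearest
    neighbors (self excluded, stable tie-break by index)."""
    keep = []
    for i in range(len(X)):
        d = [(float(np.linalg.norm(X[j] - X[i])), j) for j in range(len(X)) if j != i]
        nn = [j for _, j in sorted(d, key=lambda t: (t[0], t[1]))[:k]]
        same = sum(y[j] == y[i] for j in nn)
        keep.append(same >= k / 2.0)
    return np.array(keep)


class TestEnn:
    def test_single_class_keeps_everything(self):
        X = np.random.default_rng(0).random((10, 2))
        y = np.zeros(10, dtype=int)
        assert enn_filter(X, y, 3).all()

    def test_outlier_near_other_class_removed(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0], [13.0]])
        y = np.array([0, 0, 0, 0, 1, 1, 1])
        keep = enn_filter(X, y, 3)
        assert keep.tolist() == [True, True, True, False, True, True, True]

    def test_interleaved_lattice_fully_removed(self):
        yy, xx = np.mgrid[0:6, 0:6]
        X = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        y = ((yy + xx) % 2).ravel()
        keep = enn_filter(X, y, 3)
        assert not keep.any()

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            X = rng.random((20, 2))
            y = rng.integers(0, 3, 20)
            assert np.array_equal(enn_filter(X, y, 3), brute_force_enn_keep(X, y, 3))

    def test_even_k_tie_keeps(self):
        # 2+2 neighbor split at k=4: the sample stays
        X = np.array([[0.0], [0.1], [0.2], [-0.1], [-0.2], [5.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        keep = enn_filter(X, y, 4)
        assert keep[0]

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="k_enn"):
            enn_filter(np.zeros((3, 1)), np.zeros(3, dtype=int), 3)


def make_blobs(counts, seed=0, spread=0.05):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [5, 0], [0, 5], [5, 5], [2.5, 8]], dtype=float)
    X, y = [], []
    for c, n in enumerate(counts):
        X.append(centers[c] + rng.normal(0, spread, (n, 2)))
        y.extend([c] * n)
    return np.vstack(X), np.array(y)


class TestSmoteenn:
    def test_balanced_separable_is_identity(self):
        X, y = make_blobs([10, 10, 10], seed=1)
        X2, y2, report = smoteenn_resample(X, y, seed=0, n_classes=3)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)
        assert report.counts_after_smote.tolist() == [10, 10, 10]

    def test_imbalanced_blobs_balanced_then_edited(self):
        X, y = make_blobs([50, 10, 5, 40, 8], seed=2)
        X2, y2, report = smoteenn_resample(X, y, seed=4, n_classes=5)
        assert report.counts_after_smote.tolist() == [50] * 5
        assert np.all(report.counts_after_enn <= report.counts_after_smote)
        assert len(X2) == report.counts_after_enn.sum()  # conservation

    def test_surviving_originals_byte_identical(self):
        X, y = make_blobs([20, 6, 6, 6, 6], seed=3)
        X2, y2, report = smoteenn_resample(X, y, seed=1, n_classes=5)
        kept_original = [i for i in range(len(X)) if i not in set(report.removed_indices)]
        for out_row, orig_i in zip(X2, kept_original):
            assert np.array_equal(out_row, X[orig_i])

    def test_seeded_determinism(self):
        X, y = make_blobs([30, 8, 8, 8, 8], seed=5)
        r1 = smoteenn_resample(X, y, seed=7, n_classes=5)
        r2 = smoteenn_resample(X, y, seed=7, n_classes=5)
        assert np.array_equal(r1[0], r2[0]) and np.array_equal(r1[1], r2[1])

    def test_class_elimination_raises(self):
        # one class fully surrounded by another gets edited away
        X = np.array([[0.0], [0.05], [0.1], [0.15], [0.075], [10.0], [10.1]])
        y = np.array([0, 0, 0, 0, 1, 2, 2])
        with pytest.raises(ValueError, match="entirely"):
            smoteenn_resample(X, y, k_smote=1, k_enn=3, seed=0, n_classes=3, target=0)
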