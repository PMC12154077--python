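"""From-scratch SMOTE oversampling and ENN undersampling (SMOTEENN).

SMOTE creates synthetic minority samples by linear interpolation
between a sample and one of its k same-class nearest neighbors:
``x_new = x_i + u * (x_nn - x_i)`` with ``u ~ Uniform(0, 1)``.  ENN
(edited nearest neighbors) then removes any sample whose class label
disagrees with the majority of its k nearest neighbors — with k = 3,
exactly the rule "remove a sample whose label differs from the class
of at least two of its three nearest neighbors".  Both operate on
flattened image vectors under the Euclidean metric.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ResamplingReport",
    "SyntheticProvenance",
    "knn_indices",
    "smote_oversample",
    "enn_filter",
    "smoteenn_resample",
]


@dataclasses.dataclass
class SyntheticProvenance:
    """How one synthetic row was made: parents i, nn and mixing weight u."""

    base_index: int
    neighbor_index: int
    u: float


@dataclasses.dataclass
class ResamplingReport:
    counts_before: np.ndarray
    counts_after_smote: np.ndarray
    counts_after_enn: np.ndarray
    created_index_ranges: dict[int, tuple[int, int]]  # class -> [start, stop)
    removed_indices: np.ndarray
    k_smote: int
    k_enn: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "counts_before": self.counts_before.tolist(),
            "counts_after_smote": self.counts_after_smote.tolist(),
            "counts_after_enn": self.counts_after_enn.tolist(),
            "created_index_ranges": {
                int(k): [int(a), int(b)] for k, (a, b) in self.created_index_ranges.items()
            },
            "removed_indices": self.removed_indices.tolist(),
            "k_smote": self.k_smote,
            "k_enn": self.k_enn,
            "seed": self.seed,
        }


def knn_indices(
    X: np.ndarray, query: np.ndarray, k: int, exclude_self: bool = False
) -> np.ndarray:
    """Indices of the k rows of X nearest to query (Euclidean).

    Ties break toward the lower row index.  With ``exclude_self`` any
    row identical to the query is skipped (one copy only).
    """
    X = np.asarray(X, dtype=np.float64)
    query = np.asarray(query, dtype=np.float64).ravel()
    n = len(X)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    d = np.sqrt(np.sum((X - query) ** 2, axis=1))
    order = np.argsort(d, kind="stable")
    if exclude_self:
        self_hits = np.where(d[order] == 0.0)[0]
        if len(self_hits):
            order = np.delete(order, self_hits[0])
    return order[:k]


def _pairwise_knn(X: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbor indices per row, self excluded, ties by lower index."""
    n = len(X)
    d2 = np.sum(X**2, axis=1)
    dist = d2[:, None] + d2[None, :] - 2.0 * (X @ X.T)
    np.maximum(dist, 0.0, out=dist)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    target_counts,
    k_smote: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict[int, tuple[int, int]], list[SyntheticProvenance]]:
    """Grow each class to max(target, current) by neighbor interpolation.

    Original rows are preserved verbatim at the front of the output;
    synthetic rows are appended class-by-class.  Returns
    ``(X', y', created_ranges, provenance)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_classes = len(target_counts)
    counts = np.bincount(y, minlength=n_classes)

    new_rows, new_labels, provenance = [], [], []
    created: dict[int, tuple[int, int]] = {}
    next_index = len(X)
    for c in range(n_classes):
        deficit = int(target_counts[c]) - int(counts[c])
        if deficit <= 0:
            continue
        members = np.where(y == c)[0]
        if len(members) < 2:
            raise ValueError(
                f"class {c} has {len(members)} sample(s); need >= 2 to interpolate"
            )
        k = min(k_smote, len(members) - 1)
        nn = _pairwise_knn(X[members], k)  # neighbor positions within the class
        start = next_index
        for _ in range(deficit):
            bi = int(rng.integers(len(members)))
            ni = int(nn[bi, int(rng.integers(k))])
            u = float(rng.uniform())
            row = X[members[bi]] + u * (X[members[ni]] - X[members[bi]])
            new_rows.append(row)
            new_labels.append(c)
            provenance.append(
                SyntheticProvenance(int(members[bi]), int(members[ni]), u)
            )
            next_index += 1
        created[c] = (start, next_index)

    if new_rows:
        X_out = np.vstack([X, np.array(new_rows)])
        y_out = np.concatenate([y, np.array(new_labels, dtype=np.int64)])
    else:
        X_out, y_out = X.copy(), y.copy()
    return X_out, y_out, created, provenance


def enn_filter(
    X: np.ndarray,
    y: np.ndarray,
    k_enn: int = 3,
    apply_to: str = "all",
    majority_class: int | None = None,
) -> np.ndarray:
    """Keep mask after one edited-nearest-neighbors pass.

    A sample is kept iff at least k/2 of its k nearest neighbors (self
    excluded, neighbors from the original pre-removal set) share its
    label; even-k exact ties keep.  ``apply_to='majority'`` edits only
    the (largest or given) majority class.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n = len(X)
    if k_enn < 1:
        raise ValueError(f"k_enn must be >= 1, got {k_enn}")
    if n <= k_enn:
        raise ValueError(f"need more than k_enn={k_enn} samples, got {n}")
    if apply_to not in ("all", "majority"):
        raise ValueError("apply_to must be 'all' or 'majority'")

    nn = _pairwise_knn(X, k_enn)
    same = (y[nn] == y[:, None]).sum(axis=1)
    keep = same >= k_enn / 2.0

    if apply_to == "majority":
        if majority_class is None:
            majority_class = int(np.argmax(np.bincount(y)))
        keep = keep | (y != majority_class)
    return keep


def smoteenn_resample(
    X: np.ndarray,
    y: np.ndarray,
    k_smote: int = 5,
    k_enn: int = 3,
    seed: int = 0,
    target: str | int = "auto",
    apply_to: str = "all",
    n_classes: int | None = None,
) -> tuple[np.ndarray, np.ndarray, ResamplingReport]:
    """SMOTE to the largest-class count (or ``target``) then one ENN pass."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    counts_before = np.bincount(y, minlength=n_classes)
    if target == "auto":
        target_count = int(counts_before.max())
    else:
        target_count = int(target)
    targets = [target_count] * n_classes

    Xs, ys, created, _prov = smote_oversample(X, y, targets, k_smote, seed)
    counts_after_smote = np.bincount(ys, minlength=n_classes)

    keep = enn_filter(Xs, ys, k_enn, apply_to=apply_to)
    removed = np.where(~keep)[0]
    X_out, y_out = Xs[keep], ys[keep]
    counts_after_enn = np.bincount(y_out, minlength=n_classes)

    gone = np.where((counts_after_enn == 0) & (counts_after_smote > 0))[0]
    if len(gone):
        raise ValueError(
            f"ENN removed class(es) {gone.tolist()} entirely; "
            "training on the result is impossible"
        )
    report = ResamplingReport(
        counts_before,
        counts_after_smote,
        counts_after_enn,
        created,
        removed,
        k_smote,
        k_enn,
        seed,
    )
    return X_out, y_out, report
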