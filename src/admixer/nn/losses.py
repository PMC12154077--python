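"""Categorical cross-entropy over one-hot labels.

``L = mean_over_samples( -sum_c y_c * log(p_c) )`` with predictions
clipped to ``[eps, 1]`` (eps = 1e-7) before the log.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7

__all__ = ["cross_entropy_loss", "cross_entropy_grad", "one_hot", "EPS"]


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy_loss(y_true_onehot: np.ndarray, y_pred_probs: np.ndarray) -> float:
    y = np.asarray(y_true_onehot, dtype=np.float64)
    p = np.asarray(y_pred_probs, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs predictions {p.shape}")
    p = np.clip(p, EPS, 1.0)
    return float(-(y * np.log(p)).sum(axis=1).mean())


def cross_entropy_grad(y_true_onehot: np.ndarray, y_pred_probs: np.ndarray) -> np.ndarray:
    """dL/d(probs), matching the clipped loss; pairs with the softmax layer."""
    y = np.asarray(y_true_onehot, dtype=np.float64)
    p = np.clip(np.asarray(y_pred_probs, dtype=np.float64), EPS, 1.0)
    g = -(y / p) / len(y)
    # clipping gate: no gradient through saturated entries
    g[(y_pred_probs < EPS) | (y_pred_probs > 1.0)] = 0.0
    return g
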