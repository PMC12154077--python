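"""Data splitting, the training loop, and the ablation grid.

The ablation grid mirrors the study design: initializer x pooling x
optimizer, one model per cell, shared seed, with validation/test
accuracy, loss and F1 per cell.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd

from .arch import ArchitectureSpec
from .evaluation import evaluate_predictions
from .nn import Network, cross_entropy_loss, make_optimizer
from .nn.losses import one_hot
from .phantoms import LabeledImageSet

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "split_dataset", "train", "run_ablation_grid", "TrainedModel"]

_METRIC_COLS = ["loss", "accuracy", "precision", "recall", "f1"]


@dataclasses.dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 8
    epochs: int = 50
    initializer: str = "glorot_normal"
    pooling: str = "avg"
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 42
    resample: str = "none"  # none | smoteenn
    resample_placement: str = "train-only"  # train-only | before-split

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.resample not in ("none", "smoteenn"):
            raise ValueError("resample must be 'none' or 'smoteenn'")
        if self.resample_placement not in ("train-only", "before-split"):
            raise ValueError("resample_placement must be 'train-only' or 'before-split'")
        if self.resample_placement == "before-split" and self.resample != "none":
            logger.warning(
                "resampling before the split leaks synthetic neighbors of "
                "validation/test images into training; use for replication only"
            )


@dataclasses.dataclass
class TrainedModel:
    """A fitted network plus its provenance and per-epoch history."""

    network: Network
    arch: ArchitectureSpec
    config: TrainConfig
    history: pd.DataFrame
    class_names: tuple[str, ...]


def split_dataset(
    data: LabeledImageSet, fractions=(0.8, 0.1, 0.1), seed: int = 42
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Stratified, seeded train/val/test split.

    Per class the requested fractions are honored to within one sample
    (largest-remainder rounding); partitions are disjoint and exhaust
    the input.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    n_parts_nonempty = sum(f > 0 for f in fractions)
    for c in np.unique(data.labels):
        idx = np.where(data.labels == c)[0]
        if len(idx) < n_parts_nonempty:
            raise ValueError(
                f"class {c} has only {len(idx)} sample(s); cannot stratify "
                f"into {n_parts_nonempty} non-empty partitions"
            )
        rng.shuffle(idx)
        quota = np.array([f * len(idx) for f in fractions])
        base = np.floor(quota).astype(int)
        rem = quota - base
        for _ in range(len(idx) - base.sum()):
            j = int(np.argmax(rem))
            base[j] += 1
            rem[j] = -1
        start = 0
        for j, b in enumerate(base):
            parts[j].extend(idx[start : start + b].tolist())
            start += b
    out = []
    for j in range(3):
        sel = np.array(sorted(parts[j]), dtype=np.int64)
        out.append(data.subset(sel) if len(sel) else data.subset(np.array([], dtype=np.int64)))
    return tuple(out)


def _score(net: Network, images: np.ndarray, labels: np.ndarray, batch: int = 64) -> dict:
    probs = np.vstack(
        [net.forward(images[i : i + batch]) for i in range(0, len(images), batch)]
    )
    rep = evaluate_predictions(labels, probs, n_classes=net.n_classes)
    loss = cross_entropy_loss(one_hot(labels, net.n_classes), probs)
    return {
        "loss": loss,
        "accuracy": rep.accuracy,
        "precision": rep.precision,
        "recall": rep.recall,
        "f1": rep.f1,
    }


def train(
    arch: ArchitectureSpec,
    train_set: LabeledImageSet,
    val_set: LabeledImageSet | None,
    config: TrainConfig,
) -> TrainedModel:
    """Minimize the cross-entropy with mini-batch gradient descent.

    All randomness (weight init, dropout, shuffling) derives from
    ``config.seed``.  The history records loss, accuracy, precision,
    recall and F1 for train and validation at every epoch.
    """
    classes_present = np.unique(train_set.labels)
    if len(classes_present) < 2:
        raise ValueError(
            f"training needs >= 2 classes, found {classes_present.tolist()}"
        )
    n_classes = arch.output_shapes[-1][0]
    missing = set(range(n_classes)) - set(classes_present.tolist())
    if missing:
        logger.warning("classes %s absent from the training split", sorted(missing))

    net = Network(arch, seed=config.seed)
    opt = make_optimizer(config.optimizer, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    X, y = train_set.images, train_set.labels
    rows = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(X))
        batch_losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            loss = net.loss_and_backward(X[sel], y[sel])
            opt.step(net.parameters(), net.gradients())
            batch_losses.append(loss)
        row = {"epoch": epoch, "batch_loss": float(np.mean(batch_losses))}
        row.update({f"train_{k}": v for k, v in _score(net, X, y).items()})
        if val_set is not None and len(val_set):
            row.update(
                {f"val_{k}": v for k, v in _score(net, val_set.images, val_set.labels).items()}
            )
        rows.append(row)
        logger.info(
            "epoch %d: train loss %.4f acc %.2f%%%s",
            epoch,
            row["train_loss"],
            row["train_accuracy"],
            f" | val acc {row['val_accuracy']:.2f}%" if "val_accuracy" in row else "",
        )
    history = pd.DataFrame(rows)
    return TrainedModel(net, arch, config, history, train_set.class_names)


def run_ablation_grid(
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    test_set: LabeledImageSet | None,
    grid: dict,
    base_config: TrainConfig,
    build_arch=None,
) -> pd.DataFrame:
    """Train one model per (initializer, pooling, optimizer) cell.

    ``build_arch(initializer, pooling)`` constructs the architecture for
    a cell (defaults to the full-size mixer builder).  Returns one row
    per cell with validation and test loss/accuracy/F1.
    """
    from .arch import build_default_arch

    if build_arch is None:
        build_arch = build_default_arch
    initializers = grid.get("initializers", [base_config.initializer])
    poolings = grid.get("poolings", [base_config.pooling])
    optimizers = grid.get("optimizers", [base_config.optimizer])
    if not (initializers and poolings and optimizers):
        raise ValueError("ablation grid has an empty axis")

    rows = []
    for init, pool, optname in itertools.product(initializers, poolings, optimizers):
        cfg = dataclasses.replace(
            base_config, initializer=init, pooling=pool, optimizer=optname
        )
        cell = {"initializer": init, "pooling": pool, "optimizer": optname}
        try:
            arch = build_arch(initializer=init, pooling=pool)
            model = train(arch, train_set, val_set, cfg)
        except Exception as exc:  # noqa: BLE001 - cell failures are recorded
            logger.error("ablation cell %s failed: %s", cell, exc)
            cell["error"] = str(exc)
            rows.append(cell)
            continue
        last = model.history.iloc[-1]
        for m in _METRIC_COLS:
            cell[f"val_{m}"] = float(last[f"val_{m}"])
        if test_set is not None and len(test_set):
            ts = _score(model.network, test_set.images, test_set.labels)
            for m in _METRIC_COLS:
                cell[f"test_{m}"] = ts[m]
        rows.append(cell)
    return pd.DataFrame(rows)
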