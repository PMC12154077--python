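"""Model/Results interface over the convolutional-mixer pipeline.

``ConvMixerClassifier`` is built from a labeled image set (plus an
optional architecture and training configuration); ``fit()`` runs the
training loop and returns ``ClassifierResults`` carrying the fitted
weights, per-epoch history, held-out metrics and a ``summary()`` table.
Prediction, evaluation, and saliency mapping hang off the results
object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import trainer as _trainer
from .arch import ArchitectureSpec, build_default_arch, build_small_arch, summary_table
from .evaluation import EvalReport, evaluate_predictions
from .nn import Network, cross_entropy_loss
from .phantoms import LabeledImageSet
from .resampling import smoteenn_resample
from .trainer import TrainConfig, TrainedModel, split_dataset

__all__ = ["ConvMixerClassifier", "ClassifierResults", "forward", "cross_entropy_loss"]


def forward(model: TrainedModel | Network, images: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch (grayscale replicated as needed)."""
    net = model.network if isinstance(model, TrainedModel) else model
    return net.forward(images, training=False)


class ConvMixerClassifier:
    """The staged-dementia mixer CNN bound to a dataset.

    Parameters
    ----------
    data:
        Labeled images (loaded or phantom).
    arch:
        Architecture spec; defaults to the full mixer when the images
        are >= 68 px per side, else the scaled 3x3 variant.
    config:
        Training configuration (optimizer, initializer, pooling, split
        fractions, resampling policy, seed).
    """

    def __init__(
        self,
        data: LabeledImageSet,
        arch: ArchitectureSpec | None = None,
        config: TrainConfig | None = None,
        channels: int | None = None,
    ):
        self.data = data
        self.config = config or TrainConfig()
        if arch is None:
            h = data.images.shape[1]
            w = data.images.shape[2]
            builder = build_default_arch if min(h, w) >= 68 else build_small_arch
            c = channels if channels is not None else (3 if builder is build_default_arch else 1)
            arch = builder(
                (h, w, c),
                initializer=self.config.initializer,
                pooling=self.config.pooling,
                n_classes=len(data.class_names),
            )
        self.arch = arch

    @classmethod
    def from_directory(cls, root, target_size: int = 224, **kwargs) -> "ConvMixerClassifier":
        from .io import load_image_dataset

        data, _ = load_image_dataset(root, target_size=target_size)
        return cls(data, **kwargs)

    def fit(self) -> "ClassifierResults":
        cfg = self.config
        data = self.data
        if cfg.resample == "smoteenn" and cfg.resample_placement == "before-split":
            data = _resample_set(data, cfg)
        train_set, val_set, test_set = split_dataset(data, cfg.split, cfg.seed)
        if cfg.resample == "smoteenn" and cfg.resample_placement == "train-only":
            train_set = _resample_set(train_set, cfg)
        fitted = _trainer.train(self.arch, train_set, val_set, cfg)
        return ClassifierResults(self, fitted, train_set, val_set, test_set)


def _resample_set(data: LabeledImageSet, cfg: TrainConfig) -> LabeledImageSet:
    n, h, w = data.images.shape
    X = data.images.reshape(n, h * w)
    Xr, yr, _report = smoteenn_resample(
        X, data.labels, seed=cfg.seed, n_classes=len(data.class_names)
    )
    return LabeledImageSet(
        np.clip(Xr.reshape(len(yr), h, w), 0.0, 1.0),
        yr,
        None,
        data.class_names,
        data.provenance + "+smoteenn",
    )


class ClassifierResults:
    """Fitted estimates: weights, history, metrics, saliency access."""

    def __init__(self, model, fitted: TrainedModel, train_set, val_set, test_set):
        self.model = model
        self.fitted = fitted
        self.network: Network = fitted.network
        self.history: pd.DataFrame = fitted.history
        self.train_set, self.val_set, self.test_set = train_set, val_set, test_set
        self.class_names = fitted.class_names

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.network.forward(images, training=False)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def evaluate(self, data: LabeledImageSet | None = None) -> EvalReport:
        """Score on ``data`` (default: the held-out test split, else val)."""
        if data is None:
            data = self.test_set if len(self.test_set) else self.val_set
        probs = self.predict_proba(data.images)
        return evaluate_predictions(
            data.labels, probs, n_classes=self.network.n_classes
        )

    def saliency(self, image: np.ndarray, target_class: int | None = None, layer=None):
        from .asop import asop_map

        return asop_map(self.fitted, image, target_class, layer=layer)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.fitted.config
        last = self.history.iloc[-1]
        lines = [
            "Convolutional-mixer classifier results",
            "=" * 70,
            f"classes: {', '.join(self.class_names)}",
            f"optimizer: {cfg.optimizer}  lr: {cfg.learning_rate}  "
            f"batch: {cfg.batch_size}  epochs: {cfg.epochs}",
            f"initializer: {cfg.initializer}  pooling: {cfg.pooling}  seed: {cfg.seed}",
            f"train/val/test sizes: {len(self.train_set)}/{len(self.val_set)}/{len(self.test_set)}",
            "",
            summary_table(self.model.arch),
            "",
            f"final train loss {last['train_loss']:.4f}  accuracy {last['train_accuracy']:.2f}%",
        ]
        if "val_accuracy" in last:
            lines.append(
                f"final val   loss {last['val_loss']:.4f}  accuracy {last['val_accuracy']:.2f}%  "
                f"F1 {last['val_f1']:.2f}%"
            )
        if len(self.test_set):
            rep = self.evaluate(self.test_set)
            lines.append(
                f"test        accuracy {rep.accuracy:.2f}%  precision {rep.precision:.2f}%  "
                f"recall {rep.recall:.2f}%  F1 {rep.f1:.2f}%"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path)
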