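"""Network: an ArchitectureSpec instantiated with weights.

Holds the ordered layer objects, runs batched forward/backward passes,
exposes parameter/gradient lists for the optimizers, and computes the
gradient of a class logit with respect to an internal activation (the
quantity the saliency map needs).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import build_layer
from .losses import cross_entropy_grad, cross_entropy_loss, one_hot

__all__ = ["Network"]


class Network:
    def __init__(self, arch, seed: int = 0):
        self.arch = arch
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers = []
        shape = arch.input_shape
        for spec, out_shape in zip(arch.layers, arch.output_shapes):
            self.layers.append(build_layer(spec, shape, rng))
            shape = out_shape
        self.n_classes = arch.output_shapes[-1][0]

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params.values())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.grads[k] for k in layer.params)
        return out

    def total_params(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    # -- inference ----------------------------------------------------------
    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:  # grayscale batch -> replicate to input channels
            x = np.repeat(x[..., None], self.arch.input_shape[2], axis=-1)
        if x.shape[1:] != tuple(self.arch.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match architecture "
                f"input {self.arch.input_shape}"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities for a batch; dropout active only in training."""
        h = self._prepare(x)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def forward_with_activations(self, x: np.ndarray) -> list[np.ndarray]:
        """Inference pass returning every layer's output (index i = layer i)."""
        h = self._prepare(x)
        acts = []
        for layer in self.layers:
            h = layer.forward(h, False)
            acts.append(h)
        return acts

    # -- training -----------------------------------------------------------
    def loss_and_backward(self, x: np.ndarray, labels: np.ndarray) -> float:
        """Forward in training mode, backprop the cross-entropy, fill grads."""
        probs = self.forward(x, training=True)
        y = one_hot(labels, self.n_classes)
        loss = cross_entropy_loss(y, probs)
        d = cross_entropy_grad(y, probs)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return loss

    # -- saliency support ---------------------------------------------------
    def logits(self, x: np.ndarray) -> np.ndarray:
        """Pre-softmax class scores."""
        h = self._prepare(x)
        for layer in self.layers[:-1]:
            h = layer.forward(h, False)
        return h

    def logit_grad_wrt_activation(
        self, x: np.ndarray, target_class: int, layer_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(activation, d logit_c / d activation) at ``layer_index``.

        The backward pass starts from a one-hot seed on the pre-softmax
        logits, so softmax saturation never flattens the gradients.
        """
        acts = self.forward_with_activations(x)
        n = acts[-1].shape[0]
        seed_grad = np.zeros_like(acts[-2])
        seed_grad[:, target_class] = 1.0
        d = seed_grad
        # skip the softmax layer: seed is already on the logits
        for i in range(len(self.layers) - 2, layer_index, -1):
            d = self.layers[i].backward(d)
        assert d.shape == acts[layer_index].shape, (d.shape, n)
        return acts[layer_index], d

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a sidecar JSON of the architecture."""
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}:{k}"] = v
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(
            json.dumps({"arch_yaml": self.arch.to_yaml(), "seed": self.seed})
        )

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        from ..arch import ArchitectureSpec

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arch = ArchitectureSpec.from_yaml(meta["arch_yaml"])
        net = cls(arch, seed=meta.get("seed", 0))
        with np.load(path.with_suffix(".npz")) as data:
            for i, layer in enumerate(net.layers):
                for k in layer.params:
                    layer.params[k][...] = data[f"layer{i}:{k}"]
        return net
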