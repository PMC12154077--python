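"""Activation-space occlusion sensitivity map (gradient-weighted saliency).

For a target class c, the activation maps A_k of the final conv-type
layer are combined with weights alpha_k obtained by global average
pooling of the gradients d y_c / d A_k, where y_c is the pre-softmax
class score:

    S = ReLU( sum_k alpha_k * A_k )

S is bilinearly upsampled to the input pixel grid and normalized by its
maximum (all-zero maps are left at zero).  High values mark regions
that raise the class score.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from skimage.transform import resize as _resize

from .trainer import TrainedModel

logger = logging.getLogger(__name__)

__all__ = ["SaliencyMap", "asop_map", "overlay_heatmap"]


@dataclasses.dataclass
class SaliencyMap:
    heatmap: np.ndarray  # (H, W) in [0, 1], aligned to the input grid
    layer_index: int
    target_class: int
    alphas: np.ndarray  # pooled gradient weight per activation channel


def _last_conv_index(network) -> int:
    idx = [
        i
        for i, spec in enumerate(network.arch.layers)
        if spec.kind in ("conv", "separable_conv")
    ]
    if not idx:
        raise ValueError("model has no convolutional layer")
    return idx[-1]


def asop_map(
    model: TrainedModel,
    image: np.ndarray,
    target_class: int | None = None,
    layer: int | str | None = None,
) -> SaliencyMap:
    """Saliency for one image; defaults to the predicted class and the
    last conv-type layer."""
    net = model.network if isinstance(model, TrainedModel) else model
    if layer is None:
        layer_index = _last_conv_index(net)
    else:
        if isinstance(layer, str):
            names = [s.name for s in net.arch.layers]
            if layer not in names:
                raise ValueError(f"no layer named {layer!r}; options: {names}")
            layer_index = names.index(layer)
        else:
            layer_index = int(layer)
        if net.arch.layers[layer_index].kind not in ("conv", "separable_conv"):
            raise ValueError(
                f"layer {layer!r} is a {net.arch.layers[layer_index].kind}, "
                "not a convolutional layer"
            )
    if target_class is None:
        target_class = int(net.forward(image)[0].argmax())

    acts, grads = net.logit_grad_wrt_activation(image, target_class, layer_index)
    a, g = acts[0], grads[0]  # (h, w, K)
    alphas = g.mean(axis=(0, 1))
    s = np.maximum((a * alphas).sum(axis=-1), 0.0)

    in_h, in_w = net.arch.input_shape[:2]
    heat = _resize(s, (in_h, in_w), order=1, mode="edge", anti_aliasing=False)
    heat = np.maximum(heat, 0.0)
    m = heat.max()
    if m > 0:
        heat = heat / m
    else:
        logger.info(
            "saliency map is identically zero for class %d (no positive "
            "activation survived the ReLU)",
            target_class,
        )
    return SaliencyMap(heat, layer_index, target_class, alphas)


def overlay_heatmap(
    image: np.ndarray,
    saliency: SaliencyMap | np.ndarray,
    colormap: str = "jet",
    alpha: float = 0.4,
) -> np.ndarray:
    """Blend the heatmap over the grayscale slice as an RGB image.

    High heat maps to the red end of the colormap, low to blue/green;
    an all-zero map returns the plain grayscale rendering.
    """
    import matplotlib

    heat = saliency.heatmap if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = image.mean(axis=-1)
    if image.shape != heat.shape:
        raise ValueError(f"image {image.shape} and heatmap {heat.shape} misaligned")
    gray_rgb = np.repeat(image[:, :, None], 3, axis=2)
    if not heat.any():
        return gray_rgb
    cmap = matplotlib.colormaps[colormap]
    colored = cmap(heat)[:, :, :3]
    return np.clip((1 - alpha) * gray_rgb + alpha * colored, 0.0, 1.0)
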