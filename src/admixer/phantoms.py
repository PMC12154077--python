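"""Synthetic skull-bearing brain-slice phantoms with ground-truth masks.

The generator emulates the statistical shape of a staged dementia MRI
dataset: five classes (CN, EMCI, LMCI, MCI, AD) whose central CSF /
ventricular dark region grows monotonically with disease severity, a
bright skull annulus around the brain tissue disc, per-image geometric
jitter, and additive Gaussian noise.  Every downstream stage (skull
stripping, resampling, training, evaluation, saliency) is testable on
these images without any external download.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_ATROPHY_SCALES",
    "PhantomSpec",
    "LabeledImageSet",
    "generate_phantom",
    "generate_dataset",
    "save_image_set",
]

#: Canonical stage order: cognitively normal through Alzheimer's disease.
CLASS_NAMES = ("CN", "EMCI", "LMCI", "MCI", "AD")

#: Radius of the dark central "ventricle" disc as a fraction of image
#: size, per class, monotone non-decreasing with stage severity.
DEFAULT_ATROPHY_SCALES = (0.0, 0.07, 0.13, 0.19, 0.26)


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic brain-slice image.

    All intensities live in [0, 1].  ``atrophy_scale`` defaults to the
    class-dependent value from :data:`DEFAULT_ATROPHY_SCALES`; passing it
    explicitly overrides the class default.
    """

    image_size: int = 224
    class_id: int = 0
    skull_inner: float = 0.40
    skull_outer: float = 0.46
    skull_intensity: float = 0.95
    brain_radius: float = 0.38
    brain_intensity: float = 0.55
    ventricle_intensity: float = 0.05
    atrophy_scale: float | None = None
    jitter: float = 0.015
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.class_id <= 4:
            raise ValueError(
                f"class_id must be in 0..4 ({', '.join(CLASS_NAMES)}); "
                f"got {self.class_id}"
            )
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        for name in ("skull_intensity", "brain_intensity", "ventricle_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def resolved_atrophy(self) -> float:
        if self.atrophy_scale is not None:
            return self.atrophy_scale
        return DEFAULT_ATROPHY_SCALES[self.class_id]


@dataclasses.dataclass
class LabeledImageSet:
    """Images + integer class labels (+ optional ground-truth brain masks)."""

    images: np.ndarray  # (n, H, W) float in [0, 1]
    labels: np.ndarray  # (n,) int in {0..4}
    masks: np.ndarray | None = None  # (n, H, W) bool
    class_names: tuple[str, ...] = CLASS_NAMES
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if len(self.labels) and not np.all((self.labels >= 0) & (self.labels < len(self.class_names))):
            raise ValueError("labels outside class range")

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(
            self.images[idx],
            self.labels[idx],
            None if self.masks is None else self.masks[idx],
            self.class_names,
            self.provenance,
        )


def _disc(size: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Render one phantom; returns ``(image, brain_mask, label)``.

    The brain mask is exactly the tissue disc (ventricle included,
    skull ring and background excluded).  With ``noise_sigma=0`` the
    image is piecewise constant: 0 background, ``skull_intensity`` on
    the annulus, ``brain_intensity`` on tissue, ``ventricle_intensity``
    on the central dark disc.  Identical spec + seed is bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    # per-image geometric jitter (center shift, radius scale)
    cy = s / 2 + rng.uniform(-spec.jitter, spec.jitter) * s
    cx = s / 2 + rng.uniform(-spec.jitter, spec.jitter) * s
    rscale = 1.0 + rng.uniform(-spec.jitter, spec.jitter)

    brain_r = spec.brain_radius * s * rscale
    inner_r = spec.skull_inner * s * rscale
    outer_r = spec.skull_outer * s * rscale

    brain = _disc(s, cy, cx, brain_r)
    ring = _disc(s, cy, cx, outer_r) & ~_disc(s, cy, cx, inner_r)

    image = np.zeros((s, s), dtype=np.float64)
    image[ring] = spec.skull_intensity
    image[brain] = spec.brain_intensity

    vent_r = spec.resolved_atrophy * s * rscale
    if vent_r > 0:
        vent = _disc(s, cy, cx, vent_r)
        image[vent & brain] = spec.ventricle_intensity

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return image, brain, spec.class_id


def generate_dataset(
    class_counts,
    image_size: int = 224,
    seed: int = 42,
    noise_sigma: float = 0.02,
    **spec_overrides,
) -> LabeledImageSet:
    """Generate a phantom dataset with exactly the requested per-class counts.

    Per-image seeds derive deterministically from the master ``seed``
    (seed + running image index), so the whole set is a pure function of
    ``(class_counts, image_size, seed)`` and the remaining spec fields.
    """
    class_counts = [int(c) for c in class_counts]
    if len(class_counts) != len(CLASS_NAMES):
        raise ValueError(f"need {len(CLASS_NAMES)} class counts, got {len(class_counts)}")
    if any(c < 0 for c in class_counts):
        raise ValueError("class counts must be >= 0")

    images, labels, masks = [], [], []
    idx = 0
    for class_id, count in enumerate(class_counts):
        for _ in range(count):
            spec = PhantomSpec(
                image_size=image_size,
                class_id=class_id,
                noise_sigma=noise_sigma,
                seed=seed + idx,
                **spec_overrides,
            )
            img, mask, label = generate_phantom(spec)
            images.append(img)
            labels.append(label)
            masks.append(mask)
            idx += 1
    n = sum(class_counts)
    shape = (n, image_size, image_size)
    return LabeledImageSet(
        np.array(images, dtype=np.float64).reshape(shape),
        np.array(labels, dtype=np.int64),
        np.array(masks, dtype=bool).reshape(shape),
    )


def save_image_set(data: LabeledImageSet, root: str | Path, with_masks: bool = True) -> Path:
    """Write a class-named directory tree of 8-bit grayscale PNGs.

    Layout: ``<root>/<class_name>/<idx>.png`` plus a ``masks/`` mirror,
    interchangeable with the loader in :mod:`admixer.io`.
    """
    from PIL import Image

    root = Path(root)
    counters = {name: 0 for name in data.class_names}
    for i in range(len(data)):
        name = data.class_names[data.labels[i]]
        k = counters[name]
        counters[name] += 1
        d = root / name
        d.mkdir(parents=True, exist_ok=True)
        arr = np.clip(np.round(data.images[i] * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(d / f"{k:05d}.png")
        if with_masks and data.masks is not None:
            md = root / "masks" / name
            md.mkdir(parents=True, exist_ok=True)
            Image.fromarray(
                (data.masks[i].astype(np.uint8) * 255), mode="L"
            ).save(md / f"{k:05d}.png")
    return root
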