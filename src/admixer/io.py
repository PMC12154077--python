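"""Dataset loading from class-named directory trees.

Layout: ``<root>/<class_name>/*.png|jpg|jpeg|nii|nii.gz`` — one
directory per diagnostic class (a ``masks/`` subtree, if present, is
loaded as ground-truth brain masks, not as a class).  Images are
resized to ``target_size`` with bilinear interpolation and scaled to
[0, 1]; labels follow sorted directory names unless an explicit class
order is given.  NIfTI volumes contribute their middle axial slice.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _resize

from .phantoms import CLASS_NAMES, LabeledImageSet

logger = logging.getLogger(__name__)

__all__ = ["DatasetManifest", "load_image_dataset"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}
_NIFTI_SUFFIXES = {".nii"}


@dataclasses.dataclass
class DatasetManifest:
    root: str
    class_names: list[str]
    files: dict[str, list[str]]  # class name -> relative paths, load order
    image_size: int
    channel_policy: str
    skipped: list[str]

    @property
    def class_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.files.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DatasetManifest":
        p = Path(source)
        return cls(**json.loads(p.read_text() if p.exists() else str(source)))


def _read_image(path: Path) -> np.ndarray | None:
    suffix = path.suffix.lower()
    try:
        if suffix in _NIFTI_SUFFIXES or path.name.lower().endswith(".nii.gz"):
            import nibabel as nib

            vol = np.asanyarray(nib.load(path).dataobj).astype(np.float64)
            if vol.ndim >= 3:
                vol = vol[..., vol.shape[-1] // 2] if vol.ndim == 3 else vol[..., 0, 0]
            lo, hi = vol.min(), vol.max()
            return (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
        with Image.open(path) as im:
            arr = np.asarray(im.convert("I;16") if im.mode == "I;16" else im.convert("L"))
        scale = 65535.0 if arr.dtype == np.uint16 or arr.max() > 255 else 255.0
        return arr.astype(np.float64) / scale
    except Exception as exc:  # noqa: BLE001 - unreadable files are skipped
        logger.warning("skipping unreadable file %s: %s", path, exc)
        return None


def load_image_dataset(
    root: str | Path,
    target_size: int = 224,
    channel_policy: str = "replicate",
    class_order: list[str] | None = None,
    exclude: set[str] | None = None,
) -> tuple[LabeledImageSet, DatasetManifest]:
    """Load a class-directory tree into a LabeledImageSet + manifest.

    ``channel_policy`` is recorded for the model stage ('replicate'
    grayscale to 3 channels, or 'native'); images themselves are kept
    2D here.  ``exclude`` holds relative paths to drop (curation hook).
    """
    root = Path(root)
    if channel_policy not in ("replicate", "native"):
        raise ValueError("channel_policy must be 'replicate' or 'native'")
    class_dirs = sorted(
        d for d in root.iterdir() if d.is_dir() and d.name != "masks"
    ) if root.is_dir() else []
    if not class_dirs:
        raise ValueError(f"no class directories found under {root}")
    names = [d.name for d in class_dirs]
    if class_order is None and set(names) == set(CLASS_NAMES):
        class_order = list(CLASS_NAMES)  # canonical stage order, not alphabetic
    if class_order is not None:
        unknown = set(names) - set(class_order)
        if unknown:
            raise ValueError(f"directories {sorted(unknown)} not in class_order")
        class_dirs = sorted(class_dirs, key=lambda d: class_order.index(d.name))
        names = [d.name for d in class_dirs]

    exclude = exclude or set()
    images, labels, files, skipped = [], [], {}, []
    masks_root = root / "masks"
    masks: list[np.ndarray] = []
    have_all_masks = masks_root.is_dir()
    for label, d in enumerate(class_dirs):
        rel_files = []
        for f in sorted(d.iterdir()):
            rel = str(f.relative_to(root))
            if rel in exclude:
                skipped.append(rel + " (excluded)")
                continue
            if not (
                f.suffix.lower() in _IMAGE_SUFFIXES
                or f.suffix.lower() in _NIFTI_SUFFIXES
                or f.name.lower().endswith(".nii.gz")
            ):
                continue
            arr = _read_image(f)
            if arr is None:
                skipped.append(rel + " (unreadable)")
                continue
            if arr.shape != (target_size, target_size):
                arr = _resize(arr, (target_size, target_size), order=1, mode="edge", anti_aliasing=False)
            images.append(np.clip(arr, 0.0, 1.0))
            labels.append(label)
            rel_files.append(rel)
            if have_all_masks:
                mf = masks_root / d.name / f.name
                marr = _read_image(mf) if mf.exists() else None
                if marr is None:
                    have_all_masks = False
                else:
                    if marr.shape != (target_size, target_size):
                        marr = _resize(marr, (target_size, target_size), order=0, mode="edge", anti_aliasing=False)
                    masks.append(marr > 0.5)
        files[d.name] = rel_files
    if not images:
        raise ValueError(f"no decodable images found under {root}")

    data = LabeledImageSet(
        np.stack(images),
        np.array(labels, dtype=np.int64),
        np.stack(masks) if (have_all_masks and len(masks) == len(images)) else None,
        tuple(names),
        provenance="loaded",
    )
    manifest = DatasetManifest(
        root=str(root),
        class_names=names,
        files=files,
        image_size=target_size,
        channel_policy=channel_policy,
        skipped=skipped,
    )
    return data, manifest
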