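"""End-to-end pipeline: skull strip -> split -> resample -> train ->
evaluate -> explain, driven by one YAML/dict config, writing a
self-describing run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .arch import build_default_arch, build_small_arch
from .asop import asop_map
from .model import ConvMixerClassifier
from .phantoms import generate_dataset, LabeledImageSet
from .skullstrip import StripParams, dice_coefficient, strip_skull
from .trainer import TrainConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "default_config"]


def default_config() -> dict:
    return {
        "data": {"phantoms": {"class_counts": [40, 40, 40, 40, 40], "image_size": 64, "noise_sigma": 0.02}},
        "skullstrip": {"enabled": True, "erosion_radius": 2, "dilation_radius": 2},
        "train": {
            "optimizer": "adam",
            "learning_rate": 0.001,
            "batch_size": 8,
            "epochs": 5,
            "initializer": "glorot_normal",
            "pooling": "avg",
            "split": [0.8, 0.1, 0.1],
            "resample": "smoteenn",
            "resample_placement": "train-only",
        },
        "explain": {"n_images": 3},
        "seed": 42,
    }


def _stage(summary: dict, name: str):
    summary[name] = {"status": "ok"}
    return summary[name]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory.

    The run directory holds the resolved config, per-epoch metrics CSV,
    the model checkpoint, saliency PNGs and one ``summary.json`` with a
    block per stage.  Any stage failure aborts with the stage name.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 42))
    summary: dict = {
        "environment": {
            "admixer": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "seed": seed,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))

    stage = "data"
    try:
        block = _stage(summary, stage)
        dc = config["data"]
        if "phantoms" in dc:
            data = generate_dataset(seed=seed, **dc["phantoms"])
        else:
            from .io import load_image_dataset

            data, manifest = load_image_dataset(
                dc["root"], target_size=dc.get("target_size", 224)
            )
            manifest.to_json(out / "manifest.json")
        block["n_images"] = len(data)
        block["class_counts"] = data.class_counts().tolist()

        stage = "skullstrip"
        block = _stage(summary, stage)
        sc = dict(config.get("skullstrip", {"enabled": True}))
        if sc.pop("enabled", True):
            params = StripParams(**sc)
            stripped, dices = [], []
            for i in range(len(data)):
                s, m = strip_skull(data.images[i], params)
                stripped.append(s)
                if data.masks is not None:
                    dices.append(dice_coefficient(m, data.masks[i]))
            data = LabeledImageSet(
                np.stack(stripped), data.labels, data.masks, data.class_names, data.provenance
            )
            if dices:
                block["mean_dice"] = float(np.mean(dices))
        else:
            block["status"] = "skipped"

        stage = "resample"
        block = _stage(summary, stage)
        tc = dict(config.get("train", {}))
        split = tuple(tc.pop("split", (0.8, 0.1, 0.1)))
        cfg = TrainConfig(seed=seed, split=split, **tc)
        if cfg.resample == "none":
            block["status"] = "skipped"
            block["class_counts"] = data.class_counts().tolist()
        else:
            block["placement"] = cfg.resample_placement

        stage = "split"
        _stage(summary, stage)["fractions"] = list(split)

        stage = "train"
        block = _stage(summary, stage)
        model = ConvMixerClassifier(data, config=cfg)
        results = model.fit()
        results.history.to_csv(out / "history.csv", index=False)
        results.save(out / "checkpoint")
        if cfg.resample == "smoteenn":
            summary["resample"]["class_counts_after"] = (
                results.train_set.class_counts().tolist()
            )
        summary["split"]["sizes"] = [
            len(results.train_set), len(results.val_set), len(results.test_set)
        ]
        last = results.history.iloc[-1]
        block["epochs"] = int(cfg.epochs)
        block["final_train_accuracy_pct"] = round(float(last["train_accuracy"]), 2)
        if "val_accuracy" in last:
            block["final_val_accuracy_pct"] = round(float(last["val_accuracy"]), 2)

        stage = "evaluate"
        block = _stage(summary, stage)
        report = results.evaluate()
        block.update(report.to_dict())
        (out / "confusion_matrix.csv").write_text(
            "\n".join(",".join(map(str, row)) for row in report.confusion.tolist())
        )

        stage = "explain"
        block = _stage(summary, stage)
        n_expl = int(config.get("explain", {}).get("n_images", 3))
        eval_set = results.test_set if len(results.test_set) else results.val_set
        picks = list(range(min(n_expl, len(eval_set))))
        heat_files = []
        for i in picks:
            smap = asop_map(results.fitted, eval_set.images[i])
            from .asop import overlay_heatmap
            from PIL import Image

            rgb = overlay_heatmap(eval_set.images[i], smap)
            f = out / f"saliency_{i}_class{smap.target_class}.png"
            Image.fromarray((rgb * 255).astype(np.uint8)).save(f)
            heat_files.append(f.name)
        block["images"] = heat_files
    except Exception as exc:
        summary.setdefault(stage, {})["status"] = "failed"
        summary[stage]["error"] = str(exc)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
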