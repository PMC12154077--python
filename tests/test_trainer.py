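"""Stratified splitting, training-loop determinism and metric
consistency, and the ablation grid contract."""

import dataclasses

import numpy as np
import pytest

from admixer.arch import build_small_arch
from admixer.evaluation import evaluate_predictions
from admixer.phantoms import generate_dataset
from admixer.trainer import TrainConfig, run_ablation_grid, split_dataset, train


@pytest.fixture(scope="module")
def small_data():
    # 48 px is the smallest extent the scaled mixer accepts comfortably
    return generate_dataset([10] * 5, image_size=48, seed=17, noise_sigma=0.0)


def small_arch(**kw):
    return build_small_arch((48, 48, 1), **kw)


class TestSplit:
    def test_exact_division_single_class(self):
        data = generate_dataset([100, 0, 0, 0, 0], image_size=32, seed=0)
        tr, va, te = split_dataset(data, (0.8, 0.1, 0.1), seed=1)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_same_seed_identical_partitions(self, small_data):
        a = split_dataset(small_data, (0.6, 0.2, 0.2), seed=5)
        b = split_dataset(small_data, (0.6, 0.2, 0.2), seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.labels, y.labels)
            assert np.array_equal(x.images, y.images)

    def test_stratified_counts_per_class(self):
        data = generate_dataset([50] * 5, image_size=32, seed=3)
        tr, va, te = split_dataset(data, (0.8, 0.2, 0.0), seed=2)
        assert tr.class_counts().tolist() == [40] * 5
        assert va.class_counts().tolist() == [10] * 5
        assert len(te) == 0

    def test_partitions_disjoint_and_exhaustive(self, small_data):
        tr, va, te = split_dataset(small_data, (0.5, 0.3, 0.2), seed=9)
        assert len(tr) + len(va) + len(te) == len(small_data)
        # membership via unique pixel content (images are distinct by seed)
        seen = set()
        for part in (tr, va, te):
            for img in part.images:
                key = img.tobytes()
                assert key not in seen
                seen.add(key)

    def test_impossible_stratification_names_class(self):
        data = generate_dataset([5, 1, 5, 5, 5], image_size=32, seed=0)
        with pytest.raises(ValueError, match="class 1"):
            split_dataset(data, (0.6, 0.2, 0.2), seed=0)


class TestTrain:
    def test_zero_learning_rate_keeps_weights(self, small_data):
        cfg = TrainConfig(epochs=2, learning_rate=0.0, split=(0.8, 0.2, 0.0), seed=3)
        tr, va, _ = split_dataset(small_data, cfg.split, cfg.seed)
        from admixer.nn import Network

        reference = Network(small_arch(), seed=cfg.seed)
        model = train(small_arch(), tr, va, cfg)
        for a, b in zip(reference.parameters(), model.network.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_reproduces_run(self, small_data):
        cfg = TrainConfig(epochs=2, split=(0.8, 0.2, 0.0), seed=7)
        tr, va, _ = split_dataset(small_data, cfg.split, cfg.seed)
        h1 = train(small_arch(), tr, va, cfg).history
        h2 = train(small_arch(), tr, va, cfg).history
        assert h1["val_loss"].iloc[-1] == h2["val_loss"].iloc[-1]
        assert h1.equals(h2)

    def test_history_agrees_with_evaluation_module(self, small_data):
        cfg = TrainConfig(epochs=1, split=(0.8, 0.2, 0.0), seed=4)
        tr, va, _ = split_dataset(small_data, cfg.split, cfg.seed)
        model = train(small_arch(), tr, va, cfg)
        probs = model.network.forward(va.images)
        rep = evaluate_predictions(va.labels, probs, n_classes=5)
        last = model.history.iloc[-1]
        assert last["val_accuracy"] == pytest.approx(rep.accuracy, abs=1e-6)
        assert last["val_f1"] == pytest.approx(rep.f1, abs=1e-6)

    def test_single_class_training_rejected(self):
        data = generate_dataset([8, 0, 0, 0, 0], image_size=48, seed=2)
        cfg = TrainConfig(epochs=1, split=(1.0, 0.0, 0.0))
        tr, va, _ = split_dataset(data, cfg.split, cfg.seed)
        with pytest.raises(ValueError, match="2 classes"):
            train(small_arch(), tr, None, cfg)

    def test_loss_mostly_decreases_on_easy_task(self):
        data = generate_dataset([20] * 5, image_size=48, seed=23, noise_sigma=0.0)
        cfg = TrainConfig(epochs=6, split=(0.8, 0.2, 0.0), seed=1)
        tr, va, _ = split_dataset(data, cfg.split, cfg.seed)
        losses = train(small_arch(), tr, va, cfg).history["train_loss"].to_numpy()
        drops = (np.diff(losses) <= 1e-9).mean()
        assert drops >= 0.8


class TestAblation:
    def test_singleton_grid_matches_direct_train(self, small_data):
        cfg = TrainConfig(epochs=1, split=(0.6, 0.2, 0.2), seed=6)
        tr, va, te = split_dataset(small_data, cfg.split, cfg.seed)
        table = run_ablation_grid(
            tr, va, te,
            {"initializers": ["glorot_normal"], "poolings": ["avg"], "optimizers": ["adam"]},
            cfg,
            build_arch=small_arch,
        )
        assert len(table) == 1
        direct = train(small_arch(), tr, va, cfg)
        assert table.iloc[0]["val_loss"] == pytest.approx(
            float(direct.history.iloc[-1]["val_loss"])
        )

    def test_grid_shape_and_columns(self, small_data):
        cfg = TrainConfig(epochs=1, split=(0.6, 0.2, 0.2), seed=8)
        tr, va, te = split_dataset(small_data, cfg.split, cfg.seed)
        table = run_ablation_grid(
            tr, va, te,
            {"optimizers": ["adam", "adamax"], "poolings": ["avg", "max"]},
            cfg,
            build_arch=small_arch,
        )
        assert len(table) == 4
        for col in ("val_loss", "val_accuracy", "val_f1", "test_loss", "test_accuracy", "test_f1"):
            assert table[col].notna().all()

    def test_empty_axis_rejected(self, small_data):
        cfg = TrainConfig(epochs=1)
        tr, va, te = split_dataset(small_data, (0.6, 0.2, 0.2), 0)
        with pytest.raises(ValueError, match="empty"):
            run_ablation_grid(tr, va, te, {"optimizers": []}, cfg, build_arch=small_arch)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(split=(0.5, 0.2, 0.2)), "sum to 1"),
            (dict(batch_size=0), "batch_size"),
            (dict(learning_rate=-0.1), "learning_rate"),
            (dict(resample="tomek"), "resample"),
        ],
    )
    def test_bad_configs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            TrainConfig(**kwargs)

    def test_replace_preserves_validation(self):
        cfg = TrainConfig()
        cfg2 = dataclasses.replace(cfg, optimizer="nadam")
        assert cfg2.optimizer == "nadam" and cfg2.learning_rate == cfg.learning_rate
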