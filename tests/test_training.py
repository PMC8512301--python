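"""Training orchestration: configs, phases, null-training, tiny overfit runs."""

from dataclasses import replace

import numpy as np
import pytest

from fuzzyoc import pipeline
from fuzzyoc.model import NORMAL, OVER, BackboneSpec, HeadConfig, build_model
from fuzzyoc.training import (
    FuzzyOverclustering,
    TrainConfig,
    TrainData,
    Trainer,
    downsample,
    preset,
    train_epoch,
    warmup,
)


def tiny_config(**kw):
    base = dict(
        warmup_epochs=2,
        heads_only_epochs=1,
        main_epochs=4,
        batch=pipeline.BatchSpec(batch_size=24, unlabeled_ratio=0.5, repetitions=3),
        overcluster_k=12,
        head_copies=2,
        backbone_channels=(4, 8, 16),
        seed=0,
    )
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def tiny_data(tiny_splits):
    train, val, unl = tiny_splits
    return TrainData.from_splits(train, val, unl, image_size=16)


def tiny_model(cfg):
    return build_model(
        BackboneSpec(
            name=cfg.backbone_name,
            channels=cfg.backbone_channels,
            image_size=cfg.image_size,
        ),
        [
            HeadConfig(NORMAL, 6, cfg.head_copies),
            HeadConfig(OVER, cfg.overcluster_k, cfg.head_copies),
        ],
        seed=cfg.seed,
    )


class TestTrainConfig:
    def test_variant_constraints(self):
        with pytest.raises(ValueError):
            TrainConfig(variant="foc-light", lambda_u=1.0, warmup_epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(variant="warmup-only", lambda_s=1.0)
        with pytest.raises(ValueError):
            TrainConfig(lambda_s=-1.0)

    def test_presets(self):
        light = preset("desk", "foc-light")
        assert light.lambda_u == 0 and light.warmup_epochs == 0
        assert light.batch.repetitions == 1
        warm = preset("desk", "warmup-only")
        assert warm.lambda_s == 0
        paper = preset("paper", "foc")
        assert (paper.warmup_epochs, paper.heads_only_epochs, paper.main_epochs) == (
            500, 100, 500,
        )
        assert paper.lr_main == pytest.approx(1e-4)
        assert paper.lr_heads_only == pytest.approx(1e-3)

    def test_yaml_roundtrip(self):
        cfg = preset("desk", "foc", seed=5)
        assert TrainConfig.from_yaml(cfg.to_yaml()) == cfg


class TestDownsample:
    def test_block_mean(self):
        img = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
        out = downsample(img, 2)
        np.testing.assert_allclose(out[0, :, :, 0], [[2.5, 4.5], [10.5, 12.5]])

    def test_requires_divisibility(self):
        with pytest.raises(ValueError):
            downsample(np.zeros((1, 10, 10, 3)), 4)


class TestNullTraining:
    def test_zero_weights_leave_parameters_bitwise_unchanged(self, tiny_data):
        cfg = tiny_config(lambda_s=0.0, lambda_u=0.0, variant="foc")
        net = tiny_model(cfg)
        before = [p["value"].copy() for p in net.all_params()]
        train_epoch(net, tiny_data, cfg, NORMAL)
        train_epoch(net, tiny_data, cfg, OVER)
        for saved, p in zip(before, net.all_params()):
            np.testing.assert_array_equal(saved, p["value"])


class TestWarmup:
    def test_warmup_trains_without_supervised_loss(self, tiny_data):
        cfg = tiny_config()
        net = tiny_model(cfg)
        t = Trainer(net, tiny_data, cfg)
        t.warmup()
        rows = [r for r in t.history if r["phase"] == "warmup"]
        assert len(rows) == cfg.warmup_epochs
        assert all(r["loss_sup"] == 0.0 for r in rows)
        assert all(r["loss_mi"] != 0.0 for r in rows)

    def test_zero_epochs_is_a_no_op(self, tiny_data):
        cfg = tiny_config(warmup_epochs=0)
        net = tiny_model(cfg)
        before = [p["value"].copy() for p in net.all_params()]
        warmup(net, tiny_data, cfg)
        for saved, p in zip(before, net.all_params()):
            np.testing.assert_array_equal(saved, p["value"])

    def test_foc_light_has_no_warmup(self, tiny_data):
        cfg = preset("desk", "foc-light")
        net = tiny_model(cfg)
        with pytest.raises(ValueError):
            warmup(net, tiny_data, cfg)

    def test_mi_loss_improves_on_average(self, tiny_data):
        cfg = tiny_config(warmup_epochs=6)
        net = tiny_model(cfg)
        t = Trainer(net, tiny_data, cfg)
        t.warmup()
        mi = [r["loss_mi"] for r in t.history]
        assert np.mean(mi[-2:]) < np.mean(mi[:2])


class TestPhases:
    def test_alternation_order(self, tiny_data):
        cfg = tiny_config(warmup_epochs=0, heads_only_epochs=0, main_epochs=4)
        foc = FuzzyOverclustering(tiny_data, cfg)
        res = foc.fit()
        main = res.history[res.history.phase == "full"]
        assert list(main.head_type) == [NORMAL, OVER, NORMAL, OVER]

    def test_phase_order(self, tiny_data):
        res = FuzzyOverclustering(tiny_data, tiny_config()).fit()
        phases = list(dict.fromkeys(res.history.phase))
        assert phases == ["warmup", "heads_only", "full"]

    def test_heads_only_phase_freezes_backbone(self, tiny_data):
        cfg = tiny_config(warmup_epochs=0, heads_only_epochs=2, main_epochs=0)
        net = tiny_model(cfg)
        t = Trainer(net, tiny_data, cfg)
        backbone_before = [p["value"].copy() for p in net.backbone.params()]
        heads_before = [p["value"].copy() for p in net.head_params()]
        t.finetune(track_best=False)
        for saved, p in zip(backbone_before, net.backbone.params()):
            np.testing.assert_array_equal(saved, p["value"])
        changed = any(
            not np.array_equal(saved, p["value"])
            for saved, p in zip(heads_before, net.head_params())
        )
        assert changed

    def test_reproducible_loss_trace(self, tiny_data):
        cfg = tiny_config(main_epochs=2, warmup_epochs=1, heads_only_epochs=0)
        r1 = FuzzyOverclustering(tiny_data, cfg).fit()
        r2 = FuzzyOverclustering(tiny_data, cfg).fit()
        np.testing.assert_array_equal(
            r1.history["loss"].to_numpy(), r2.history["loss"].to_numpy()
        )


class TestOverfit:
    def test_normal_head_overfits_a_tiny_certain_set(self, tiny_splits):
        """Training accuracy on 32 certain images reaches >= 0.95."""
        train, val, unl = tiny_splits
        data = TrainData.from_splits(train, val, unl, image_size=16)
        idx = np.arange(32)
        small = TrainData(
            labeled_images=data.labeled_images[idx],
            labels=data.labels[idx],
            unlabeled_images=data.unlabeled_images[:8],
            val_images=data.labeled_images[idx],
            val_labels=data.labels[idx],
            eval_images=data.labeled_images[idx],
            eval_labels=data.labels[idx],
            k_gt=6,
        )
        cfg = tiny_config(
            variant="foc-light",
            lambda_u=0.0,
            warmup_epochs=0,
            heads_only_epochs=0,
            main_epochs=400,
            batch=pipeline.BatchSpec(batch_size=16, unlabeled_ratio=0.0, repetitions=1),
            aspect_jitter=0.1,
        )
        res = FuzzyOverclustering(small, cfg).fit()
        preds = res.predict(small.labeled_images * 255.0, kind=NORMAL).argmax(1)
        assert np.mean(preds == small.labels) >= 0.95


class TestResults:
    def test_summary_and_scores_schema(self, tiny_data):
        res = FuzzyOverclustering(tiny_data, tiny_config()).fit()
        text = res.summary()
        assert "normal" in text and "overclustering" in text
        for kind in (NORMAL, OVER):
            assert len(res.head_scores[kind]["val_macro_f1"]) == 2
            assert 0 <= res.unlabeled_macro_f1[kind] <= 1
        assert 0 <= res.headline_macro_f1 <= 1
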