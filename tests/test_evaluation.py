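"""Evaluation batteries: determinism, sweeps, matched comparisons."""

import numpy as np
import pytest

from plastinet.degradations import DegradationSpec
from plastinet.evaluation import (
    EvalRecord,
    aggregate_seeds,
    blur_sweep,
    compare_matched,
    comparison_frame,
    evaluate,
    hue_sweep,
    timing_sweep,
)
from plastinet.imagesets import LabeledImageSet
from plastinet.network import build_model
from plastinet.schedules import make_lr_schedule, make_regimen
from plastinet.training import TrainConfig, train

NONE = DegradationSpec("none")


def _rec(regimen, schedule, seed, acc, condition="full"):
    cond = NONE if condition == "full" else DegradationSpec("grayscale")
    return EvalRecord(regimen, schedule, seed, cond, acc)


class TestEvaluate:
    def test_constant_output_model_is_at_chance(self, tiny_arch, tiny_sets):
        _, test_set = tiny_sets
        ckpt = build_model(tiny_arch, seed=0)
        for layer in ckpt.layers.values():
            layer["W"][:] = 0.0
        rec = evaluate(ckpt, test_set, NONE)
        assert rec.top1_accuracy == pytest.approx(1 / test_set.n_classes)

    def test_deterministic(self, tiny_arch, tiny_sets):
        _, test_set = tiny_sets
        ckpt = build_model(tiny_arch, seed=1)
        a = evaluate(ckpt, test_set, NONE).top1_accuracy
        b = evaluate(ckpt, test_set, NONE).top1_accuracy
        assert a == b

    def test_permutation_invariant(self, tiny_arch, tiny_sets):
        _, test_set = tiny_sets
        ckpt = build_model(tiny_arch, seed=1)
        perm = np.random.default_rng(0).permutation(len(test_set))
        shuffled = LabeledImageSet(
            images=[test_set.images[i] for i in perm],
            labels=[test_set.labels[i] for i in perm],
            split="test", n_classes=test_set.n_classes,
        )
        assert (
            evaluate(ckpt, test_set, NONE).top1_accuracy
            == evaluate(ckpt, shuffled, NONE).top1_accuracy
        )

    def test_memorizing_model_reaches_perfect_accuracy(self, tiny_arch):
        # a 10-image 2-class set trained to ~zero loss is a lookup table
        from plastinet.imagesets import SyntheticSetSpec, generate_dataset
        from plastinet.network import ArchConfig, ConvLayerSpec

        spec = SyntheticSetSpec(n_classes=2, train_per_class=5, test_per_class=1,
                                image_size=32, seed=4)
        train_set, test_set = generate_dataset(spec)
        arch = ArchConfig(
            conv_layers=(ConvLayerSpec(4, 3, 1, True), ConvLayerSpec(8, 3, 1, True)),
            fc_layers=(16,), n_classes=2, input_size=24,
        )
        cfg = TrainConfig(epochs=30, seed=2, batch_size=10, crop_size=24,
                          eval_each_epoch=False, checkpoint_every=30)
        run = train(arch, train_set, test_set, make_regimen("F2F", 30),
                    make_lr_schedule("const1", 30), cfg)
        assert run.per_epoch[-1]["train_loss"] < 0.01
        as_test = LabeledImageSet(
            images=train_set.images, labels=train_set.labels,
            split="test", n_classes=2,
        )
        rec = evaluate(run.final_checkpoint(), as_test, NONE)
        assert rec.top1_accuracy == 1.0

    def test_empty_test_set_rejected(self, tiny_arch, tiny_sets):
        ckpt = build_model(tiny_arch, seed=0)
        empty = LabeledImageSet.__new__(LabeledImageSet)
        empty.images, empty.labels = [], []
        empty.split, empty.n_classes = "test", 4
        with pytest.raises(ValueError):
            evaluate(ckpt, empty, NONE)


class TestSweeps:
    def test_blur_sweep_zero_sigma_equals_plain_evaluate(self, tiny_arch, tiny_sets):
        _, test_set = tiny_sets
        ckpt = build_model(tiny_arch, seed=3)
        records = blur_sweep(ckpt, test_set, sigmas=(0.0, 2.0))
        assert len(records) == 2
        assert records[0].top1_accuracy == evaluate(ckpt, test_set, NONE).top1_accuracy
        assert records[0].test_condition.kind == "none"

    def test_hue_sweep_closure(self, tiny_arch, tiny_sets):
        _, test_set = tiny_sets
        ckpt = build_model(tiny_arch, seed=3)
        records = hue_sweep(ckpt, test_set, angles=(0.0, 360.0, 90.0))
        assert records[0].top1_accuracy == records[1].top1_accuracy
        assert len(records) == 3

    def test_negative_sigma_rejected(self, tiny_arch, tiny_sets):
        _, test_set = tiny_sets
        ckpt = build_model(tiny_arch, seed=3)
        with pytest.raises(ValueError):
            blur_sweep(ckpt, test_set, sigmas=(-1.0,))


class TestAggregation:
    def test_mean_and_se_hand_example(self):
        records = [_rec("F2F", "const1", s, a) for s, a in zip((1, 2, 3), (0.4, 0.5, 0.6))]
        df = aggregate_seeds(records)
        row = df.iloc[0]
        assert row["mean_accuracy"] == pytest.approx(0.5)
        assert row["se"] == pytest.approx(0.1 / np.sqrt(3))

    def test_identical_values_zero_se(self):
        records = [_rec("F2F", "const1", s, 0.7) for s in (1, 2)]
        assert aggregate_seeds(records).iloc[0]["se"] == 0.0

    def test_single_seed_flagged(self):
        df = aggregate_seeds([_rec("F2F", "const1", 1, 0.7)])
        row = df.iloc[0]
        assert row["mean_accuracy"] == 0.7
        assert not row["se_defined"]
        assert np.isnan(row["se"])


class TestCompareMatched:
    def test_identical_arms_zero_delta(self):
        records = []
        for s in (1, 2, 3):
            records.append(_rec("D2F", "dec1", s, 0.5))
            records.append(_rec("D2F", "const1", s, 0.5))
        cells = compare_matched(records, "initial")
        assert len(cells) == 1
        assert cells[0].delta_accuracy == 0.0

    def test_hand_computed_delta_and_se(self):
        records = []
        for s, a in zip((1, 2, 3), (0.50, 0.52, 0.54)):
            records.append(_rec("D2F", "dec1", s, a))
            records.append(_rec("D2F", "const1", s, 0.50))
        cell = compare_matched(records, "initial")[0]
        deltas = np.array([0.0, 0.02, 0.04])
        assert cell.delta_accuracy == pytest.approx(0.02)
        assert cell.se == pytest.approx(np.std(deltas, ddof=1) / np.sqrt(3))
        assert cell.pair == ("dec1", "const1")

    def test_missing_pair_member_rejected(self):
        records = [
            _rec("D2F", "dec1", 1, 0.5),
            _rec("D2F", "dec1", 2, 0.5),
            _rec("D2F", "const1", 1, 0.5),
        ]
        with pytest.raises(ValueError, match="missing"):
            compare_matched(records, "initial")

    def test_frame_schema(self):
        records = [_rec("D2F", "dec1", 1, 0.6), _rec("D2F", "const1", 1, 0.5)]
        df = comparison_frame(compare_matched(records, "initial"))
        assert list(df.columns) == [
            "regimen", "decreasing", "constant", "condition", "delta_accuracy", "se",
        ]


class TestTimingSweep:
    def test_rows_and_boundaries(self, tiny_arch, tiny_sets):
        train_set, test_set = tiny_sets
        cfg = TrainConfig(epochs=4, seed=1, batch_size=16, crop_size=24,
                          eval_each_epoch=False, checkpoint_every=4)
        df = timing_sweep(tiny_arch, train_set, test_set, cfg,
                          switch_epochs=(1, 2, 3), degraded_kind="blur")
        assert len(df) == 3 * 2
        assert set(df["condition"]) == {"full", "degraded"}
        with pytest.raises(ValueError):
            timing_sweep(tiny_arch, train_set, test_set, cfg, switch_epochs=(4,))
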