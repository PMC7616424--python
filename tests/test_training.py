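"""Training loop, loss decomposition, grid search and the noise sweep."""

import numpy as np
import pandas as pd
import pytest

from calibrax import (
    METHODS,
    GeneratorSpec,
    ImageClassifier,
    TrainConfig,
    grid_search,
    noise_sweep,
)


def quick_cfg(**kw):
    base = dict(capacity="low", epochs=2, batch_size=64, seed=0, num_classes=4)
    base.update(kw)
    return TrainConfig(**base)


def test_methods_are_the_two_by_two_design():
    assert METHODS == {
        "baseline": ("softmax", False),
        "uvac": ("softmax", True),
        "enn": ("evidential", False),
        "enn_uvac": ("evidential", True),
    }
    for name in METHODS:
        assert TrainConfig.for_method(name).method == name


def test_config_protocol_defaults():
    cfg = TrainConfig()
    assert (cfg.learning_rate, cfg.epochs, cfg.batch_size) == (1e-3, 10, 128)
    long = TrainConfig.long_protocol()
    assert (long.learning_rate, long.epochs, long.batch_size) == (1e-3, 200, 16)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        TrainConfig(head="bayes")
    with pytest.raises(ValueError):
        TrainConfig(capacity="medium")
    with pytest.raises(ValueError):
        TrainConfig(avuc_weight=-0.5)


class TestFit:
    def test_zero_avuc_weight_reduces_to_baseline_trajectory(self, tiny_splits):
        """(softmax, beta=0) must be byte-for-byte plain cross-entropy."""
        tr, va, _ = tiny_splits
        base = ImageClassifier(tr, va, quick_cfg(head="softmax", use_avuc=False)).fit()
        off = ImageClassifier(
            tr, va, quick_cfg(head="softmax", use_avuc=True, avuc_weight=0.0)
        ).fit()
        pd.testing.assert_frame_equal(base.log, off.log)
        for pa, pb in zip(base.network.parameters(), off.network.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_zero_avuc_weight_reduces_to_pure_enn(self, tiny_splits):
        tr, va, _ = tiny_splits
        enn = ImageClassifier(tr, va, quick_cfg(head="evidential")).fit()
        off = ImageClassifier(
            tr, va, quick_cfg(head="evidential", use_avuc=True, avuc_weight=0.0)
        ).fit()
        pd.testing.assert_frame_equal(enn.log, off.log)

    def test_loss_decomposition(self, tiny_splits):
        """Logged total = base + beta * avuc at every epoch."""
        tr, va, _ = tiny_splits
        res = ImageClassifier(
            tr, va, quick_cfg(head="softmax", use_avuc=True, avuc_weight=2.0)
        ).fit()
        np.testing.assert_allclose(
            res.log["total_loss"],
            res.log["base_loss"] + 2.0 * res.log["avuc_loss"],
            atol=1e-6,
        )

    def test_evidential_kl_component_zero_at_epoch_zero(self, tiny_splits):
        tr, va, _ = tiny_splits
        res = ImageClassifier(
            tr, va, quick_cfg(head="evidential", enn_annealing_factor=10.0)
        ).fit()
        assert res.log.loc[0, "kl_component"] == 0.0
        assert res.log.loc[1, "kl_component"] > 0.0

    def test_fixed_seed_reproduces_final_metrics(self, tiny_splits):
        tr, va, te = tiny_splits
        a = ImageClassifier(tr, va, quick_cfg(seed=5)).fit()
        b = ImageClassifier(tr, va, quick_cfg(seed=5)).fit()
        assert a.evaluate(te) == b.evaluate(te)

    def test_separable_task_learned_quickly(self, tiny_splits):
        tr, va, te = tiny_splits
        res = ImageClassifier(tr, va, quick_cfg(epochs=5)).fit()
        assert res.evaluate(te)["accuracy"] >= 0.9

    def test_predictions_well_formed(self, tiny_splits):
        tr, va, te = tiny_splits
        for head in ("softmax", "evidential"):
            res = ImageClassifier(tr, va, quick_cfg(head=head)).fit()
            ps = res.predict(te)
            assert len(ps) == len(te)
            assert np.all((ps.confidence > 0) & (ps.confidence <= 1))
            assert np.all((ps.uncertainty >= 0) & (ps.uncertainty <= 1))

    def test_summary_mentions_method_and_capacity(self, tiny_splits):
        tr, va, _ = tiny_splits
        res = ImageClassifier(tr, va, quick_cfg()).fit()
        s = res.summary()
        assert "baseline" in s and "low" in s and "validation" in s

    def test_mismatched_num_classes_rejected(self, tiny_splits):
        tr, va, _ = tiny_splits
        with pytest.raises(ValueError, match="num_classes"):
            ImageClassifier(tr, va, quick_cfg(num_classes=7))


class TestGridSearch:
    def test_singleton_grids_return_that_point(self, tiny_splits):
        tr, va, _ = tiny_splits
        res = grid_search(quick_cfg(epochs=1), tr, va, [1.5], [20.0])
        assert (res.best_beta, res.best_factor) == (1.5, 20.0)
        assert len(res.table) == 1

    def test_stubbed_scorer_selects_argmax(self, tiny_splits):
        tr, va, _ = tiny_splits
        res = grid_search(
            quick_cfg(),
            tr,
            va,
            [0, 1, 2, 4],
            [0, 10, 30, 40],
            scorer=lambda b, f: 1.0 if (b, f) == (2, 30) else 0.5,
        )
        assert (res.best_beta, res.best_factor) == (2.0, 30.0)
        assert len(res.table) == 16

    def test_ties_break_toward_smaller_beta_then_factor(self, tiny_splits):
        tr, va, _ = tiny_splits
        res = grid_search(quick_cfg(), tr, va, [1, 2], [10, 20], scorer=lambda b, f: 0.9)
        assert (res.best_beta, res.best_factor) == (1.0, 10.0)

    @pytest.mark.parametrize("betas,factors", [([5.0], [10.0]), ([1.0], [50.0]), ([-1.0], [0.0])])
    def test_out_of_range_grid_rejected(self, tiny_splits, betas, factors):
        tr, va, _ = tiny_splits
        with pytest.raises(ValueError, match="range"):
            grid_search(quick_cfg(), tr, va, betas, factors)

    def test_empty_grid_rejected(self, tiny_splits):
        tr, va, _ = tiny_splits
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(quick_cfg(), tr, va, [], [10.0])


class TestNoiseSweep:
    SPEC = GeneratorSpec(
        num_classes=4, n_train=120, n_val=40, n_test=60, image_size=(16, 16)
    )

    def test_single_run_single_method(self):
        res = noise_sweep(
            ["baseline"], [0.0], 1, quick_cfg(epochs=1), self.SPEC, base_seed=1
        )
        assert len(res.records) == 1
        agg = res.aggregates()
        assert agg.loc[0, "accuracy_std"] == 0.0
        assert agg.loc[0, "n_runs"] == 1

    def test_rerun_reproduces_records(self):
        kw = dict(base_config=quick_cfg(epochs=1), generator_spec=self.SPEC, base_seed=3)
        a = noise_sweep(["baseline", "enn"], [0.0], 1, **kw)
        b = noise_sweep(["baseline", "enn"], [0.0], 1, **kw)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_records_schema_and_seed_discipline(self):
        res = noise_sweep(
            ["baseline"], [0.0, 1.0], 2, quick_cfg(epochs=1), self.SPEC, base_seed=10
        )
        assert list(res.records.columns) == ["method", "noise_std", "seed", "accuracy", "aece"]
        assert sorted(res.records["seed"].unique()) == [10, 11]

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            noise_sweep(["baseline"], [0.0], 0, quick_cfg(), self.SPEC)
        with pytest.raises(ValueError):
            noise_sweep(["baseline"], [-1.0], 1, quick_cfg(), self.SPEC)
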