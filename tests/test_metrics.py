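"""ECE / adaptive ECE against per-sample loop oracles, plus diagrams."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calibrax import (
    PredictionSet,
    accuracy,
    adaptive_ece,
    ece,
    reliability_diagram,
    report_from_table,
)


def random_prediction_set(rng, n):
    conf = rng.uniform(0.05, 1.0, n)
    pred = rng.integers(0, 3, n)
    true = np.where(rng.uniform(size=n) < conf, pred, (pred + 1) % 3)
    return PredictionSet(conf, pred, true)


def ece_loop_oracle(preds, num_bins):
    """Equal-width ECE computed sample by sample."""
    n = len(preds)
    total = 0.0
    for b in range(num_bins):
        lo, hi = b / num_bins, (b + 1) / num_bins
        sel = [i for i in range(n) if lo < preds.confidence[i] <= hi]
        if not sel:
            continue
        acc = np.mean([preds.correct[i] for i in sel])
        conf = np.mean([preds.confidence[i] for i in sel])
        total += len(sel) / n * abs(acc - conf)
    return total


def aece_loop_oracle(preds, num_bins):
    """Equal-mass AECE: stable sort then contiguous chunks differing by <=1."""
    n = len(preds)
    order = sorted(range(n), key=lambda i: preds.confidence[i])
    base, extra = divmod(n, num_bins)
    total, start = 0.0, 0
    for b in range(num_bins):
        size = base + (1 if b < extra else 0)
        chunk = order[start : start + size]
        start += size
        acc = np.mean([preds.correct[i] for i in chunk])
        conf = np.mean([preds.confidence[i] for i in chunk])
        total += size / n * abs(acc - conf)
    return total


class TestAccuracy:
    def test_all_correct(self):
        ps = PredictionSet([0.9] * 5, [1] * 5, [1] * 5)
        assert accuracy(ps) == 1.0

    def test_fraction(self):
        pred = np.zeros(100, dtype=int)
        true = np.zeros(100, dtype=int)
        true[62:] = 1
        assert accuracy(PredictionSet(np.full(100, 0.8), pred, true)) == 0.62


class TestEce:
    def test_perfect_confidence_zero_error(self):
        ps = PredictionSet([1.0] * 10, [0] * 10, [0] * 10)
        assert ece(ps, 15).scalar_error == 0.0

    def test_single_bin_hand_computation(self):
        ps = PredictionSet([0.9, 0.6], [0, 0], [0, 1])
        report = ece(ps, 1)
        assert report.scalar_error == pytest.approx(abs(0.5 - 0.75))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ps = random_prediction_set(rng, int(rng.integers(5, 1000)))
            for b in (1, 5, 15):
                assert ece(ps, b).scalar_error == pytest.approx(
                    ece_loop_oracle(ps, b), abs=1e-12
                )

    def test_empty_bins_contribute_zero(self):
        ps = PredictionSet([0.95] * 4, [0] * 4, [0, 0, 1, 1])
        report = ece(ps, 10)
        counts = [b.count for b in report.bins]
        assert sum(counts) == 4 and counts[9] == 4
        assert all(b.accuracy == 0.0 for b in report.bins[:9])

    def test_invalid_bins_rejected(self):
        ps = PredictionSet([0.5], [0], [0])
        with pytest.raises(ValueError):
            ece(ps, 0)


class TestAdaptiveEce:
    def test_constant_confidence_case(self):
        for b in (1, 3, 5):
            ps = PredictionSet([0.8] * 10, [0] * 10, [0] * 10)
            assert adaptive_ece(ps, b).scalar_error == pytest.approx(0.2)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ps = random_prediction_set(rng, int(rng.integers(20, 1000)))
            for b in (1, 5, 15):
                assert adaptive_ece(ps, b).scalar_error == pytest.approx(
                    aece_loop_oracle(ps, b), abs=1e-12
                )

    def test_equal_mass_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(2)
        ps = random_prediction_set(rng, 103)
        report = adaptive_ece(ps, 15)
        counts = [b.count for b in report.bins]
        assert sum(counts) == 103
        assert set(counts) <= {103 // 15, 103 // 15 + 1}

    def test_single_bin_equals_accuracy_confidence_gap(self):
        rng = np.random.default_rng(3)
        ps = random_prediction_set(rng, 257)
        gap = abs(accuracy(ps) - ps.confidence.mean())
        assert adaptive_ece(ps, 1).scalar_error == pytest.approx(gap, abs=1e-15)

    def test_calibrated_generator_converges(self):
        """Confidence-matched correctness: AECE shrinks roughly as n^-1/2."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            small = _calibrated(rng, 1_000)
            large = _calibrated(rng, 100_000)
            if adaptive_ece(small, 15).scalar_error > adaptive_ece(large, 15).scalar_error:
                hits += 1
        assert hits >= 4

    def test_too_few_samples_advises_smaller_bins(self):
        ps = PredictionSet([0.5, 0.6], [0, 0], [0, 0])
        with pytest.raises(ValueError, match="fewer bins"):
            adaptive_ece(ps, 5)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 99999), b=st.sampled_from([1, 5, 15]))
    def test_permutation_invariant_and_bounded(self, seed, b):
        rng = np.random.default_rng(seed)
        ps = random_prediction_set(rng, 60)
        err = adaptive_ece(ps, b).scalar_error
        assert 0.0 <= err <= 1.0
        perm = rng.permutation(60)
        ps2 = PredictionSet(ps.confidence[perm], ps.predicted_label[perm], ps.true_label[perm])
        assert adaptive_ece(ps2, b).scalar_error == pytest.approx(err, abs=1e-12)


def _calibrated(rng, n):
    conf = rng.uniform(0.5, 1.0, n)
    correct = rng.uniform(size=n) < conf
    pred = np.zeros(n, dtype=int)
    true = np.where(correct, 0, 1)
    return PredictionSet(conf, pred, true)


class TestReliabilityDiagram:
    def test_writes_figure_and_lossless_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        ps = random_prediction_set(rng, 300)
        report = adaptive_ece(ps, 10)
        png, csv_path = reliability_diagram(report, tmp_path / "rel.png")
        assert png.exists() and csv_path.exists()
        back = report_from_table(pd.read_csv(csv_path), scheme="equal-mass")
        assert back.scalar_error == pytest.approx(report.scalar_error, abs=1e-12)

    def test_nearly_calibrated_bars_lie_on_diagonal(self, tmp_path):
        ps = _calibrated(np.random.default_rng(5), 100_000)
        report = adaptive_ece(ps, 15)
        for b in report.bins:
            assert abs(b.accuracy - b.mean_confidence) < 0.05

    def test_empty_equal_width_bin_round_trips_with_zero_count(self, tmp_path):
        ps = PredictionSet([0.95] * 6, [0] * 6, [0] * 6)
        report = ece(ps, 10)
        _, csv_path = reliability_diagram(report, tmp_path / "r.png")
        df = pd.read_csv(csv_path)
        assert (df["count"] == 0).sum() == 9
        back = report_from_table(df, scheme="equal-width")
        assert back.scalar_error == pytest.approx(report.scalar_error, abs=1e-12)


def test_prediction_set_validation():
    with pytest.raises(ValueError):
        PredictionSet([], [], [])
    with pytest.raises(ValueError):
        PredictionSet([1.2], [0], [0])
    with pytest.raises(ValueError):
        PredictionSet([0.5, 0.5], [0], [0, 1])
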