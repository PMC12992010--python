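"""Losses against hand-computed fixtures; metrics against independent oracles."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import f1_score as sk_f1
from sklearn.metrics import roc_auc_score

from mganet.autograd import Tensor
from mganet.config import LossConfig
from mganet.losses_metrics import (MetricsReport, auc_score, bce_loss,
                                   confusion_percent, cross_entropy,
                                   dice_loss, f1_score, run_ci, seg_loss,
                                   total_loss)

LN2 = np.log(2.0)


class TestCrossEntropy:
    def test_confident_correct_is_near_zero(self):
        assert cross_entropy(Tensor(np.array([[20.0, -20.0]])), [0]).item() < 1e-8

    def test_uniform_logits_give_ln2(self):
        for label in (0, 1):
            loss = cross_entropy(Tensor(np.array([[0.0, 0.0]])), [label])
            assert abs(loss.item() - LN2) < 1e-12

    def test_hand_computed_softmax_value(self):
        loss = cross_entropy(Tensor(np.array([[1.0, -1.0]])), [0])
        expect = -np.log(np.e / (np.e + np.e ** -1))
        assert abs(loss.item() - expect) < 1e-12
        assert abs(expect - 0.1269) < 1e-4

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(Tensor(np.array([[0.0, 0.0]])), [2])


class TestBCE:
    def test_perfect_binary_prediction_bounded_by_clamp(self):
        mask = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert bce_loss(Tensor(mask.copy()), mask).item() < 1e-6

    def test_half_probability_gives_ln2_regardless_of_mask(self):
        for mask in (np.zeros((3, 3)), np.ones((3, 3))):
            loss = bce_loss(Tensor(np.full((3, 3), 0.5)), mask)
            assert abs(loss.item() - LN2) < 1e-12

    def test_hand_summed_two_by_two(self):
        mask = np.array([[1.0, 0.0], [0.0, 0.0]])
        prob = np.array([[0.8, 0.2], [0.2, 0.2]])
        # every pixel contributes -ln 0.8
        assert abs(bce_loss(Tensor(prob), mask).item() + np.log(0.8)) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(Tensor(np.zeros((2, 2))), np.zeros((3, 3)))

    def test_gradient_finite_at_probability_extremes(self):
        p = Tensor(np.array([[0.0, 1.0], [0.5, 1.0]]), requires_grad=True)
        bce_loss(p, np.array([[0.0, 1.0], [1.0, 0.0]])).backward()
        assert np.isfinite(p.grad).all()


class TestDice:
    def test_perfect_overlap_is_zero(self):
        mask = np.zeros((6, 6))
        mask[2:5, 2:5] = 1.0
        assert dice_loss(Tensor(mask.copy()), mask, 1.0).item() == pytest.approx(0.0)

    def test_zero_overlap_approaches_one(self):
        mask = np.zeros((6, 6))
        mask[0:3, 0:3] = 1.0  # S = 9
        loss = dice_loss(Tensor(np.zeros((6, 6))), mask, 1e-6)
        assert loss.item() == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_partial_overlap(self):
        mask = np.zeros((4, 4))
        mask[0, :] = 1.0  # 4 ones
        prob = np.where(mask == 1.0, 0.5, 0.0)
        loss = dice_loss(Tensor(prob), mask, 1e-9)
        assert loss.item() == pytest.approx(1.0 / 3.0, abs=1e-8)

    def test_batched_mean_over_images(self):
        mask = np.zeros((2, 1, 4, 4))
        mask[0, 0, 0, :] = 1.0
        mask[1] = 0.0
        prob = np.where(mask == 1.0, 0.5, 0.0)
        prob[1] = 0.0
        # image 0 contributes 1/3 (eps -> 0), image 1 contributes 0 (eps cancels)
        loss = dice_loss(Tensor(prob), mask, 1e-9)
        assert loss.item() == pytest.approx(1.0 / 6.0, abs=1e-6)

    def test_gradient_finite_everywhere_on_unit_interval(self):
        p = Tensor(np.array([[0.0, 0.5], [1.0, 0.2]]), requires_grad=True)
        dice_loss(p, np.array([[1.0, 0.0], [1.0, 1.0]]), 1.0).backward()
        assert np.isfinite(p.grad).all()


class TestComposite:
    def _fixtures(self):
        mask = np.array([[1.0, 0.0], [0.0, 0.0]])
        prob = np.array([[0.8, 0.2], [0.2, 0.2]])
        return prob, mask

    def test_alpha_endpoints(self):
        prob, mask = self._fixtures()
        bce = seg_loss(Tensor(prob), mask, LossConfig(alpha=1.0)).item()
        dice = seg_loss(Tensor(prob), mask, LossConfig(alpha=0.0, eps_dice=1e-9)).item()
        assert bce == pytest.approx(bce_loss(Tensor(prob), mask).item())
        assert dice == pytest.approx(dice_loss(Tensor(prob), mask, 1e-9).item())

    def test_alpha_half_is_arithmetic_mean(self):
        prob, mask = self._fixtures()
        cfg = LossConfig(alpha=0.5, eps_dice=1e-9)
        both = seg_loss(Tensor(prob), mask, cfg).item()
        mean = 0.5 * (bce_loss(Tensor(prob), mask).item()
                      + dice_loss(Tensor(prob), mask, 1e-9).item())
        assert both == pytest.approx(mean, abs=1e-12)

    def test_total_loss_is_commutative_sum(self):
        assert total_loss(Tensor(0.0), Tensor(0.0)).item() == 0.0
        assert total_loss(Tensor(0.3), Tensor(0.2)).item() == pytest.approx(0.5)
        assert total_loss(Tensor(0.3), Tensor(0.2)).item() == \
            total_loss(Tensor(0.2), Tensor(0.3)).item()


class TestF1:
    def test_limits(self):
        assert f1_score(10, 0, 0) == 1.0
        assert f1_score(0, 3, 4) == 0.0

    def test_harmonic_mean_of_precision_and_recall(self):
        tp, fp, fn = 50, 10, 10
        f1 = f1_score(tp, fp, fn)
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert f1 == pytest.approx(2 * precision * recall / (precision + recall))
        assert f1 == pytest.approx(100 / 120)

    def test_undefined_f1_raises(self):
        with pytest.raises(ValueError):
            f1_score(0, 0, 0)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            tp = int(np.sum((y == 1) & (p == 1)))
            fp = int(np.sum((y == 0) & (p == 1)))
            fn = int(np.sum((y == 1) & (p == 0)))
            if 2 * tp + fp + fn == 0:
                continue
            assert abs(f1_score(tp, fp, fn) - sk_f1(y, p, zero_division=0)) < 1e-10


class TestAUC:
    def test_perfect_separation_and_pure_ties(self):
        assert auc_score([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert auc_score([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_exhaustive_pairwise_oracle(self):
        pos, neg = [0.9, 0.4], [0.5, 0.3]
        wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
                   for p in pos for n in neg)
        assert auc_score(pos, neg) == pytest.approx(wins / 4)
        assert auc_score(pos, neg) == pytest.approx(0.75)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([], [0.1])

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y = np.concatenate([np.ones(10), np.zeros(15)]).astype(int)
            s = np.round(rng.random(25), 2)  # rounding forces ties
            assert abs(auc_score(s[y == 1], s[y == 0])
                       - roc_auc_score(y, s)) < 1e-10


class TestRunCI:
    def test_identical_values_zero_width(self):
        mean, lo, hi = run_ci([0.8, 0.8, 0.8])
        assert mean == pytest.approx(0.8)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_two_run_interval_from_t_table(self):
        mean, lo, hi = run_ci([0.8, 0.9])
        sd = np.std([0.8, 0.9], ddof=1)
        half = 12.7062 * sd / np.sqrt(2)
        assert mean == pytest.approx(0.85)
        assert hi - mean == pytest.approx(half, abs=1e-4)
        assert abs(half - 0.6353) < 1e-3

    def test_coverage_at_n5(self):
        rng = np.random.default_rng(2)
        covered = 0
        for _ in range(1000):
            v = rng.normal(0.0, 1.0, 5)
            _, lo, hi = run_ci(v)
            covered += lo <= 0.0 <= hi
        assert covered >= 930

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            run_ci([0.5])


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        out = confusion_percent([0, 0, 1, 1], [0, 0, 1, 1])
        np.testing.assert_allclose(np.diag(out), [100.0, 100.0])

    def test_hand_counted_rows(self):
        out = confusion_percent([0, 0, 1, 1], [0, 1, 1, 1])
        np.testing.assert_allclose(out, [[50.0, 50.0], [0.0, 100.0]])

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(3)
        out = confusion_percent(rng.integers(0, 2, 40), rng.integers(0, 2, 40))
        np.testing.assert_allclose(out.sum(axis=1), [100.0, 100.0])

    def test_absent_class_row_is_undefined(self):
        out = confusion_percent([1, 1], [0, 1])
        assert np.isnan(out[0]).all() and not np.isnan(out[1]).any()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_percent([], [])


def test_metrics_report_aggregates_and_serialises(tmp_path):
    runs = [{"accuracy": 0.9, "auc": 0.95, "f1": 0.88,
             "confusion_percent": np.array([[90.0, 10.0], [10.0, 90.0]])},
            {"accuracy": 0.8, "auc": 0.90, "f1": 0.84,
             "confusion_percent": np.array([[80.0, 20.0], [20.0, 80.0]])}]
    report = MetricsReport.from_runs(runs)
    assert report.n_runs == 2
    assert report.accuracy[0] == pytest.approx(0.85)
    assert report.accuracy[1] <= report.accuracy[0] <= report.accuracy[2]
    text = report.to_json(tmp_path / "report.json")
    assert (tmp_path / "report.json").read_text() == text
    assert '"n_runs": 2' in text
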