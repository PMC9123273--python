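import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokekit.imageio import SegMap
from strokekit.metrics import (ConfusionCounts, RankedPredictions, auprc,
                               auroc, confusion_counts, dice, iou,
                               lesion_volume_ml, pixel_accuracy,
                               segmentation_report, youden_threshold)


def _mask(data):
    return SegMap(np.asarray(data, dtype=np.uint8), (1.0, 1.0, 1.0),
                  np.eye(4))


def _pair(n_overlap, n_pred_only, n_truth_only, size=64):
    pred = np.zeros(size, dtype=np.uint8)
    truth = np.zeros(size, dtype=np.uint8)
    pred[:n_overlap + n_pred_only] = 1
    truth[:n_overlap] = 1
    truth[n_overlap + n_pred_only:n_overlap + n_pred_only + n_truth_only] = 1
    return (_mask(pred.reshape(4, 4, -1)), _mask(truth.reshape(4, 4, -1)))


class TestOverlapMetrics:
    def test_hand_computed_example(self):
        pred, truth = _pair(6, 2, 4)
        assert dice(pred, truth) == pytest.approx(12 / 18)
        assert iou(pred, truth) == pytest.approx(6 / 12)

    @given(st.integers(1, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_dice_iou_identity(self, n_ov, n_p, n_t):
        # Dice = 2*IoU/(1+IoU) for any pair of masks
        pred, truth = _pair(n_ov, n_p, n_t)
        d, j = dice(pred, truth), iou(pred, truth)
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_both_empty_raises(self):
        pred, truth = _pair(0, 0, 0)
        with pytest.raises(ValueError):
            dice(pred, truth)
        with pytest.raises(ValueError):
            iou(pred, truth)

    def test_grid_mismatch_raises(self):
        a = _mask(np.zeros((4, 4, 4)))
        b = SegMap(np.zeros((4, 4, 4), dtype=np.uint8), (2.0, 1.0, 1.0),
                   np.diag([2.0, 1, 1, 1]))
        with pytest.raises(ValueError, match="grid"):
            dice(a, b)

    def test_confusion_partitions_grid(self):
        pred, truth = _pair(5, 3, 2)
        c = confusion_counts(pred, truth)
        assert c.total == pred.data.size
        assert (c.TP, c.FP, c.FN) == (5, 3, 2)
        assert pixel_accuracy(c) == pytest.approx((c.TP + c.TN) / c.total)


class TestRankingMetrics:
    def test_auroc_matches_pairwise_concordance(self, rng):
        scores = rng.uniform(size=30)
        labels = (rng.uniform(size=30) > 0.6).astype(int)
        if labels.sum() in (0, len(labels)):
            labels[0], labels[1] = 0, 1
        preds = RankedPredictions(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0)
                        for p in pos for n in neg])
        assert auroc(preds) == pytest.approx(conc, abs=1e-12)

    def test_perfect_and_inverted(self):
        p = RankedPredictions([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auroc(p) == 1.0
        q = RankedPredictions([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert auroc(q) == 0.0

    def test_auprc_perfect(self):
        p = RankedPredictions([0.1, 0.9], [0, 1])
        assert auprc(p) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc(RankedPredictions([0.5, 0.6], [1, 1]))

    def test_nonbinary_labels_raise(self):
        with pytest.raises(ValueError):
            RankedPredictions([0.5, 0.6], [1, 2])


class TestYouden:
    def test_separable_case(self):
        preds = RankedPredictions([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
        thr, j = youden_threshold(preds)
        assert thr == pytest.approx(0.7)
        assert j == pytest.approx(1.0)

    def test_threshold_is_a_score_and_ge_rule(self):
        preds = RankedPredictions([0.3, 0.5, 0.5, 0.8], [0, 1, 0, 1])
        thr, _ = youden_threshold(preds)
        assert thr in preds.scores
        called = preds.scores >= thr
        assert called.dtype == bool

    def test_tie_resolves_to_smallest_threshold(self):
        # J identical at thresholds 0.4 and 0.8; the smaller must win
        preds = RankedPredictions([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
        thr, _ = youden_threshold(preds)
        assert thr == pytest.approx(0.4)

    def test_exhaustive_against_bruteforce(self, rng):
        scores = np.round(rng.uniform(size=25), 2)
        labels = (rng.uniform(size=25) > 0.5).astype(int)
        labels[:2] = [0, 1]
        preds = RankedPredictions(scores, labels)
        thr, j = youden_threshold(preds)
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        js = {}
        for cand in np.unique(scores):
            called = scores >= cand
            sens = (called & (labels == 1)).sum() / n_pos
            spec = (~called & (labels == 0)).sum() / n_neg
            js[cand] = sens + spec - 1
        assert j == pytest.approx(max(js.values()))
        assert js[thr] == pytest.approx(j)


class TestVolume:
    def test_worked_example(self):
        assert lesion_volume_ml(769, (0.57, 0.57, 7.0)) == 1.75

    def test_zero(self):
        assert lesion_volume_ml(0, (1, 1, 1)) == 0.0

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            lesion_volume_ml(-1, (1, 1, 1))


class TestReport:
    def test_macro_average_row(self, tmp_path):
        rows = [{"patient_id": "a", "dice": 0.8, "iou": 0.7},
                {"patient_id": "b", "dice": 0.6, "iou": 0.5}]
        df = segmentation_report(rows, out_tsv=tmp_path / "r.tsv",
                                 out_json=tmp_path / "r.json")
        macro = df[df.patient_id == "MACRO_AVERAGE"].iloc[0]
        assert macro.dice == pytest.approx(0.7)
        assert (tmp_path / "r.tsv").exists()
        assert (tmp_path / "r.json").exists()
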