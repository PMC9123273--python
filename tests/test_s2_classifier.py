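import dataclasses

import numpy as np
import pytest

from strokekit.imageio import DwiVolume, SegMap
from strokekit.s2_classifier import (ClassPrediction, S2Config, load_s2,
                                     make_s2_input, predict_class, save_s2,
                                     train_one_stage, train_s2)


@pytest.fixture(scope="module")
def tiny_config():
    return S2Config(epochs=2, seed=0)


@pytest.fixture(scope="module")
def trained_size(cohort16_norm, tiny_config):
    gt = [c.truth_mask for c in cohort16_norm]
    return train_s2(list(cohort16_norm), gt, "size", tiny_config)


class TestConfig:
    def test_invalid_values(self):
        with pytest.raises(ValueError):
            S2Config(backbone="resnet50")
        with pytest.raises(ValueError):
            S2Config(input_mode="volume")
        with pytest.raises(ValueError):
            S2Config(task="age")
        with pytest.raises(ValueError):
            S2Config(epochs=0)


class TestMakeInput:
    def _vol_mask(self, vol_data, mask_data):
        vol = DwiVolume(np.asarray(vol_data, dtype=float), (1, 1, 7),
                        np.eye(4))
        msk = SegMap(np.asarray(mask_data, dtype=np.uint8), (1, 1, 7),
                     np.eye(4))
        return vol, msk

    def test_elementwise_product_oracle(self):
        vol_data = np.arange(9, dtype=float).reshape(3, 3, 1)
        mask_data = (np.arange(9).reshape(3, 3, 1) % 2).astype(np.uint8)
        vol, msk = self._vol_mask(vol_data, mask_data)
        out = make_s2_input(vol, msk, "masked_dwi")
        np.testing.assert_array_equal(out[0], vol_data * mask_data)

    def test_all_zero_mask(self):
        vol, msk = self._vol_mask(np.ones((3, 3, 1)), np.zeros((3, 3, 1)))
        assert make_s2_input(vol, msk, "masked_dwi").sum() == 0

    def test_all_one_mask_identity(self):
        vol, msk = self._vol_mask(np.random.default_rng(0).normal(
            size=(3, 3, 1)), np.ones((3, 3, 1)))
        np.testing.assert_array_equal(
            make_s2_input(vol, msk, "masked_dwi")[0], vol.data)

    def test_two_channel(self):
        vol, msk = self._vol_mask(np.ones((3, 3, 1)), np.ones((3, 3, 1)))
        out = make_s2_input(vol, msk, "two_channel")
        assert out.shape == (2, 3, 3, 1)

    def test_grid_mismatch(self):
        vol, _ = self._vol_mask(np.ones((3, 3, 1)), np.ones((3, 3, 1)))
        _, msk = self._vol_mask(np.ones((4, 4, 1)), np.ones((4, 4, 1)))
        with pytest.raises(ValueError, match="mismatch"):
            make_s2_input(vol, msk, "masked_dwi")


class TestTraining:
    def test_validation_outputs(self, trained_size):
        assert trained_size.trained
        assert trained_size.val_probs.shape == trained_size.val_labels.shape
        assert np.all((trained_size.val_probs >= 0)
                      & (trained_size.val_probs <= 1))
        # one history per ensemble member, one record per epoch
        assert len(trained_size.history) == trained_size.config.n_ensemble
        assert len(trained_size.history[0]) == trained_size.config.epochs

    def test_determinism(self, cohort16_norm, tiny_config):
        gt = [c.truth_mask for c in cohort16_norm]
        a = train_s2(list(cohort16_norm), gt, "size", tiny_config)
        b = train_s2(list(cohort16_norm), gt, "size", tiny_config)
        np.testing.assert_array_equal(a.val_probs, b.val_probs)
        assert a.threshold == b.threshold

    def test_single_class_raises(self, cohort16_norm, tiny_config):
        lacunes = [c for c in cohort16_norm if c.size_label == "lacune"]
        gt = [c.truth_mask for c in lacunes]
        with pytest.raises(ValueError, match="class"):
            train_s2(lacunes, gt, "size", tiny_config)

    def test_both_territory_excluded_and_logged(self, phantom_config, atlas,
                                                tiny_config):
        import dataclasses as dc

        from strokekit import simulate_cohort, zscore_normalize

        cases = simulate_cohort(16, phantom_config, atlas, seed=21,
                                both_fraction=0.25)
        cases = [dc.replace(c, volume=zscore_normalize(c.volume))
                 for c in cases]
        gt = [c.truth_mask for c in cases]
        clf = train_s2(cases, gt, "territory", tiny_config)
        assert clf.n_excluded_both == 4

    def test_one_stage_trains(self, cohort16_norm, tiny_config):
        clf = train_one_stage(list(cohort16_norm), "size", tiny_config)
        assert clf.trained and not clf.two_stage


class TestPrediction:
    def test_untrained_raises(self, cohort16_norm, tiny_config):
        from strokekit.s2_classifier import Net3D, TrainedS2

        cfg = tiny_config
        net = Net3D(cfg, 1, (32, 32, 8))
        clf = TrainedS2(models=[net], config=cfg, two_stage=True,
                        input_shape=(32, 32, 8), in_channels=1)
        with pytest.raises(ValueError, match="untrained"):
            predict_class(clf, cohort16_norm[0].volume,
                          cohort16_norm[0].truth_mask)

    def test_prediction_fields(self, trained_size, cohort16_norm):
        case = cohort16_norm[0]
        pred = predict_class(trained_size, case.volume, case.truth_mask)
        assert isinstance(pred, ClassPrediction)
        assert 0.0 <= pred.probability <= 1.0
        assert pred.predicted_class in ("lacune", "non_lacune")
        assert pred.threshold_used == trained_size.threshold

    def test_threshold_tie_is_positive(self):
        p = ClassPrediction("x", 0.5, "non_lacune", 0.5)
        assert p.probability >= p.threshold_used

    def test_ge_rule(self, trained_size, cohort16_norm):
        case = cohort16_norm[0]
        pred = predict_class(trained_size, case.volume, case.truth_mask)
        expect = ("non_lacune" if pred.probability >= trained_size.threshold
                  else "lacune")
        assert pred.predicted_class == expect

    def test_missing_segmap_raises(self, trained_size, cohort16_norm):
        with pytest.raises(ValueError, match="SegMap"):
            predict_class(trained_size, cohort16_norm[0].volume, None)

    def test_grid_mismatch_raises(self, trained_size):
        vol = DwiVolume(np.zeros((16, 16, 8)), (1, 1, 7), np.eye(4))
        seg = SegMap(np.zeros((16, 16, 8), dtype=np.uint8), (1, 1, 7),
                     np.eye(4))
        with pytest.raises(ValueError, match="grid"):
            predict_class(trained_size, vol, seg)


class TestCheckpoint:
    def test_round_trip(self, trained_size, cohort16_norm, tmp_path):
        path = tmp_path / "s2.npz"
        save_s2(trained_size, path)
        back = load_s2(path)
        case = cohort16_norm[1]
        a = predict_class(trained_size, case.volume, case.truth_mask)
        b = predict_class(back, case.volume, case.truth_mask)
        assert a == b
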