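"""Patch extraction, residual classifiers, confidence filtering, evaluation."""

import numpy as np
import pytest

from semiq import classification as cls
from semiq.types import CELL_TYPES, CellType, ChannelStack, LabelMask
from conftest import make_nucleus


@pytest.fixture()
def small_stack():
    rng = np.random.default_rng(0)
    arr = rng.random((200, 200)).astype(np.float32)
    return ChannelStack(
        {
            "hoechst": arr,
            "acta2": rng.random((200, 200)).astype(np.float32),
            "acrv1": rng.random((200, 200)).astype(np.float32),
        }
    )


class TestCellPatch:
    def test_interior_crop_no_padding(self, small_stack):
        p = cls.extract_cell_patch(small_stack, (100, 100), 64)
        assert p.shape == (64, 64)
        assert (p > 0).all()  # random positive image: no zero padding present

    def test_corner_centroid_zero_padded(self, small_stack):
        p = cls.extract_cell_patch(small_stack, (1, 1), 64)
        # window starts 31 px above/left of the image: zero margin
        assert np.all(p[:31, :] == 0) and np.all(p[:, :31] == 0)
        assert p[31, 31] == pytest.approx(
            small_stack["hoechst"][0, 0] / small_stack["hoechst"].max()
        )

    def test_values_scaled_to_unit_interval(self, small_stack):
        for c in [(5, 5), (100, 100), (199, 199)]:
            p = cls.extract_cell_patch(small_stack, c, 64)
            assert p.shape == (64, 64)
            assert 0 <= p.min() and p.max() <= 1.0

    def test_centroid_outside_image_rejected(self, small_stack):
        with pytest.raises(ValueError):
            cls.extract_cell_patch(small_stack, (250, 50), 64)


class TestTubulePatch:
    def test_no_classified_cells_gives_zero_prob_channels(self, small_stack):
        pm = np.zeros((7, 200, 200), np.float32)
        p = cls.extract_tubule_patch(small_stack, pm, (100, 100), crop_px=64, out_px=32)
        assert p.shape == (10, 32, 32)
        assert np.all(p[3:] == 0)

    def test_footprint_carries_class_probability(self, small_stack):
        labels = np.zeros((200, 200), np.int32)
        labels[95:105, 95:105] = 1
        rec = make_nucleus(id=1, probs=[0, 0, 0.6, 0, 0.4, 0, 0], centroid=(100, 100))
        pm = cls.render_cell_prob_map(LabelMask(labels, "nucleus"), [rec])
        assert pm[int(CellType.SPC), 100, 100] == pytest.approx(0.6)
        assert pm[int(CellType.RSPD), 100, 100] == pytest.approx(0.4)
        # survives crop + area-average downsampling proportionally
        p = cls.extract_tubule_patch(small_stack, pm, (100, 100), crop_px=64, out_px=32)
        assert p[3 + int(CellType.SPC)].max() == pytest.approx(0.6)

    def test_border_tubule_zero_padded_quadrant(self, small_stack):
        pm = np.zeros((7, 200, 200), np.float32)
        p = cls.extract_tubule_patch(small_stack, pm, (10, 10), crop_px=128, out_px=64)
        # window extends 64 px up/left of (10,10): top-left is padding
        assert np.all(p[0, :26, :] == 0) and np.all(p[0, :, :26] == 0)
        assert p[0, 30:, 30:].max() > 0

    def test_missing_channel_rejected(self):
        stack = ChannelStack({"hoechst": np.ones((50, 50))})
        with pytest.raises(ValueError, match="acta2"):
            cls.extract_tubule_patch(
                stack, np.zeros((7, 50, 50)), (25, 25), crop_px=20, out_px=10
            )


class TestModelContracts:
    def test_output_dimension_matches_task(self):
        cell = cls.build_classifier(
            cls.ClassifierSpec.for_cells(backbone_depth=18, base_width=4)
        )
        out = cell.predict_proba(np.random.default_rng(0).random((2, 1, 64, 64)))
        assert out.shape == (2, 7)
        tub = cls.build_classifier(
            cls.ClassifierSpec.for_tubules(
                backbone_depth=18, base_width=4, input_size_px=50
            )
        )
        out = tub.predict_proba(np.random.default_rng(0).random((2, 10, 50, 50)))
        assert out.shape == (2, 12)

    def test_softmax_head_row_stochastic(self):
        spec = cls.ClassifierSpec.for_cells(backbone_depth=18, base_width=4)
        model = cls.build_classifier(spec)
        probs, calls, conf = cls.classify(
            model, np.random.default_rng(1).random((5, 1, 64, 64)), spec
        )
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()
        np.testing.assert_array_equal(calls, probs.argmax(axis=1))
        np.testing.assert_allclose(conf, probs.max(axis=1))

    def test_unsupported_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            cls.build_classifier(
                cls.ClassifierSpec.for_cells(backbone_depth=34, base_width=4)
            )

    def test_zero_patches_give_empty_outputs(self):
        spec = cls.ClassifierSpec.for_cells(backbone_depth=18, base_width=4)
        model = cls.build_classifier(spec)
        probs, calls, conf = cls.classify(model, np.zeros((0, 1, 64, 64)), spec)
        assert probs.shape == (0, 7) and len(calls) == 0 and len(conf) == 0


class TestTraining:
    def _spec(self, epochs=5, seed=0):
        return cls.ClassifierSpec.for_cells(
            backbone_depth=18, base_width=4, epochs=epochs, seed=seed,
            input_size_px=32, batch_size=16, learn_rate=3e-3,
        )

    def test_separable_fixture_learned(self, separable_patches):
        xt, yt, xh, yh = separable_patches
        spec = self._spec()
        model = cls.build_classifier(spec)
        model, log = cls.train_classifier(model, xt, yt, spec, allow_missing_class=True)
        assert log[-1]["train_accuracy"] >= 0.95 or log[-1].get("val_accuracy", 0) >= 0.95
        probs, calls, _ = cls.classify(model, xh, spec)
        assert (calls == yh).mean() >= 0.9

    def test_same_seed_reproduces_training(self, separable_patches):
        xt, yt, _, _ = separable_patches
        accs = []
        for _ in range(2):
            spec = self._spec()
            model = cls.build_classifier(spec)
            _, log = cls.train_classifier(model, xt, yt, spec, allow_missing_class=True)
            accs.append(log[-1]["train_accuracy"])
        assert abs(accs[0] - accs[1]) <= 0.02

    def test_empty_dataset_rejected(self):
        spec = self._spec()
        with pytest.raises(ValueError):
            cls.train_classifier(
                cls.build_classifier(spec), np.zeros((0, 1, 32, 32)), np.zeros(0, int), spec
            )

    def test_missing_class_needs_flag(self, separable_patches):
        xt, yt, _, _ = separable_patches
        spec = self._spec()
        with pytest.raises(ValueError, match="without examples"):
            cls.train_classifier(cls.build_classifier(spec), xt, yt, spec)

    def test_save_load_round_trip_identical_calls(self, separable_patches, tmp_path):
        xt, yt, xh, _ = separable_patches
        spec = self._spec(epochs=2)
        model = cls.build_classifier(spec)
        model, _ = cls.train_classifier(model, xt, yt, spec, allow_missing_class=True)
        cls.save_classifier(model, spec, tmp_path / "m")
        back, back_spec = cls.load_classifier(tmp_path / "m")
        p1, _, _ = cls.classify(model, xh[:4], spec)
        p2, _, _ = cls.classify(back, xh[:4], back_spec)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
        assert back_spec.class_labels == spec.class_labels


class TestConfidenceFilter:
    def test_threshold_boundary_inclusive(self):
        records = [
            make_nucleus(id=1, probs=[0.9, 0.1, 0, 0, 0, 0, 0]),
            make_nucleus(id=2, probs=[0.7, 0.3, 0, 0, 0, 0, 0]),
            make_nucleus(id=3, probs=[0.85, 0.15, 0, 0, 0, 0, 0]),
        ]
        kept, frac = cls.filter_low_confidence(records, 0.80)
        assert [r.id for r in kept] == [1, 3]
        assert frac == pytest.approx(2 / 3)
        # exactly 80% confidence is retained ("below 80%" is removed)
        exact = make_nucleus(probs=[0.80, 0.20, 0, 0, 0, 0, 0])
        kept, frac = cls.filter_low_confidence([exact], 0.80)
        assert len(kept) == 1 and frac == 1.0

    def test_all_below_and_empty(self):
        low = [make_nucleus(probs=[0.5, 0.5, 0, 0, 0, 0, 0])]
        kept, frac = cls.filter_low_confidence(low, 0.80)
        assert kept == [] and frac == 0.0
        kept, frac = cls.filter_low_confidence([], 0.80)
        assert kept == [] and np.isnan(frac)


class TestEvaluation:
    def test_perfect_predictions(self):
        y = np.arange(12)
        res = cls.evaluate(y, y, "tubule")
        assert res.accuracy == 1.0
        assert res.within_1_cyclic_accuracy == 1.0

    def test_cyclic_shift_by_one(self):
        y = np.arange(12)
        pred = (y + 1) % 12  # includes XII -> I wrap
        res = cls.evaluate(y, pred, "tubule")
        assert res.accuracy == 0.0
        assert res.within_1_cyclic_accuracy == 1.0

    def test_within_one_never_below_direct_accuracy(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 12, 100)
        pred = rng.integers(0, 12, 100)
        res = cls.evaluate(y, pred, "tubule")
        assert res.within_1_cyclic_accuracy >= res.accuracy

    def test_hand_counted_confusion(self):
        # 3 classes in use: truth [A,A,B,C], predicted [A,B,B,C]
        y = np.array([0, 0, 1, 2])
        pred = np.array([0, 1, 1, 2])
        res = cls.evaluate(y, pred, "cell")
        assert res.accuracy == pytest.approx(0.75)
        np.testing.assert_array_equal(res.confusion[0, :3], [1, 1, 0])
        assert res.confusion.sum(axis=1)[0] == 2  # row sums = annotated counts

    def test_confidence_histogram_bins(self):
        hist = cls.confidence_histogram([0.0, 0.049, 0.05, 0.999, 1.0])
        assert hist.sum() == 5
        assert hist[0] == 2  # [0, 0.05)
        assert hist[1] == 1  # [0.05, 0.10)
        assert hist[19] == 2  # [0.95, 1.0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cls.evaluate([0, 1], [0], "cell")
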