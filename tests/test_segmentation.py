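"""Detection, segmentation, loss, and the trainable backend."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import slidequant as sq

LN2 = 0.6931471805599453
LN4 = 1.3862943611198906

CAL1 = sq.PixelCalibration(1.0)


def _soft_disc_image(shape, centers, radius_px, amp=200.0, background=5.0):
    img = np.full(shape, background)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for r, c in centers:
        d = np.hypot(yy - r, xx - c) / radius_px
        img += amp * np.exp(-(d**4))
    return img


class TestDetectNuclei:
    def test_blank_image_empty(self):
        assert len(sq.detect_nuclei_baseline(np.zeros((64, 64)), CAL1)) == 0

    def test_recovers_isolated_discs(self):
        centers = [(20, 20), (20, 80), (80, 20), (80, 80), (50, 50)]
        img = _soft_disc_image((100, 100), centers, 3.5)
        found = sq.detect_nuclei_baseline(img, CAL1, expected_radius_um=3.5)
        assert len(found) == 5
        for c in centers:
            d = np.min(np.hypot(*(found.centers - c).T))
            assert d <= 2.0

    def test_close_pair_suppressed_to_one(self):
        img = _soft_disc_image((64, 64), [(30, 30), (30, 33)], 3.5)
        found = sq.detect_nuclei_baseline(img, CAL1, min_separation_um=5.0)
        assert len(found) == 1

    def test_bad_scale_rejected(self):
        with pytest.raises(sq.InvalidParameterError):
            sq.detect_nuclei_baseline(np.zeros((8, 8)), sq.PixelCalibration(10.0),
                                      expected_radius_um=3.5)

    def test_count_error_within_15pct_on_default_slide(self, default_slide):
        slide, truth = default_slide
        found = sq.detect_nuclei_baseline(slide.channels["nuclear"], slide.calibration)
        planted = len(truth.nucleus_centers)
        assert abs(len(found) - planted) / planted <= 0.15

    def test_deterministic(self):
        img = _soft_disc_image((64, 64), [(20, 20), (44, 44)], 3.5)
        a = sq.detect_nuclei_baseline(img, CAL1)
        b = sq.detect_nuclei_baseline(img, CAL1)
        np.testing.assert_array_equal(a.centers, b.centers)


class TestSegmentEpithelium:
    def test_noise_free_two_level_is_perfect(self):
        truth = np.zeros((80, 80), dtype=bool)
        truth[20:60, 15:65] = True
        img = np.where(truth, 200.0, 10.0)
        mask = sq.segment_epithelium_baseline(img, CAL1, smooth_sigma_um=0.0)
        assert sq.iou(mask.mask, truth) == 1.0

    def test_mild_noise_keeps_iou_above_09(self):
        rng = np.random.default_rng(6)
        truth = np.zeros((120, 120), dtype=bool)
        truth[20:100, 30:90] = True
        img = np.where(truth, 200.0, 10.0) + rng.normal(0, 30, truth.shape)
        mask = sq.segment_epithelium_baseline(np.maximum(img, 0), CAL1)
        assert sq.iou(mask.mask, truth) >= 0.9

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask = sq.segment_epithelium_baseline(np.full((32, 32), 7.0), CAL1)
        assert mask.area_px == 0


class TestWeightedSoftmaxXent:
    def test_perfect_prediction_is_zero(self):
        scores = np.zeros((4, 4, 2))
        scores[..., 1] = 100.0
        labels = np.ones((4, 4), dtype=int)
        loss = sq.weighted_softmax_xent(scores, labels, np.ones((4, 4)))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_uniform_scores_give_ln2(self):
        scores = np.zeros((3, 5, 2))
        labels = np.random.default_rng(0).integers(0, 2, (3, 5))
        loss = sq.weighted_softmax_xent(scores, labels, np.ones((3, 5)))
        assert loss == pytest.approx(LN2, rel=1e-12)

    def test_hand_computed_ln4(self):
        scores = np.array([[0.0, np.log(3.0)]])
        loss = sq.weighted_softmax_xent(scores, np.array([0]), np.array([1.0]))
        assert loss == pytest.approx(LN4, rel=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(sq.InvalidParameterError):
            sq.weighted_softmax_xent(np.zeros((2, 2, 2)), np.zeros((2, 2), int),
                                     np.zeros((2, 2)))

    @given(st.floats(-50, 50), st.floats(0.01, 100))
    def test_shift_and_weight_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 3, (4, 4, 2))
        labels = rng.integers(0, 2, (4, 4))
        weights = rng.random((4, 4)) + 0.1
        base = sq.weighted_softmax_xent(scores, labels, weights)
        assert sq.weighted_softmax_xent(scores + shift, labels, weights) == \
            pytest.approx(base, rel=1e-9)
        assert sq.weighted_softmax_xent(scores, labels, weights * scale) == \
            pytest.approx(base, rel=1e-9)
        assert base >= 0


def _training_tiles(n, rng):
    tiles = []
    for _ in range(n):
        lab = np.zeros((64, 64), dtype=int)
        r, c = rng.integers(10, 54, 2)
        rad = rng.integers(10, 20)
        yy, xx = np.ogrid[:64, :64]
        lab[(yy - r) ** 2 + (xx - c) ** 2 <= rad**2] = 1
        img = 10 + 140 * lab + rng.normal(0, 8, (64, 64))
        tiles.append((img, lab, None))
    return tiles


@pytest.fixture(scope="module")
def trained_model():
    rng = np.random.default_rng(1)
    tiles = _training_tiles(20, rng)
    config = sq.TrainingConfig(learning_rate=1e-3, iterations=150, batch_size=2,
                               widths=(6, 12), seed=0)
    return sq.train_unet_lite(tiles, config), _training_tiles(5, rng)


class TestTrainableBackend:
    def test_loss_decreases_on_constant_target(self):
        tile = (np.full((16, 16), 5.0), np.zeros((16, 16), int), None)
        cfg = sq.TrainingConfig(learning_rate=1e-2, iterations=50, widths=(4, 8))
        model = sq.train_unet_lite([tile], cfg)
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_zero_iterations_rejected(self):
        with pytest.raises(sq.InvalidParameterError):
            sq.TrainingConfig(iterations=0)

    def test_heldout_iou_above_07(self, trained_model):
        model, heldout = trained_model
        scores = [
            sq.iou(sq.seg_infer(model, img, "mask").mask, lab > 0)
            for img, lab, _ in heldout
        ]
        assert min(scores) >= 0.7

    def test_inference_deterministic(self, trained_model):
        model, heldout = trained_model
        img = heldout[0][0]
        a = sq.seg_infer(model, img, "mask")
        b = sq.seg_infer(model, img, "mask")
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_state_roundtrip_bit_identical(self, trained_model, tmp_path):
        model, heldout = trained_model
        path = tmp_path / "model.npz"
        model.save(path)
        reloaded = sq.SegModelState.load(path)
        img = heldout[0][0]
        np.testing.assert_array_equal(
            sq.seg_infer(model, img, "mask").mask,
            sq.seg_infer(reloaded, img, "mask").mask,
        )
        for k, v in model.params.items():
            np.testing.assert_array_equal(v, reloaded.params[k])

    def test_points_mode_finds_blob(self, trained_model):
        model, heldout = trained_model
        img, lab, _ = heldout[0]
        pts = sq.seg_infer(model, img, "points", calibration=CAL1)
        assert len(pts) >= 1
        # strongest point sits inside the labeled blob
        r, c = np.round(pts.centers[0]).astype(int)
        assert lab[r, c] == 1

    def test_border_weight_map_emphasizes_edges(self):
        lab = np.zeros((20, 20), dtype=int)
        lab[5:15, 5:15] = 1
        w = sq.border_weight_map(lab, border_px=2, border_weight=3.0)
        assert w[5, 5] == 3.0  # on the boundary
        assert w[0, 0] == 1.0  # far away
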