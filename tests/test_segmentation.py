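import numpy as np
import pytest
from scipy import ndimage

from sinter4d import segmentation as seg
from .conftest import noisy_disk_slice


def brute_force_otsu(volume: np.ndarray) -> int:
    """Exhaustive search over all 256 thresholds maximizing between-class variance."""
    hist = np.bincount(volume.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    values = np.arange(256, dtype=float)
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * values[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * values[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestFeatureBank:
    def test_default_bank_has_77_attributes(self):
        assert len(seg.feature_names()) == 77
        stack = seg.compute_feature_stack(np.zeros((2, 12, 12), np.uint8))
        assert stack.n_features == 77

    def test_constant_volume_features(self):
        stack = seg.compute_feature_stack(np.full((2, 16, 16), 55, np.uint8))
        names = stack.names
        flat = stack.flat()
        for j, name in enumerate(names):
            if name.startswith(("gauss", "raw")):
                np.testing.assert_allclose(flat[:, j], 55.0, atol=0.05)
            else:  # all derivative-type features vanish (float32 kernels)
                np.testing.assert_allclose(flat[:, j], 0.0, atol=0.05)

    def test_dog_peaks_at_bright_voxel_for_smallest_scale_pair(self):
        vol = np.zeros((1, 9, 9), np.float32)
        vol[0, 4, 4] = 255.0
        stack = seg.compute_feature_stack(vol.astype(np.uint8))
        j = stack.names.index("dog_s1_s2")
        dog = stack.values[0, :, :, j]
        assert (dog.argmax() // 9, dog.argmax() % 9) == (4, 4)
        # oracle: direct convolution difference at the center
        direct = ndimage.gaussian_filter(vol[0], 1.0, mode="reflect") - ndimage.gaussian_filter(
            vol[0], 2.0, mode="reflect"
        )
        np.testing.assert_allclose(dog[4, 4], direct[4, 4], rtol=1e-4)


class TestVoxelClassifier:
    def _toy(self, rng, n=400):
        X0 = rng.normal(20, 2, size=(n, 5))
        X1 = rng.normal(200, 2, size=(n, 5))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        return X, y

    def test_separable_toy_has_tiny_oob_error(self, rng):
        X, y = self._toy(rng)
        clf = seg.train_voxel_classifier(X, y, n_trees=50, seed=0)
        assert clf.oob_error <= 0.01

    def test_same_seed_gives_identical_predictions(self, rng):
        X, y = self._toy(rng)
        probe = rng.normal(100, 80, size=(50, 5))
        a = seg.train_voxel_classifier(X, y, n_trees=30, seed=5).forest.predict(probe)
        b = seg.train_voxel_classifier(X, y, n_trees=30, seed=5).forest.predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_single_class_labels_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            seg.train_voxel_classifier(X, np.zeros(10, int), n_trees=10, seed=0)

    def test_feature_recipe_mismatch_refused(self, rng):
        X, y = self._toy(rng, n=50)
        clf = seg.train_voxel_classifier(X, y, n_trees=10, seed=0)
        voi = np.zeros((2, 12, 12), np.uint8)
        with pytest.raises(ValueError, match="recipe"):
            seg.segment_glass_rf(voi, clf)

    def test_noise_free_binary_phantom_is_easy(self, rng):
        truth = np.zeros((4, 20, 20), bool)
        truth[:, 4:16, 4:16] = True
        voi = np.where(truth, 200, 30).astype(np.uint8)
        stack = seg.compute_feature_stack(voi)
        idx = rng.choice(voi.size, size=1500, replace=False)
        clf = seg.train_voxel_classifier(stack.flat()[idx], truth.ravel()[idx], n_trees=50, seed=0)
        mask = seg.segment_glass_rf(voi, clf, features=stack)
        assert seg.evaluate_segmentation(mask, truth).iou >= 0.99


class TestOtsu:
    def test_matches_exhaustive_search_on_random_volumes(self, rng):
        for _ in range(20):
            mode = rng.integers(0, 3)
            if mode == 0:
                vol = rng.integers(0, 256, size=(6, 10, 10), dtype=np.uint8)
            elif mode == 1:
                vol = np.clip(
                    rng.normal(90, 30, (6, 10, 10)) + 80 * (rng.random((6, 10, 10)) > 0.6),
                    0,
                    255,
                ).astype(np.uint8)
            else:
                vol = np.clip(rng.normal(120, 10, (6, 10, 10)), 0, 255).astype(np.uint8)
            assert seg.otsu_threshold(vol) == brute_force_otsu(vol)

    def test_two_spike_histogram_thresholds_between_spikes(self):
        vol = np.full((2, 10, 10), 50, np.uint8)
        vol[1] = 200
        t = seg.otsu_threshold(vol)
        assert 50 <= t < 200
        mask = seg.segment_glass_otsu(vol)
        assert mask[1].all() and not mask[0].any()

    def test_constant_volume_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = seg.segment_glass_otsu(np.full((2, 5, 5), 9, np.uint8))
        assert not mask.any()


class TestChooseSegmenter:
    @pytest.mark.parametrize(
        "history,expected",
        [
            ([], "rf"),
            ([60.0, 75.0, 85.0], "rf"),
            ([88.0, 91.0, 92.0], "otsu"),
            ([89.0, 91.0, 89.0, 91.0], "rf"),  # never two consecutive >= 90
            ([91.0, 91.0, 80.0], "otsu"),  # permanence after the switch
        ],
    )
    def test_hysteresis_rule(self, history, expected):
        assert seg.choose_segmenter(history, 90.0) == expected


class TestStrutLevelset:
    def test_clean_disk_recovered(self):
        img, disk = noisy_disk_slice(radius=20, noise_sigma=0.0)
        mask = seg.segment_strut_levelset(img[np.newaxis])
        assert seg.evaluate_segmentation(mask[0], disk).iou >= 0.97

    def test_noisy_disk_iou(self):
        child = []
        disks = []
        for z in range(5):
            img, disk = noisy_disk_slice(radius=20, noise_sigma=20.0, seed=z)
            child.append(img)
            disks.append(disk)
        mask = seg.segment_strut_levelset(np.stack(child))
        for z in range(5):
            assert seg.evaluate_segmentation(mask[z], disks[z]).iou >= 0.95

    def test_interior_holes_are_filled(self):
        img, disk = noisy_disk_slice(radius=20, noise_sigma=10.0, hole_fraction=0.15, seed=3)
        mask = seg.segment_strut_levelset(img[np.newaxis])
        area = mask[0].sum()
        # area tracks the filled disk (within the estimator's dilation under
        # interior porosity), never the disk minus its holes (~0.85 of disk)
        assert 0.95 * disk.sum() <= area <= 1.25 * disk.sum()

    def test_empty_slice_gives_empty_mask(self):
        with pytest.warns(UserWarning, match="no strut"):
            mask = seg.segment_strut_levelset(np.zeros((2, 32, 32), np.uint8))
        assert not mask.any()

    def test_noise_only_slice_gives_empty_mask(self, rng):
        img = np.clip(rng.normal(60, 15, (1, 48, 48)), 0, 255).astype(np.uint8)
        with pytest.warns(UserWarning, match="no strut"):
            mask = seg.segment_strut_levelset(img)
        assert not mask.any()


class TestMetrics:
    def test_identical_masks_score_one(self, rng):
        m = rng.random((3, 6, 6)) > 0.5
        r = seg.evaluate_segmentation(m, m)
        assert r.iou == r.accuracy == r.precision == 1.0

    def test_formula_identities(self):
        # constructed confusion: TP=8, FP=1, FN=1, TN=90
        pred = np.zeros((1, 10, 10), bool)
        truth = np.zeros((1, 10, 10), bool)
        pred.ravel()[:9] = True
        truth.ravel()[1:10] = True
        r = seg.evaluate_segmentation(pred, truth)
        assert (r.tp, r.fp, r.fn, r.tn) == (8, 1, 1, 90)
        assert r.iou == pytest.approx(0.8)
        assert r.precision == pytest.approx(8 / 9)
        assert r.accuracy == pytest.approx(0.98)

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((1, 4, 4), bool)
        b = np.zeros((1, 4, 4), bool)
        a[0, 0, 0] = True
        b[0, 1, 1] = True
        r = seg.evaluate_segmentation(a, b)
        assert r.iou == 0.0 and r.precision == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            seg.evaluate_segmentation(np.zeros((1, 2, 2), bool), np.zeros((1, 3, 3), bool))

    def test_ranges_are_bounded(self, rng):
        for _ in range(10):
            a = rng.random((2, 5, 5)) > rng.random()
            b = rng.random((2, 5, 5)) > rng.random()
            r = seg.evaluate_segmentation(a, b)
            for v in (r.iou, r.accuracy, r.precision):
                assert 0.0 <= v <= 1.0
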