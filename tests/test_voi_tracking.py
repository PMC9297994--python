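import numpy as np
import pytest

from sinter4d import voi_tracking as vt
from sinter4d.io_core import ScanVolume


class TestSliceClassifier:
    @staticmethod
    def _toy_slices(rng, n=12):
        out = []
        for i in range(n):
            bright = rng.normal(200, 5, (16, 16))
            dark = rng.normal(20, 5, (16, 16))
            out.append((np.clip(bright, 0, 255).astype(np.uint8), 1))
            out.append((np.clip(dark, 0, 255).astype(np.uint8), 0))
        return out

    def test_separable_slices_classified_perfectly(self, rng):
        data = self._toy_slices(rng)
        clf = vt.train_slice_classifier(data, seed=0)
        X = np.stack([vt.slice_feature_vector(s) for s, _ in data])
        y = np.array([l for _, l in data])
        np.testing.assert_array_equal(clf.predict(X), y.astype(bool))

    def test_training_is_order_independent(self, rng):
        data = self._toy_slices(rng)
        shuffled = [data[i] for i in rng.permutation(len(data))]
        probe = np.stack([vt.slice_feature_vector(s) for s, _ in self._toy_slices(rng)])
        a = vt.train_slice_classifier(data, seed=1).predict(probe)
        b = vt.train_slice_classifier(shuffled, seed=1).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        data = [(rng.normal(100, 5, (8, 8)).astype(np.uint8), 1) for _ in range(6)]
        with pytest.raises(ValueError, match="single class"):
            vt.train_slice_classifier(data, seed=0)

    def test_run_filter_removes_spurs_and_fills_gaps(self):
        flags = np.zeros(30, bool)
        flags[5:13] = True
        flags[8] = False  # gap of 1 inside a run: filled
        flags[20] = True  # isolated positive: removed
        out = vt._filter_runs(flags, min_run=3, max_gap=2)
        assert out[5:13].all()
        assert not out[20]
        assert not out[:5].any() and not out[13:].any()


class TestLabelAndCenters:
    def test_single_cube_centroid(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[0:3, 0:3, 0:3] = True
        [(label, center, count)] = vt.label_and_center_3d(mask, min_size=1)
        assert center == (1.0, 1.0, 1.0)
        assert count == 27

    def test_two_disjoint_cubes(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[0:3, 0:3, 0:3] = True
        mask[8:11, 8:11, 8:11] = True
        comps = vt.label_and_center_3d(mask, min_size=1)
        centers = sorted(c for _, c, _ in comps)
        assert centers == [(1.0, 1.0, 1.0), (9.0, 9.0, 9.0)]

    def test_min_size_filter(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[0:4, 0:4, 0:4] = True  # 64 voxels
        mask[7, 7, 7] = True  # 1 voxel speck
        comps = vt.label_and_center_3d(mask, min_size=10)
        assert len(comps) == 1

    def test_empty_mask(self):
        assert vt.label_and_center_3d(np.zeros((4, 4, 4), bool)) == []


class TestCoordinates:
    @pytest.mark.parametrize(
        "coarse,factor,expected",
        [((10, 20, 30), 0.25, (40.0, 80.0, 120.0)), ((0, 0, 0), 0.25, (0.0, 0.0, 0.0))],
    )
    def test_upscale_examples(self, coarse, factor, expected):
        assert vt.upscale_centers([coarse], factor)[0] == expected

    def test_upscale_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            vt.upscale_centers([(1, 1, 1)], 0.0)

    def test_extract_exact_box(self, rng):
        vol = ScanVolume(
            voxels=rng.integers(0, 256, (70, 330, 306), dtype=np.uint8), voxel_size_um=0.81
        )
        sub, clipped = vt.extract_voi(vol, (35, 165, 153), (70, 330, 306))
        assert sub.shape == (70, 330, 306)
        assert not clipped
        np.testing.assert_array_equal(sub, vol.voxels)

    def test_extract_corner_is_zero_padded_and_flagged(self, rng):
        vol = rng.integers(1, 256, (10, 10, 10), dtype=np.uint8)
        sub, clipped = vt.extract_voi(vol, (0, 0, 0), (6, 6, 6))
        assert clipped
        assert sub.shape == (6, 6, 6)
        # box [-3, 3) per axis: the in-bounds octant lands at [3:, 3:, 3:]
        np.testing.assert_array_equal(sub[3:, 3:, 3:], vol[:3, :3, :3])
        assert (sub[:3] == 0).all()
        assert (sub[:, :3] == 0).all()
        assert (sub[:, :, :3] == 0).all()

    def test_extract_single_voxel(self, rng):
        vol = rng.integers(0, 256, (5, 5, 5), dtype=np.uint8)
        sub, _ = vt.extract_voi(vol, (2, 3, 4), (1, 1, 1))
        assert sub[0, 0, 0] == vol[2, 3, 4]

    def test_extract_center_outside_rejected(self, rng):
        vol = rng.integers(0, 256, (5, 5, 5), dtype=np.uint8)
        with pytest.raises(ValueError, match="outside"):
            vt.extract_voi(vol, (9, 2, 2), (3, 3, 3))


class TestTracking:
    def test_identical_lists_give_identity_matching(self):
        pts = [(0.0, 1.0, 2.0), (5.0, 5.0, 5.0), (9.0, 0.0, 3.0)]
        assert vt.track_centers(pts, pts) == [(0, 0), (1, 1), (2, 2)]

    def test_uniform_drift_recovers_bijection(self, rng):
        pts = rng.uniform(0, 100, size=(5, 3))
        drifted = pts + np.array([-3.0, -3.0, 0.0])
        perm = rng.permutation(5)
        pairs = vt.track_centers([tuple(p) for p in pts], [tuple(p) for p in drifted[perm]])
        recovered = {i: j for i, j in pairs}
        for i in range(5):
            assert np.allclose(drifted[perm][recovered[i]], pts[i] + [-3, -3, 0])

    def test_vanished_center_leaves_partial_matching(self, rng):
        pts = [(0.0, 0.0, 0.0), (20.0, 0.0, 0.0), (40.0, 0.0, 0.0), (60.0, 0.0, 0.0), (80.0, 0.0, 0.0)]
        pairs = vt.track_centers(pts, pts[:4], max_displacement=5.0)
        assert len(pairs) == 4
        assert pairs == vt.track_centers_bruteforce(pts, pts[:4], max_displacement=5.0)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(30):
            n, m = rng.integers(1, 7, size=2)
            a = [tuple(p) for p in rng.uniform(0, 30, size=(n, 3))]
            b = [tuple(p) for p in rng.uniform(0, 30, size=(m, 3))]
            cap = float(rng.uniform(5, 30))
            assert vt.track_centers(a, b, cap) == vt.track_centers_bruteforce(a, b, cap)

    def test_result_is_partial_bijection(self, rng):
        a = [tuple(p) for p in rng.uniform(0, 50, size=(7, 3))]
        b = [tuple(p) for p in rng.uniform(0, 50, size=(6, 3))]
        pairs = vt.track_centers(a, b, 25.0)
        assert len({i for i, _ in pairs}) == len(pairs)
        assert len({j for _, j in pairs}) == len(pairs)


class TestHyperstacks:
    @staticmethod
    def _drifting_series(n_time=4, n_pts=6, drift=(-1.0, -1.0, 0.0), seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(20, 200, size=(n_pts, 3))
        centers, records = [], []
        for t in range(n_time):
            pts = base + t * np.asarray(drift)
            centers.append([tuple(p) for p in pts])
            records.append(
                [
                    vt.VOIRecord(
                        label=i,
                        center_zyx_full=tuple(p),
                        center_zyx_coarse=tuple(v / 4 for v in p),
                        time_index=t,
                        extents=(4, 4, 4),
                    )
                    for i, p in enumerate(pts)
                ]
            )
        return centers, records

    def test_all_tracks_complete_under_small_drift(self):
        centers, records = self._drifting_series()
        stacks = vt.build_hyperstacks(centers, records, n_select=None, max_displacement=10.0)
        assert len(stacks) == 6
        for hs in stacks:
            assert hs.time_indices == [0, 1, 2, 3]

    def test_n_select_limits_output(self):
        centers, records = self._drifting_series()
        stacks = vt.build_hyperstacks(centers, records, n_select=3, max_displacement=10.0)
        assert len(stacks) == 3

    def test_single_time_point(self):
        centers, records = self._drifting_series(n_time=1)
        stacks = vt.build_hyperstacks(centers, records, n_select=2, max_displacement=10.0)
        assert all(len(hs.entries) == 1 for hs in stacks)

    def test_tracks_never_mix(self):
        centers, records = self._drifting_series(n_pts=5, drift=(-2.0, 0.0, 0.0), seed=2)
        stacks = vt.build_hyperstacks(centers, records, n_select=None, max_displacement=8.0)
        for hs in stacks:
            pts = hs.centers()
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            assert (steps <= 8.0).all()

    def test_selection_prefers_centroid_proximity(self):
        centers, records = self._drifting_series(n_pts=6, seed=3)
        stacks = vt.build_hyperstacks(centers, records, n_select=2, max_displacement=10.0)
        pts0 = np.array(centers[0])
        centroid = pts0.mean(axis=0)
        dists = np.linalg.norm(pts0 - centroid, axis=1)
        chosen = {hs.entries[0][1].label for hs in stacks}
        assert chosen == set(np.argsort(dists)[:2])
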