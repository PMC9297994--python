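import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sinter4d import quantify as q
from sinter4d.io_core import series_from_rows


class TestRelativeDensity:
    @pytest.mark.parametrize(
        "glass,pore,porosity,density",
        [(75, 25, 25.0, 75.0), (1, 0, 0.0, 100.0), (0, 10, 100.0, 0.0)],
    )
    def test_examples(self, glass, pore, porosity, density):
        p, d = q.relative_density(glass, pore)
        assert p == pytest.approx(porosity)
        assert d == pytest.approx(density)

    def test_empty_voi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            q.relative_density(0, 0)

    @given(glass=st.integers(0, 10**9), pore=st.integers(0, 10**9))
    @settings(max_examples=100, deadline=None)
    def test_conservation_is_exact(self, glass, pore):
        if glass + pore == 0:
            return
        p, d = q.relative_density(glass, pore)
        assert p + d == 100.0


class TestStrutDiameter:
    def test_zero_area_gives_zero_diameter(self):
        assert q.diameter_from_area(0.0) == 0.0

    def test_rasterized_disk_diameter(self):
        yy, xx = np.ogrid[:128, :128]
        disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 50**2
        rec = q.strut_diameter(disk[np.newaxis], voxel_size_um=1.0)
        assert rec.mean_diameter_px == pytest.approx(100.0, abs=1.0)

    def test_pixel_rounding_rule_before_unit_conversion(self):
        # a 298-px mean diameter reports 298 * 0.81 = 241.38 um
        assert q.pixels_to_um(297.9, 0.81) == pytest.approx(241.38)
        assert q.pixels_to_um(298.4, 0.81) == pytest.approx(241.38)

    def test_empty_slices_excluded_with_warning(self):
        masks = np.zeros((3, 10, 10), bool)
        masks[0, 2:8, 2:8] = True
        with pytest.warns(UserWarning, match="empty slice"):
            rec = q.strut_diameter(masks, voxel_size_um=1.0)
        assert rec.mean_diameter_px == pytest.approx(q.diameter_from_area(36.0))

    def test_monotone_in_foreground(self, rng):
        base = rng.random((1, 20, 20)) > 0.6
        grown = base.copy()
        grown[0, 0, 0] = True
        d0 = q.strut_diameter(base, 1.0).slice_diameters_px[0]
        d1 = q.strut_diameter(grown, 1.0).slice_diameters_px[0]
        assert d1 >= d0


class TestPoreDiagonalDistance:
    def test_printed_scaffold_arithmetic(self):
        # centers 661 px apart at 0.81 um/px -> 535.41 um; minus 241.4 um diameter
        pdd = q.pore_diagonal_distance((0.0, 0.0, 0.0), (0.0, 600.0, 277.0), 241.4, 0.81)
        dist = np.hypot(600.0, 277.0)
        assert pdd == pytest.approx(round(dist) * 0.81 - 241.4)
        assert pdd == pytest.approx(294.0, abs=0.2)

    def test_coincident_centers_zero_diameter(self):
        assert q.pore_diagonal_distance((0, 0, 0), (0, 0, 0), 0.0, 0.81) == 0.0

    def test_overlapping_struts_warn_negative(self):
        with pytest.warns(UserWarning, match="negative"):
            v = q.pore_diagonal_distance((0, 0, 0), (0, 3, 4), 100.0, 1.0)
        assert v == pytest.approx(5.0 - 100.0)


class TestShrinkage:
    @pytest.mark.parametrize("s,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_limits(self, s, expected):
        assert q.volume_shrinkage_isotropic(s) == expected

    def test_reported_linear_to_volume_conversion(self):
        assert q.volume_shrinkage_isotropic(0.158) == pytest.approx(0.40305, abs=1e-5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            q.volume_shrinkage_isotropic(1.2)

    @given(st.floats(0.001, 0.998), st.floats(0.001, 0.998))
    @settings(max_examples=60, deadline=None)
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted([a, b])
        if hi - lo < 1e-9:
            return
        assert q.volume_shrinkage_isotropic(lo) < q.volume_shrinkage_isotropic(hi)

    def test_measured_shrinkage_from_boxes(self):
        assert q.measured_volume_shrinkage((10, 10, 10), (10, 10, 10)) == 0.0
        assert q.measured_volume_shrinkage((100, 80, 60), (85, 68, 51)) == pytest.approx(
            1 - 0.85**3
        )

    def test_percent_reduction(self):
        assert q.percent_reduction(241.4, 203.3) == pytest.approx(15.78, abs=0.01)


class TestStrutOverlap:
    def test_printed_diameter_and_spacing(self):
        overlap, pct = q.strut_overlap(241.4, 200.0)
        assert overlap == pytest.approx(41.4)
        assert pct == pytest.approx(17.15, abs=0.01)

    def test_no_interpenetration_when_spacing_exceeds_diameter(self):
        assert q.strut_overlap(100.0, 120.0) == (0.0, 0.0)

    def test_direct_arithmetic(self):
        assert q.strut_overlap(100.0, 80.0) == (20.0, 20.0)


class TestSeriesAssembly:
    @staticmethod
    def _manifest(n):
        return series_from_rows([(f"s{i:03d}", float(i * 120), 500.0 + i) for i in range(n)])

    def test_full_series_row_count(self):
        records = {
            f"s{i:03d}": {"relative_density_pct": 55.0 + i * 0.4, "strut_diameter_um": 241.0}
            for i in range(93)
        }
        series = q.assemble_series(records, self._manifest(93))
        assert len(series.table) == 93
        assert (series.table["porosity_pct"] + series.table["relative_density_pct"] == 100).all()

    def test_missing_field_kept_as_null_with_warning(self):
        records = {"s000": {"relative_density_pct": 60.0}, "s001": {"strut_diameter_um": 240.0}}
        with pytest.warns(UserWarning, match="missing field"):
            series = q.assemble_series(records, self._manifest(2))
        assert np.isnan(series.table.loc[0, "strut_diameter_um"])
        assert np.isnan(series.table.loc[1, "relative_density_pct"])

    def test_unknown_scan_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            q.assemble_series({"ghost": {}}, self._manifest(2))


class TestStageAnnotation:
    @staticmethod
    def _series(densities):
        rows = {
            f"s{i:02d}": {"relative_density_pct": d, "strut_diameter_um": 1.0}
            for i, d in enumerate(densities)
        }
        manifest = series_from_rows(
            [(f"s{i:02d}", float(i * 60), 500.0) for i in range(len(densities))]
        )
        return q.assemble_series(rows, manifest)

    def test_logistic_curve_gives_three_contiguous_stages(self):
        x = np.linspace(-6, 6, 30)
        d = 55 + 40 / (1 + np.exp(-x))
        series = self._series(d)
        labels = q.annotate_stages(series)
        assert labels[0] == "initial" and labels[-1] == "final"
        assert set(labels) == {"initial", "intermediate", "final"}
        order = {"initial": 0, "intermediate": 1, "final": 2}
        ranks = [order[s] for s in labels]
        assert ranks == sorted(ranks)

    def test_flat_curve_below_cutoff_has_no_final_stage(self):
        labels = q.annotate_stages(self._series([60.0] * 10))
        assert "final" not in labels

    def test_curve_starting_dense_is_all_final(self):
        labels = q.annotate_stages(self._series([95.0, 96.0, 97.0]))
        assert labels == ["final"] * 3

    def test_nonmonotone_density_warns_but_labels(self):
        d = [55, 60, 52, 70, 80, 91, 92]
        with pytest.warns(UserWarning, match="decreases"):
            labels = q.annotate_stages(self._series(d))
        assert len(labels) == 7
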