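"""Operation catalog: filters, thresholds, labelling, measurements, tables.

Numerical operations are cross-checked against the naive reference
implementations in :mod:`oracles` on randomized small stacks.
"""

import numpy as np
import pandas as pd
import pytest

from voxpipe import Calibration, LabelMap, ModuleError, VoxelGrid, write_grid
from voxpipe.containers import BinaryMask
from voxpipe.ops import (
    _ellipsoid_footprint,
    op_attach,
    op_autoThreshold,
    op_calibration,
    op_closing,
    op_coloc,
    op_crop,
    op_deleteList,
    op_distances,
    op_excludeEdges,
    op_fillHoles,
    op_filterShape,
    op_filterSize,
    op_filters,
    op_hysteresis,
    op_keepBiggest,
    op_label,
    op_loadCalibration,
    op_math,
    op_measurement,
    op_mergeTables,
    op_numbering,
    op_appendTables,
    op_percentile,
    op_quantification,
    op_save,
    op_saveCalibration,
    op_scale,
    op_threshold,
)

import oracles
from conftest import grid_of, run_op


def random_grid(rng, shape=(5, 6, 7), levels=8):
    """Small random uint8 stack with few distinct levels (forces ties)."""
    return (rng.integers(0, levels, shape) * (255 // max(levels - 1, 1))).astype(
        np.uint8
    )


def sparse_mask(rng, shape=(5, 8, 8), density=0.25):
    return rng.random(shape) < density


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------


class TestFilters:
    @pytest.mark.parametrize("name", ["median", "mean", "min", "max", "gauss"])
    def test_zero_radius_is_identity(self, name):
        rng = np.random.default_rng(0)
        grid = grid_of(random_grid(rng))
        out, _ = run_op(op_filters, grid, filter=name, radiusXY=0, radiusZ=0)
        np.testing.assert_array_equal(out.data, grid.data)

    def test_min_max_ordering(self):
        rng = np.random.default_rng(1)
        grid = grid_of(random_grid(rng))
        open_, _ = run_op(op_filters, grid, filter="min", radiusXY=1, radiusZ=1)
        open_, _ = run_op(op_filters, open_, filter="max", radiusXY=1, radiusZ=1)
        close_, _ = run_op(op_filters, grid, filter="max", radiusXY=1, radiusZ=1)
        close_, _ = run_op(op_filters, close_, filter="min", radiusXY=1, radiusZ=1)
        assert (open_.data <= grid.data).all()
        assert (grid.data <= close_.data).all()

    def test_median_removes_single_impulse(self):
        data = np.full((3, 7, 7), 10, dtype=np.uint8)
        data[1, 3, 3] = 250
        out, _ = run_op(op_filters, grid_of(data), filter="median", radiusXY=1, radiusZ=1)
        assert (out.data == 10).all()

    def test_median_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        footprint = _ellipsoid_footprint(1, 1)
        for _ in range(50):
            data = random_grid(rng, shape=(4, 5, 5))
            out, _ = run_op(
                op_filters, grid_of(data), filter="median", radiusXY=1, radiusZ=1
            )
            expected = oracles.brute_median_filter(data, footprint)
            np.testing.assert_array_equal(out.data, expected)

    def test_mean_preserves_constant_field(self):
        grid = grid_of(np.full((4, 6, 6), 37, dtype=np.uint8))
        out, _ = run_op(op_filters, grid, filter="mean", radiusXY=2, radiusZ=1)
        assert (out.data == 37).all()

    def test_unknown_filter_lists_choices(self):
        with pytest.raises(ModuleError, match="median, mean, min, max, gauss"):
            run_op(op_filters, grid_of(np.zeros((1, 2, 2))), filter="blur")


# --------------------------------------------------------------------------
# Thresholding
# --------------------------------------------------------------------------


class TestAutoThreshold:
    def test_otsu_separates_bimodal_halves(self):
        data = np.zeros((2, 10, 10), dtype=np.uint8)
        data[1] = 100
        out, _ = run_op(op_autoThreshold, grid_of(data), method="Otsu")
        assert isinstance(out, BinaryMask)
        np.testing.assert_array_equal(out.data, data == 100)

    def test_otsu_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        from voxpipe.ops import otsu_threshold

        for _ in range(50):
            data = random_grid(rng, shape=(4, 6, 6), levels=10)
            if data.min() == data.max():
                continue
            assert otsu_threshold(data) == oracles.exhaustive_otsu(data)

    def test_mean_method_on_two_level_grid(self):
        data = np.zeros((1, 2, 10), dtype=np.uint8)
        data[0, 1] = 100
        out, state = run_op(op_autoThreshold, grid_of(data), method="Mean")
        np.testing.assert_array_equal(out.data, data > 50)
        assert any("threshold=50" in line for line in state.log_lines)

    def test_isodata_is_a_fixpoint(self):
        rng = np.random.default_rng(4)
        from voxpipe.ops import isodata_threshold

        for _ in range(20):
            data = random_grid(rng, shape=(3, 6, 6), levels=12)
            if data.min() == data.max():
                continue
            t = isodata_threshold(data)
            flat = data.astype(float).ravel()
            below, above = flat[flat <= t], flat[flat > t]
            if below.size and above.size:
                assert abs((below.mean() + above.mean()) / 2 - t) < 1e-6

    def test_constant_image_is_degenerate(self):
        with pytest.raises(ModuleError, match="degenerate"):
            run_op(op_autoThreshold, grid_of(np.full((2, 3, 3), 7, dtype=np.uint8)))

    def test_unknown_method_rejected(self):
        with pytest.raises(ModuleError, match="Otsu, Mean, IsoData"):
            run_op(op_autoThreshold, grid_of(np.arange(8).reshape(2, 2, 2)), method="Li")


class TestFixedThresholds:
    def test_threshold_is_strictly_above(self):
        data = np.array([[[10, 50, 51, 200]]], dtype=np.uint8)
        out, _ = run_op(op_threshold, grid_of(data), low=50)
        np.testing.assert_array_equal(out.data[0, 0], [False, False, True, True])

    def test_percentile_on_distinct_values(self):
        rng = np.random.default_rng(5)
        data = rng.permutation(100).reshape(1, 10, 10).astype(np.uint8)
        out, _ = run_op(op_percentile, grid_of(data), percentile=10)
        assert out.data.sum() == 10

    def test_percentile_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            data = random_grid(rng, shape=(3, 5, 5), levels=6)
            pct = float(rng.uniform(1, 99))
            out, _ = run_op(op_percentile, grid_of(data), percentile=pct)
            t = oracles.percentile_threshold(data, pct)
            np.testing.assert_array_equal(out.data, data > t)

    @pytest.mark.parametrize("pct", [0, 100, -5, 120])
    def test_percentile_range_checked(self, pct):
        with pytest.raises(ModuleError, match=r"\(0, 100\)"):
            run_op(op_percentile, grid_of(np.zeros((1, 2, 2))), percentile=pct)

    def test_hysteresis_weak_connected_to_strong_survives(self):
        data = np.array([[[0, 60, 120]]], dtype=np.uint8)
        out, _ = run_op(op_hysteresis, grid_of(data), low=50, high=100)
        np.testing.assert_array_equal(out.data[0, 0], [False, True, True])

    def test_hysteresis_without_seed_is_empty(self):
        data = np.array([[[0, 60, 0]]], dtype=np.uint8)
        out, _ = run_op(op_hysteresis, grid_of(data), low=50, high=100)
        assert not out.data.any()

    def test_hysteresis_matches_reachability_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            data = random_grid(rng, shape=(4, 5, 5), levels=6)
            low, high = sorted(rng.uniform(0, 255, 2))
            out, _ = run_op(op_hysteresis, grid_of(data), low=low, high=high)
            expected = oracles.reachable_hysteresis(data, low, high)
            np.testing.assert_array_equal(out.data, expected)

    def test_hysteresis_low_above_high_rejected(self):
        with pytest.raises(ModuleError, match="low"):
            run_op(op_hysteresis, grid_of(np.zeros((1, 2, 2))), low=10, high=5)


# --------------------------------------------------------------------------
# Labelling
# --------------------------------------------------------------------------


class TestLabel:
    def test_two_disjoint_cubes(self):
        mask = np.zeros((4, 8, 8), dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        mask[2:4, 5:7, 5:7] = True
        out, _ = run_op(op_label, grid_of(mask, cls=BinaryMask))
        assert isinstance(out, LabelMap)
        assert out.n_labels == 2

    def test_min_size_boundary_removes_99_voxel_blob(self):
        mask = np.zeros((1, 20, 20), dtype=bool)
        blob = np.zeros(400, dtype=bool)
        blob[:99] = True
        mask[0] = blob.reshape(20, 20)  # a single 8-connected 99-voxel slab
        out, _ = run_op(op_label, grid_of(mask, cls=BinaryMask), minSize=100)
        assert out.n_labels == 0
        mask[0] = np.concatenate([np.ones(100, dtype=bool), np.zeros(300, dtype=bool)]).reshape(20, 20)
        out, _ = run_op(op_label, grid_of(mask, cls=BinaryMask), minSize=100)
        assert out.n_labels == 1

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            mask = sparse_mask(rng)
            out, _ = run_op(op_label, grid_of(mask, cls=BinaryMask))
            expected = oracles.flood_fill_components(mask)
            np.testing.assert_array_equal(out.data, expected)

    def test_grayscale_input_thresholded_above_zero(self):
        data = np.zeros((1, 4, 4), dtype=np.uint8)
        data[0, 1, 1] = 7
        out, _ = run_op(op_label, grid_of(data))
        assert out.n_labels == 1

    def test_empty_mask_warns_not_errors(self):
        out, state = run_op(op_label, grid_of(np.zeros((2, 3, 3), dtype=bool), cls=BinaryMask))
        assert out.n_labels == 0
        assert state.warnings


# --------------------------------------------------------------------------
# Post-processing
# --------------------------------------------------------------------------


def _hollow_cube(outer=5, pad=2):
    mask = np.zeros((outer + 2 * pad,) * 3, dtype=bool)
    sl = slice(pad, pad + outer)
    mask[sl, sl, sl] = True
    inner = slice(pad + 1, pad + outer - 1)
    mask[inner, inner, inner] = False
    return mask


class TestFillHoles:
    def test_hollow_cube_becomes_solid(self):
        mask = _hollow_cube()
        out, _ = run_op(op_fillHoles, grid_of(mask, cls=BinaryMask))
        assert out.data.sum() == 5**3

    def test_idempotent(self):
        mask = _hollow_cube()
        once, _ = run_op(op_fillHoles, grid_of(mask, cls=BinaryMask))
        twice, _ = run_op(op_fillHoles, once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_2d_ring_filled_slice_wise(self):
        mask = np.zeros((1, 7, 7), dtype=bool)
        mask[0, 1:6, 1:6] = True
        mask[0, 2:5, 2:5] = False
        out, _ = run_op(op_fillHoles, grid_of(mask, cls=BinaryMask))
        assert out.data[0, 1:6, 1:6].all()

    def test_label_map_holes_take_their_object_id(self):
        labels = _hollow_cube().astype(np.int32) * 2  # a single object with id 2
        out, _ = run_op(op_fillHoles, grid_of(labels, cls=LabelMap))
        assert isinstance(out, LabelMap)
        assert (out.data[3:6, 3:6, 3:6] == 2).all()


class TestClosing:
    def test_closes_small_gap_between_blocks(self):
        mask = np.zeros((1, 7, 13), dtype=bool)
        mask[0, 2:5, 1:5] = True
        mask[0, 2:5, 6:10] = True  # 1-voxel gap at x=5
        out, _ = run_op(op_closing, grid_of(mask, cls=BinaryMask), radiusXY=2, radiusZ=0)
        assert out.data[0, 3, 5]
        assert out.data[mask].all()  # closing is extensive

    def test_superset_of_input(self):
        rng = np.random.default_rng(9)
        mask = sparse_mask(rng, density=0.2)
        out, _ = run_op(op_closing, grid_of(mask, cls=BinaryMask), radiusXY=1, radiusZ=1)
        assert (out.data | ~mask).all() or (out.data[mask]).all()


class TestExcludeEdges:
    def _two_objects(self):
        labels = np.zeros((3, 8, 8), dtype=np.int32)
        labels[1, 0:2, 0:2] = 1  # touches y=0 and x=0 borders
        labels[1, 4:6, 4:6] = 2  # interior
        return grid_of(labels, cls=LabelMap)

    def test_xy_touching_object_removed_interior_kept(self):
        out, _ = run_op(op_excludeEdges, self._two_objects())
        assert out.n_labels == 1
        assert (out.data[1, 4:6, 4:6] == 1).all()

    def test_z_borders_only_when_requested(self):
        labels = np.zeros((3, 8, 8), dtype=np.int32)
        labels[0, 3:5, 3:5] = 1  # touches z=0 only
        keep, _ = run_op(op_excludeEdges, grid_of(labels, cls=LabelMap))
        assert keep.n_labels == 1
        drop, _ = run_op(op_excludeEdges, grid_of(labels, cls=LabelMap), edgeZ="yes")
        assert drop.n_labels == 0

    def test_idempotent(self):
        once, _ = run_op(op_excludeEdges, self._two_objects())
        twice, _ = run_op(op_excludeEdges, once)
        np.testing.assert_array_equal(once.data, twice.data)


class TestKeepBiggest:
    def _labels(self, sizes=(5, 9, 3)):
        labels = np.zeros((1, 4, 20), dtype=np.int32)
        x = 0
        for i, size in enumerate(sizes, start=1):
            labels[0, i % 4, x : x + size] = i
            x += size + 1
        return grid_of(labels, cls=LabelMap)

    def test_keeps_the_biggest(self):
        out, _ = run_op(op_keepBiggest, self._labels())
        assert out.n_labels == 1
        assert out.data.sum() == 9  # the 9-voxel object, relabelled to 1

    def test_tie_broken_by_smallest_id(self):
        grid = self._labels(sizes=(7, 7, 2))
        original = grid.data.copy()
        out, _ = run_op(op_keepBiggest, grid)
        np.testing.assert_array_equal(out.data == 1, original == 1)

    def test_idempotent(self):
        once, _ = run_op(op_keepBiggest, self._labels())
        twice, _ = run_op(op_keepBiggest, once)
        np.testing.assert_array_equal(once.data, twice.data)


class TestFilterSizeShape:
    def test_filter_size_window(self):
        labels = np.zeros((1, 3, 12), dtype=np.int32)
        labels[0, 0, 0:2] = 1
        labels[0, 1, 0:5] = 2
        labels[0, 2, 0:9] = 3
        out, _ = run_op(op_filterSize, grid_of(labels, cls=LabelMap), minSize=3, maxSize=6)
        assert out.n_labels == 1
        assert (out.data[0, 1, 0:5] == 1).all()

    def test_filter_shape_keeps_compact_objects(self):
        labels = np.zeros((9, 13, 13), dtype=np.int32)
        zz, yy, xx = np.indices(labels.shape)
        ball = ((zz - 4) ** 2 + (yy - 4) ** 2 + (xx - 4) ** 2) <= 9
        labels[ball] = 1
        labels[0, 12, 0:12] = 2  # thin rod
        # compactness cutoff from the face-counting oracle, between the two
        compactness = {}
        for lid in (1, 2):
            v = float((labels == lid).sum())
            s = oracles.count_faces(labels, lid, 1.0, 1.0, 1.0)
            compactness[lid] = 36 * np.pi * v**2 / s**3
        assert compactness[1] > compactness[2]
        cutoff = (compactness[1] + compactness[2]) / 2
        out, _ = run_op(
            op_filterShape, grid_of(labels, cls=LabelMap), measure="compactness", min=cutoff
        )
        assert set(np.unique(out.data)) == {0, 1}
        assert ((out.data == 1) == (labels == 1)).all()

    def test_unknown_measure_rejected(self):
        with pytest.raises(ModuleError, match="unknown measure"):
            run_op(
                op_filterShape,
                grid_of(np.ones((1, 2, 2), dtype=np.int32), cls=LabelMap),
                measure="roundness",
            )


# --------------------------------------------------------------------------
# Analysis
# --------------------------------------------------------------------------


class TestMeasurement:
    def test_voxels_and_volume_uncalibrated(self, tmp_path):
        labels = np.zeros((2, 4, 4), dtype=np.int32)
        labels[0, 0, :4] = 1
        labels[1, 2, 0:3] = 1  # 7 voxels
        labels[1, 3, 0:3] = 2
        grid = grid_of(labels, cls=LabelMap)
        out, _ = run_op(
            op_measurement, grid, list="voxels, volume", dir=tmp_path, file="m.csv"
        )
        table = pd.read_csv(tmp_path / "m.csv")
        assert list(table.columns) == ["label", "voxels", "volume"]
        assert table.loc[0, "voxels"] == 7
        assert table.loc[0, "volume"] == 7.0
        # the current image is returned bit-identical
        assert out is grid

    def test_calibrated_volume(self, tmp_path):
        labels = np.zeros((4, 10, 10), dtype=np.int32)
        labels[0, 0:10, 0:10] = 1  # 100 voxels
        grid = LabelMap(labels, Calibration(0.2, 1.0, "micron"))
        run_op(op_measurement, grid, list="volume", dir=tmp_path, file="m.csv")
        table = pd.read_csv(tmp_path / "m.csv")
        assert table.loc[0, "volume"] == pytest.approx(100 * 0.2 * 0.2 * 1.0)

    def test_volume_conservation_on_random_label_maps(self, tmp_path):
        rng = np.random.default_rng(10)
        for i in range(10):
            mask = sparse_mask(rng, shape=(4, 7, 7))
            out, _ = run_op(op_label, grid_of(mask, cls=BinaryMask))
            cal = Calibration(0.5, 2.0, "um")
            lab = LabelMap(out.data, cal)
            run_op(op_measurement, lab, list="volume", dir=tmp_path, file=f"c{i}.csv")
            table = pd.read_csv(tmp_path / f"c{i}.csv")
            assert table["volume"].sum() == pytest.approx(
                mask.sum() * cal.voxel_volume, abs=1e-9
            )

    def test_surface_matches_face_enumeration_oracle(self, tmp_path):
        rng = np.random.default_rng(11)
        mask = sparse_mask(rng, shape=(3, 5, 5), density=0.3)
        out, _ = run_op(op_label, grid_of(mask, cls=BinaryMask))
        lab = LabelMap(out.data, Calibration(0.4, 1.5, "um"))
        run_op(op_measurement, lab, list="surface", dir=tmp_path, file="s.csv")
        table = pd.read_csv(tmp_path / "s.csv")
        for _, row in table.iterrows():
            expected = oracles.count_faces(lab.data, int(row["label"]), 0.4, 0.4, 1.5)
            assert row["surface"] == pytest.approx(expected)

    def test_ball_more_compact_than_rod(self, tmp_path):
        labels = np.zeros((11, 40, 40), dtype=np.int32)
        zz, yy, xx = np.indices(labels.shape)
        ball = ((zz - 5) ** 2 + (yy - 8) ** 2 + (xx - 8) ** 2) <= 16
        labels[ball] = 1
        n = int(ball.sum())
        labels[5, 20, :] = 0
        rod = np.zeros_like(labels)
        rod[5, 25, :] = 0
        # a 1-voxel-thick rod with the same voxel count
        coords = [(5, 25 + i // 40, i % 40) for i in range(n)]
        for z, y, x in coords:
            labels[z, y, x] = 2
        run_op(
            op_measurement,
            grid_of(labels, cls=LabelMap),
            list="compactness, sphericity",
            dir=tmp_path,
            file="c.csv",
        )
        table = pd.read_csv(tmp_path / "c.csv").set_index("label")
        assert table.loc[1, "compactness"] > table.loc[2, "compactness"]
        assert table.loc[1, "sphericity"] == pytest.approx(
            table.loc[1, "compactness"] ** (1 / 3)
        )

    def test_centroid_and_bbox_columns(self, tmp_path):
        labels = np.zeros((3, 5, 7), dtype=np.int32)
        labels[1, 2:4, 3:6] = 1
        grid = LabelMap(labels, Calibration(2.0, 3.0, "um"))
        run_op(op_measurement, grid, list="centroid, bbox", dir=tmp_path, file="cb.csv")
        table = pd.read_csv(tmp_path / "cb.csv")
        assert table.loc[0, "cx"] == pytest.approx(4.0 * 2.0)
        assert table.loc[0, "cy"] == pytest.approx(2.5 * 2.0)
        assert table.loc[0, "cz"] == pytest.approx(1.0 * 3.0)
        assert (
            table.loc[0, ["bx_min", "bx_max", "by_min", "by_max", "bz_min", "bz_max"]]
            .tolist()
            == [3, 5, 2, 3, 1, 1]
        )

    def test_unknown_measure_rejected(self, tmp_path):
        with pytest.raises(ModuleError, match="unknown measure"):
            run_op(
                op_measurement,
                grid_of(np.ones((1, 2, 2), dtype=np.int32), cls=LabelMap),
                list="volume, elongation",
                dir=tmp_path,
                file="x.csv",
            )

    def test_empty_label_map_writes_header_only(self, tmp_path):
        _, state = run_op(
            op_measurement,
            grid_of(np.zeros((1, 3, 3), dtype=np.int32), cls=LabelMap),
            list="volume",
            dir=tmp_path,
            file="e.csv",
        )
        table = pd.read_csv(tmp_path / "e.csv")
        assert len(table) == 0
        assert state.warnings


class TestQuantification:
    def _save_raw(self, tmp_path, data, name="raw"):
        write_grid(tmp_path / f"{name}.tif", VoxelGrid(np.asarray(data)))

    def test_mean_and_sum(self, tmp_path):
        raw = np.zeros((1, 2, 2), dtype=np.uint8)
        raw[0, 0] = [10, 20]
        labels = np.zeros((1, 2, 2), dtype=np.int32)
        labels[0, 0] = 1
        self._save_raw(tmp_path, raw)
        run_op(
            op_quantification,
            grid_of(labels, cls=LabelMap),
            dirRaw=tmp_path, fileRaw="raw", list="mean, sum",
            dir=tmp_path, file="q.csv",
        )
        table = pd.read_csv(tmp_path / "q.csv")
        assert table.loc[0, "mean"] == 15.0
        assert table.loc[0, "sum"] == 30.0

    def test_constant_raw_gives_constant_means(self, tmp_path):
        rng = np.random.default_rng(12)
        mask = sparse_mask(rng, shape=(3, 6, 6))
        labelled, _ = run_op(op_label, grid_of(mask, cls=BinaryMask))
        self._save_raw(tmp_path, np.full((3, 6, 6), 100, dtype=np.uint8))
        run_op(
            op_quantification, labelled,
            dirRaw=tmp_path, fileRaw="raw", list="mean, sum, sd, min, max, median",
            dir=tmp_path, file="q.csv",
        )
        table = pd.read_csv(tmp_path / "q.csv")
        assert (table["mean"] == 100.0).all()
        assert (table["sd"] == 0.0).all()
        counts = np.bincount(labelled.data.ravel())
        np.testing.assert_allclose(table["sum"], 100.0 * counts[1:])

    def test_per_label_sums_conserve_masked_total(self, tmp_path):
        rng = np.random.default_rng(13)
        raw = random_grid(rng, shape=(3, 6, 6))
        mask = sparse_mask(rng, shape=(3, 6, 6))
        labelled, _ = run_op(op_label, grid_of(mask, cls=BinaryMask))
        self._save_raw(tmp_path, raw)
        run_op(
            op_quantification, labelled,
            dirRaw=tmp_path, fileRaw="raw", list="sum",
            dir=tmp_path, file="q.csv",
        )
        table = pd.read_csv(tmp_path / "q.csv")
        assert table["sum"].sum() == pytest.approx(
            raw[labelled.data > 0].sum(), abs=1e-9
        )

    def test_extent_mismatch_rejected(self, tmp_path):
        self._save_raw(tmp_path, np.zeros((1, 3, 3), dtype=np.uint8))
        with pytest.raises(ModuleError, match="extents"):
            run_op(
                op_quantification,
                grid_of(np.ones((1, 2, 2), dtype=np.int32), cls=LabelMap),
                dirRaw=tmp_path, fileRaw="raw", list="mean",
                dir=tmp_path, file="q.csv",
            )

    def test_missing_raw_points_at_save_first_convention(self, tmp_path):
        with pytest.raises(ModuleError, match="saved locally first"):
            run_op(
                op_quantification,
                grid_of(np.ones((1, 2, 2), dtype=np.int32), cls=LabelMap),
                dirRaw=tmp_path, fileRaw="nothere", list="mean",
                dir=tmp_path, file="q.csv",
            )


class TestColocNumberingDistances:
    def _pair(self, tmp_path, a, b):
        write_grid(tmp_path / "b.tif", LabelMap(np.asarray(b, dtype=np.int32)))
        return grid_of(np.asarray(a, dtype=np.int32), cls=LabelMap)

    def test_coloc_identical_objects(self, tmp_path):
        a = np.zeros((2, 5, 5), dtype=np.int32)
        a[:, 0:5, 0:5] = 1
        grid = self._pair(tmp_path, a, a)
        run_op(op_coloc, grid, dirRaw=tmp_path, fileRaw="b", dir=tmp_path, file="c.csv")
        table = pd.read_csv(tmp_path / "c.csv")
        assert table.values.tolist() == [[1, 1, 50, 1.0]]

    def test_coloc_disjoint_is_empty_but_distances_reports(self, tmp_path):
        a = np.zeros((1, 6, 6), dtype=np.int32)
        a[0, 0, 0] = 1
        b = np.zeros((1, 6, 6), dtype=np.int32)
        b[0, 5, 5] = 1
        grid = self._pair(tmp_path, a, b)
        run_op(op_coloc, grid, dirRaw=tmp_path, fileRaw="b", dir=tmp_path, file="c.csv")
        assert len(pd.read_csv(tmp_path / "c.csv")) == 0
        run_op(op_distances, grid, dirRaw=tmp_path, fileRaw="b", dir=tmp_path, file="d.csv")
        d = pd.read_csv(tmp_path / "d.csv")
        assert d.loc[0, "nearest"] == 1
        assert d.loc[0, "distance"] == pytest.approx(np.hypot(5, 5))

    def test_coloc_partial_overlap_fraction(self, tmp_path):
        a = np.zeros((1, 2, 4), dtype=np.int32)
        a[0, 0, 0:4] = 1
        b = np.zeros((1, 2, 4), dtype=np.int32)
        b[0, 0, 2:4] = 3
        grid = self._pair(tmp_path, a, b)
        run_op(op_coloc, grid, dirRaw=tmp_path, fileRaw="b", dir=tmp_path, file="c.csv")
        table = pd.read_csv(tmp_path / "c.csv")
        assert table.loc[0, "overlap_fraction_of_A"] == pytest.approx(0.5)

    def test_numbering_counts_centroids_inside(self, tmp_path):
        a = np.zeros((1, 10, 10), dtype=np.int32)
        a[0, 0:6, 0:6] = 1
        b = np.zeros((1, 10, 10), dtype=np.int32)
        b[0, 1, 1] = 1
        b[0, 3, 3] = 2
        b[0, 5, 5] = 3
        b[0, 9, 9] = 4  # outside A
        grid = self._pair(tmp_path, a, b)
        run_op(op_numbering, grid, dirRaw=tmp_path, fileRaw="b", dir=tmp_path, file="n.csv")
        table = pd.read_csv(tmp_path / "n.csv")
        assert table.values.tolist() == [[1, 3]]

    def test_distances_use_calibration(self, tmp_path):
        a = np.zeros((1, 4, 4), dtype=np.int32)
        a[0, 0, 0] = 1
        b = np.zeros((1, 4, 4), dtype=np.int32)
        b[0, 0, 2] = 1
        write_grid(tmp_path / "b.tif", LabelMap(b))
        grid = LabelMap(a, Calibration(0.5, 2.0, "um"))
        run_op(op_distances, grid, dirRaw=tmp_path, fileRaw="b", dir=tmp_path, file="d.csv")
        table = pd.read_csv(tmp_path / "d.csv")
        assert table.loc[0, "distance"] == pytest.approx(2 * 0.5)


class TestTables:
    def test_merge_adds_source_column(self, tmp_path):
        for name in ("a.csv", "b.csv"):
            pd.DataFrame({"label": [1, 2, 3], "v": [1, 2, 3]}).to_csv(
                tmp_path / name, index=False
            )
        run_op(op_mergeTables, dir=tmp_path, list="a.csv, b.csv", file="m.csv")
        table = pd.read_csv(tmp_path / "m.csv")
        assert len(table) == 6
        assert list(table["source"].unique()) == ["a.csv", "b.csv"]

    def test_merge_single_table_adds_source(self, tmp_path):
        pd.DataFrame({"x": [1]}).to_csv(tmp_path / "a.csv", index=False)
        run_op(op_mergeTables, dir=tmp_path, list="a.csv", file="m.csv")
        table = pd.read_csv(tmp_path / "m.csv")
        assert list(table.columns) == ["source", "x"]
        assert len(table) == 1

    def test_merge_union_of_columns(self, tmp_path):
        pd.DataFrame({"label": [1], "v": [2]}).to_csv(tmp_path / "a.csv", index=False)
        pd.DataFrame({"label": [1], "w": [3]}).to_csv(tmp_path / "b.csv", index=False)
        run_op(op_mergeTables, dir=tmp_path, list="a.csv,b.csv", file="m.csv")
        table = pd.read_csv(tmp_path / "m.csv")
        assert {"v", "w"} <= set(table.columns)
        assert table["v"].isna().sum() == 1

    def test_append_joins_on_label(self, tmp_path):
        pd.DataFrame({"label": [1, 2, 3, 4, 5], "volume": range(5)}).to_csv(
            tmp_path / "m.csv", index=False
        )
        pd.DataFrame({"label": [1, 2, 3, 4, 5], "mean": range(5)}).to_csv(
            tmp_path / "q.csv", index=False
        )
        run_op(op_appendTables, dir=tmp_path, list="m.csv, q.csv", file="j.csv")
        table = pd.read_csv(tmp_path / "j.csv")
        assert len(table) == 5
        assert {"label", "volume", "mean"} == set(table.columns)

    def test_append_requires_label_column(self, tmp_path):
        pd.DataFrame({"x": [1]}).to_csv(tmp_path / "a.csv", index=False)
        with pytest.raises(ModuleError, match="label"):
            run_op(op_appendTables, dir=tmp_path, list="a.csv", file="j.csv")


# --------------------------------------------------------------------------
# Processing / calibration / file housekeeping
# --------------------------------------------------------------------------


class TestProcessing:
    def test_crop_full_extent_is_identity(self):
        rng = np.random.default_rng(14)
        grid = grid_of(random_grid(rng))
        out, _ = run_op(op_crop, grid)
        np.testing.assert_array_equal(out.data, grid.data)

    def test_crop_subvolume(self):
        grid = grid_of(np.arange(24).reshape(2, 3, 4))
        out, _ = run_op(op_crop, grid, xmin=1, xmax=3, ymin=0, ymax=2, zmin=1, zmax=2)
        np.testing.assert_array_equal(out.data, grid.data[1:2, 0:2, 1:3])

    @pytest.mark.parametrize("bad", [{"xmin": 3, "xmax": 2}, {"xmax": 99}, {"zmin": -1}])
    def test_crop_bad_bounds_rejected(self, bad):
        with pytest.raises(ModuleError, match="bounds"):
            run_op(op_crop, grid_of(np.zeros((2, 3, 4))), **bad)

    def test_math_add(self):
        grid = grid_of(np.full((1, 2, 2), 5, dtype=np.uint8))
        out, _ = run_op(op_math, grid, operation="add", value=10)
        assert (out.data == 15).all()

    def test_math_clamps_to_dtype(self):
        grid = grid_of(np.full((1, 2, 2), 250, dtype=np.uint8))
        out, _ = run_op(op_math, grid, operation="add", value=100)
        assert (out.data == 255).all()

    def test_math_divide_by_zero_rejected(self):
        with pytest.raises(ModuleError, match="zero"):
            run_op(op_math, grid_of(np.ones((1, 2, 2))), operation="divide", value=0)

    def test_scale_doubles_xy_and_halves_pixel_size(self):
        grid = VoxelGrid(np.zeros((4, 10, 10), dtype=np.uint8), Calibration(0.5, 1.0, "um"))
        out, _ = run_op(op_scale, grid, factorXY=2)
        assert out.data.shape == (4, 20, 20)
        assert out.calibration.pixel_size_xy == pytest.approx(0.25)
        assert out.calibration.pixel_size_z == pytest.approx(1.0)

    def test_scale_label_map_stays_integer_nearest(self):
        labels = np.zeros((1, 4, 4), dtype=np.int32)
        labels[0, 0:2, 0:2] = 7
        out, _ = run_op(op_scale, grid_of(labels, cls=LabelMap), factorXY=2)
        assert isinstance(out, LabelMap)
        assert set(np.unique(out.data)) == {0, 7}


class TestCalibrationOps:
    def test_apply_then_volume_arithmetic(self, tmp_path):
        labels = np.zeros((4, 10, 10), dtype=np.int32)
        labels[0].flat[:100] = 1
        grid, _ = run_op(
            op_calibration, grid_of(labels, cls=LabelMap), xy=0.2, z=1.0, unit="micron"
        )
        run_op(op_measurement, grid, list="volume", dir=tmp_path, file="v.csv")
        assert pd.read_csv(tmp_path / "v.csv").loc[0, "volume"] == pytest.approx(4.0)

    def test_save_load_roundtrip(self, tmp_path):
        grid = VoxelGrid(np.zeros((1, 2, 2)), Calibration(0.25, 1.5, "micron"))
        run_op(op_saveCalibration, grid, dir=tmp_path, file="cal.txt")
        other = grid_of(np.zeros((1, 2, 2)))
        out, _ = run_op(op_loadCalibration, other, dir=tmp_path, file="cal.txt")
        assert out.calibration == grid.calibration

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ModuleError):
            run_op(op_calibration, grid_of(np.zeros((1, 2, 2))), xy=0, z=1)


class TestFileOps:
    def test_save_appends_tif_and_keeps_current(self, tmp_path):
        grid = grid_of(np.ones((1, 2, 2), dtype=np.uint8))
        out, _ = run_op(op_save, grid, dir=tmp_path, file="x")
        assert (tmp_path / "x.tif").exists()
        assert out is grid

    def test_delete_list_with_missing_file_warns_deletes_rest(self, tmp_path):
        (tmp_path / "a.tif").write_bytes(b"x")
        (tmp_path / "b.csv").write_text("x\n")
        _, state = run_op(op_deleteList, dir=tmp_path, list="a, gone.csv, b.csv")
        assert not (tmp_path / "a.tif").exists()
        assert not (tmp_path / "b.csv").exists()
        assert any("gone.csv" in w for w in state.warnings)
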