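"""The three 3D filters: opening, object assembly, boundary behavior at the
published thresholds, and exact recovery on scenes with distractors."""

import numpy as np
import pytest

from blebcount.postprocess import (
    PostprocessConfig,
    assemble_objects,
    count_blebs,
    filter_size,
    filter_slice_thickness,
    filter_travelling,
    open_binary,
)


def paint_box(stack, z0, span, y0, x0, h, w):
    stack[z0 : z0 + span, y0 : y0 + h, x0 : x0 + w] = 1


def paint_moving_disc(stack, z0, span, start_yx, step_yx, r=4):
    """Blob whose per-slice centroid moves by step_yx each slice; slices are
    connected via a 1-px overlap column at the trailing edge when the step
    is small, otherwise intentionally disconnected."""
    nz, ny, nx = stack.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    for i in range(span):
        yc = start_yx[0] + i * step_yx[0]
        xc = start_yx[1] + i * step_yx[1]
        stack[z0 + i][(yy - yc) ** 2 + (xx - xc) ** 2 <= r * r] = 1


class TestOpenBinary:
    def test_empty_stack_stays_empty(self):
        assert open_binary(np.zeros((2, 8, 8), np.uint8), 1).sum() == 0

    def test_isolated_pixel_removed(self):
        stack = np.zeros((1, 9, 9), np.uint8)
        stack[0, 4, 4] = 1
        assert open_binary(stack, 1).sum() == 0

    def test_matches_min_then_max_filter_oracle(self):
        from skimage.morphology import disk

        rng = np.random.default_rng(0)
        stack = (rng.random((2, 20, 20)) > 0.4).astype(np.uint8)
        selem = disk(1).astype(bool)
        out = open_binary(stack, 1)
        k = selem.shape[0] // 2
        for z in range(2):
            padded = np.pad(stack[z].astype(bool), k, constant_values=False)
            eroded = np.zeros_like(stack[z], dtype=bool)
            for y in range(20):
                for x in range(20):
                    eroded[y, x] = padded[y : y + 2 * k + 1, x : x + 2 * k + 1][selem].all()
            pade = np.pad(eroded, k, constant_values=False)
            dilated = np.zeros_like(eroded)
            for y in range(20):
                for x in range(20):
                    dilated[y, x] = pade[y : y + 2 * k + 1, x : x + 2 * k + 1][selem].any()
            assert np.array_equal(out[z].astype(bool), dilated)

    def test_large_disc_interior_preserved(self):
        stack = np.zeros((1, 21, 21), np.uint8)
        yy, xx = np.mgrid[0:21, 0:21]
        stack[0][(yy - 10) ** 2 + (xx - 10) ** 2 <= 36] = 1
        out = open_binary(stack, 1)
        assert out[0, 10, 10] == 1
        assert out.sum() >= 0.9 * stack.sum()

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            open_binary(np.zeros((1, 4, 4)), -1)


def flood_fill_label(stack, connectivity=26):
    """Oracle: brute-force BFS connected-component labelling."""
    stack = stack > 0
    nz, ny, nx = stack.shape
    if connectivity == 26:
        neigh = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                 for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    labels = np.zeros(stack.shape, int)
    cur = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if stack[z, y, x] and not labels[z, y, x]:
                    cur += 1
                    queue = [(z, y, x)]
                    labels[z, y, x] = cur
                    while queue:
                        cz, cy, cx = queue.pop()
                        for dz, dy, dx in neigh:
                            pz, py, px = cz + dz, cy + dy, cx + dx
                            if (0 <= pz < nz and 0 <= py < ny and 0 <= px < nx
                                    and stack[pz, py, px] and not labels[pz, py, px]):
                                labels[pz, py, px] = cur
                                queue.append((pz, py, px))
    return labels, cur


class TestAssembleObjects:
    def test_empty_stack_gives_no_objects(self):
        assert assemble_objects(np.zeros((3, 8, 8), np.uint8)) == []

    def test_solid_cube(self):
        stack = np.zeros((5, 8, 8), np.uint8)
        paint_box(stack, 1, 3, 2, 2, 3, 3)
        (obj,) = assemble_objects(stack)
        assert obj.span == 3
        assert obj.voxel_count == 27
        assert np.allclose(obj.centroids, [[3.0, 3.0]] * 3)
        assert obj.max_consecutive_shift() == 0.0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(1)
        stack = (rng.random((4, 12, 12)) > 0.7).astype(np.uint8)
        objects = assemble_objects(stack, connectivity)
        ref_labels, n_ref = flood_fill_label(stack, connectivity)
        assert len(objects) == n_ref
        sizes = sorted(o.voxel_count for o in objects)
        ref_sizes = sorted(np.bincount(ref_labels.ravel())[1:].tolist())
        assert sizes == ref_sizes

    def test_diagonal_touch_merges_only_with_26(self):
        stack = np.zeros((2, 4, 4), np.uint8)
        stack[0, 0, 0] = 1
        stack[1, 1, 1] = 1
        assert len(assemble_objects(stack, 26)) == 1
        assert len(assemble_objects(stack, 6)) == 2


class TestFilterBoundaries:
    def _objects_with_spans(self, spans):
        stack = np.zeros((12, 30, 30 * len(spans)), np.uint8)
        for i, s in enumerate(spans):
            paint_box(stack, 0, s, 4, 30 * i + 4, 6, 6)
        return assemble_objects(stack), stack

    def test_span_5_kept_span_4_removed_at_default(self):
        objects, _ = self._objects_with_spans([4, 5])
        kept = filter_slice_thickness(objects, 5)
        assert [o.span for o in kept] == [5]

    def test_span_sweep_matches_threshold(self):
        spans = list(range(1, 11))
        objects, _ = self._objects_with_spans(spans)
        kept = filter_slice_thickness(objects, 5)
        assert sorted(o.span for o in kept) == [s for s in spans if s >= 5]

    def test_min_slices_one_keeps_everything(self):
        objects, _ = self._objects_with_spans([1, 2, 3])
        assert len(filter_slice_thickness(objects, 1)) == 3

    def test_shift_15_kept_16_removed(self):
        stack = np.zeros((6, 40, 160), np.uint8)
        # axis-aligned steps: exactly 15 px then exactly 16 px
        paint_moving_disc(stack, 0, 2, (20, 20), (0, 15), r=8)
        objects = assemble_objects(stack)
        assert len(objects) == 1
        assert np.isclose(objects[0].max_consecutive_shift(), 15.0)
        assert filter_travelling(objects, 15.0) == objects

        stack2 = np.zeros((6, 40, 160), np.uint8)
        paint_moving_disc(stack2, 0, 2, (20, 20), (0, 16), r=9)
        objects2 = assemble_objects(stack2)
        assert len(objects2) == 1
        assert np.isclose(objects2[0].max_consecutive_shift(), 16.0)
        assert filter_travelling(objects2, 15.0) == []

    def test_diagonal_12_12_shift_removed(self):
        # sqrt(12^2 + 12^2) ~ 16.97 > 15
        stack = np.zeros((4, 60, 60), np.uint8)
        paint_moving_disc(stack, 0, 2, (20, 20), (12, 12), r=9)
        objects = assemble_objects(stack)
        assert len(objects) == 1
        assert np.isclose(objects[0].max_consecutive_shift(), np.hypot(12, 12))
        assert filter_travelling(objects, 15.0) == []

    def test_static_centroid_kept(self):
        stack = np.zeros((6, 12, 12), np.uint8)
        paint_box(stack, 0, 6, 3, 3, 5, 5)
        objects = assemble_objects(stack)
        assert filter_travelling(objects, 15.0) == objects

    def test_size_100_kept_99_removed(self):
        stack = np.zeros((6, 12, 40), np.uint8)
        paint_box(stack, 0, 4, 2, 2, 5, 5)    # 100 voxels
        paint_box(stack, 0, 1, 2, 20, 9, 11)  # 99 voxels
        objects = assemble_objects(stack)
        assert sorted(o.voxel_count for o in objects) == [99, 100]
        kept = filter_size(objects, 100)
        assert [o.voxel_count for o in kept] == [100]

    def test_size_sweep_matches_threshold(self):
        sizes = list(range(50, 151, 10))
        stack = np.zeros((2, 20, 30 * len(sizes)), np.uint8)
        for i, s in enumerate(sizes):
            # 1-slice slab of exactly s voxels: 10 x (s // 10) plus remainder row
            w = s // 10
            stack[0, 0:10, 30 * i : 30 * i + w] = 1
            stack[0, 0, 30 * i + w : 30 * i + w + s % 10] = 1
        objects = assemble_objects(stack)
        assert sorted(o.voxel_count for o in objects) == sizes
        kept = filter_size(objects, 100)
        assert sorted(o.voxel_count for o in kept) == [s for s in sizes if s >= 100]

    def test_min_size_one_keeps_everything(self):
        objects, _ = self._objects_with_spans([2, 3])
        assert len(filter_size(objects, 1)) == 2

    def test_filters_are_idempotent_restrictions(self):
        rng = np.random.default_rng(2)
        stack = (rng.random((8, 30, 30)) > 0.8).astype(np.uint8)
        objects = assemble_objects(stack)
        for filt in (
            lambda o: filter_slice_thickness(o, 3),
            lambda o: filter_travelling(o, 5.0),
            lambda o: filter_size(o, 10),
        ):
            once = filt(objects)
            assert set(o.id for o in once) <= set(o.id for o in objects)
            assert filt(once) == once


class TestCountBlebs:
    def test_empty_stack_counts_zero(self):
        catalog = count_blebs(np.zeros((4, 16, 16), np.uint8))
        assert catalog.count == 0
        assert catalog.eliminations["assembled"] == 0

    def test_recovers_exactly_the_qualifying_blebs(self, distractor_scene):
        _, _, truth = distractor_scene
        catalog = count_blebs(truth.all_objects_mask, PostprocessConfig())
        assert catalog.count == len(truth.qualifying_ids())
        # each distractor class is removed by its own filter
        n_travel = sum(o.cls == "travel_segment" for o in truth.objects)
        assert catalog.eliminations["travelling"] == n_travel
        # survivors sit where the qualifying blebs were planted
        planted = [
            (np.mean([c[0] for c in o.centroids]), np.mean([c[1] for c in o.centroids]))
            for o in truth.objects if o.qualifies_as_bleb
        ]
        for fy, fx in (o.static_centroid() for o in catalog.objects):
            nearest = min(np.hypot(fy - py, fx - px) for py, px in planted)
            assert nearest < 2.0

    def test_count_monotone_in_min_slices(self, distractor_scene):
        _, _, truth = distractor_scene
        counts = [
            count_blebs(truth.all_objects_mask,
                        PostprocessConfig(min_slices=m)).count
            for m in (1, 3, 5, 7, 10)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_provenance_records_config_and_eliminations(self, distractor_scene):
        _, _, truth = distractor_scene
        catalog = count_blebs(truth.all_objects_mask)
        prov = catalog.provenance()
        assert prov["config"]["min_slices"] == 5
        assert prov["config"]["max_centroid_shift"] == 15.0
        assert prov["config"]["min_size"] == 100
        assert prov["count"] == catalog.count
        assert set(prov["eliminations"]) == {
            "assembled", "slice_thickness", "travelling", "opening", "size"
        }

    def test_survivor_mask_holds_exactly_the_survivors(self, distractor_scene):
        _, _, truth = distractor_scene
        catalog = count_blebs(truth.all_objects_mask)
        mask = catalog.survivor_mask()
        assert int(mask.sum()) == sum(o.voxel_count for o in catalog.objects)
        assert len(assemble_objects(mask, catalog.config.connectivity)) == catalog.count
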