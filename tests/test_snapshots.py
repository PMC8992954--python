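"""Snapshot-panel primitives and per-study rendering."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from mrdqc.niftiio import LabelMap, VoxelGrid, GeometryError
from mrdqc.snapshots import (
    PLANE_AXES,
    RenderConfig,
    composite_overlay,
    crosshair_target,
    max_area_slice,
    render_density_panel,
    render_study,
    window_for_display,
)


def _labelmap(data):
    return LabelMap(grid=VoxelGrid(np.asarray(data, np.int16), np.eye(4)))


class TestMaxAreaSlice:
    def test_known_areas_with_tie_to_lowest(self):
        # per-axial-slice foreground areas [0, 5, 9, 9, 2] -> index 2
        data = np.zeros((5, 5, 5), np.int16)
        for k, area in enumerate([0, 5, 9, 9, 2]):
            data.reshape(25, 5)[:area, k] = 1
        assert max_area_slice(_labelmap(data), "axial") == 2

    def test_empty_map_falls_back_to_middle(self):
        assert max_area_slice(_labelmap(np.zeros((3, 3, 11))), "axial") == 5

    def test_single_voxel(self):
        data = np.zeros((9, 9, 9), np.int16)
        data[1, 2, 7] = 1
        assert max_area_slice(_labelmap(data), "axial") == 7
        assert max_area_slice(_labelmap(data), "sagittal") == 1
        assert max_area_slice(_labelmap(data), "coronal") == 2

    def test_agrees_with_brute_force_on_random_masks(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(3, 9, size=3))
            data = (rng.random(shape) < 0.2).astype(np.int16)
            m = _labelmap(data)
            for plane, axis in PLANE_AXES.items():
                counts = [np.count_nonzero(np.take(data, i, axis=axis))
                          for i in range(shape[axis])]
                expect = int(np.argmax(counts)) if max(counts) else shape[axis] // 2
                assert max_area_slice(m, plane) == expect


class TestWindowForDisplay:
    def test_full_range_is_linear_ramp(self):
        vals = np.arange(101.0).reshape(1, 101)
        out = window_for_display(vals, 0, 100)
        assert np.allclose(out, vals / 100.0)

    def test_constant_slice_maps_to_zeros(self):
        assert not window_for_display(np.full((4, 4), 7.0)).any()

    def test_outlier_clipped_to_one(self):
        vals = np.arange(101.0)
        vals[50] = 1e6
        out = window_for_display(vals.reshape(1, 101), 1, 99)
        assert out[0, 50] == 1.0
        lo, hi = np.percentile(vals, [1, 99])
        inside = (vals > lo) & (vals < hi)
        assert (out[0, inside] > 0).all() and (out[0, inside] < 1).all()

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            window_for_display(np.zeros((2, 2)), 60, 40)


class TestCompositeOverlay:
    def test_empty_masks_reproduce_grayscale(self):
        gray = np.random.default_rng(0).random((4, 4))
        out = composite_overlay(gray, [(np.zeros((4, 4), bool), (1, 0, 0))])
        assert np.allclose(out, np.repeat(gray[..., None], 3, axis=2))

    def test_alpha_one_full_mask_is_solid_color(self):
        out = composite_overlay(np.zeros((3, 3)), [(np.ones((3, 3), bool), (0.2, 0.4, 0.6))],
                                alpha=1.0)
        assert np.allclose(out, np.broadcast_to((0.2, 0.4, 0.6), (3, 3, 3)))

    def test_later_mask_wins_overlap(self):
        # 2x2: first mask covers left column, second covers top row; the
        # (0,0) overlap pixel must show the second color
        gray = np.zeros((2, 2))
        m1 = np.array([[1, 0], [1, 0]], bool)
        m2 = np.array([[1, 1], [0, 0]], bool)
        out = composite_overlay(gray, [(m1, (1, 0, 0)), (m2, (0, 0, 1))], alpha=1.0)
        assert np.allclose(out[0, 0], (0, 0, 1))
        assert np.allclose(out[1, 0], (1, 0, 0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            composite_overlay(np.zeros((3, 3)), [(np.zeros((2, 2), bool), (1, 0, 0))])


class TestCrosshairTarget:
    def test_global_max_inside_roi(self):
        img = np.zeros((8, 8, 8))
        img[3, 4, 5] = 10.0
        assert crosshair_target(VoxelGrid(img, np.eye(4)),
                                _labelmap(np.ones((8, 8, 8)))) == (3, 4, 5)

    def test_masked_argmax_ignores_outside_max(self):
        img = np.zeros((4, 4, 4))
        img[3, 3, 3] = 100.0  # outside roi
        img[1, 1, 1] = 5.0
        roi = np.zeros((4, 4, 4), np.int16)
        roi[:2, :2, :2] = 1
        assert crosshair_target(VoxelGrid(img, np.eye(4)), _labelmap(roi)) == (1, 1, 1)

    def test_empty_roi_falls_back_to_center(self):
        g = VoxelGrid(np.zeros((10, 10, 10)), np.eye(4))
        assert crosshair_target(g, _labelmap(np.zeros((10, 10, 10)))) == (5, 5, 5)

    def test_agrees_with_brute_force_on_random_grids(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(3, 7, size=3))
            img = rng.random(shape)
            roi = (rng.random(shape) < 0.3).astype(np.int16)
            got = crosshair_target(VoxelGrid(img, np.eye(4)), _labelmap(roi))
            if not roi.any():
                assert got == tuple(s // 2 for s in shape)
                continue
            best, best_val = None, -np.inf
            for idx in np.ndindex(shape):
                if roi[idx] and (img[idx] > best_val
                                 or (img[idx] == best_val and idx < best)):
                    best, best_val = idx, img[idx]
            assert got == best


class TestDensityPanel:
    def test_nonempty_region_renders(self, tmp_path):
        img = VoxelGrid(np.random.default_rng(0).normal(size=(8, 8, 8)), np.eye(4))
        region = _labelmap(np.ones((8, 8, 8)))
        spec = render_density_panel(img, [(region, "brain", (0.5, 0.5, 0.5))],
                                    tmp_path / "d.png")
        assert spec.status == "rendered"
        assert Path(spec.path).exists()

    def test_all_regions_empty_is_skipped(self, tmp_path):
        img = VoxelGrid(np.zeros((4, 4, 4)), np.eye(4))
        spec = render_density_panel(img, [(_labelmap(np.zeros((4, 4, 4))), "x", (1, 0, 0))],
                                    tmp_path / "d.png")
        assert spec.status == "skipped_missing_input"
        assert not (tmp_path / "d.png").exists()


class TestRenderStudy:
    def test_complete_study_renders_all_panels(self, clean_study, tmp_path):
        rec, _ = clean_study
        snaps = render_study(rec, tmp_path)
        assert snaps.panels
        assert all(p.status == "rendered" for p in snaps.panels)
        for p in snaps.panels:
            assert Path(p.path).exists()
        # sidecar inventory matches
        payload = json.loads((tmp_path / f"{rec.study_id}_snapshots.json").read_text())
        assert len(payload["panels"]) == len(snaps.panels)

    def test_panel_inventory_unique_paths(self, clean_study, tmp_path):
        rec, _ = clean_study
        snaps = render_study(rec, tmp_path)
        paths = [p.path for p in snaps.panels]
        assert len(paths) == len(set(paths))

    def test_missing_modality_skips_only_its_panels(self, clean_study, tmp_path):
        rec, _ = clean_study
        import copy
        rec2 = copy.deepcopy(rec)
        del rec2.anatomical["FLAIR"]
        snaps = render_study(rec2, tmp_path)
        for p in snaps.panels:
            if p.modality == "FLAIR":
                assert p.status == "skipped_missing_input"
            else:
                assert p.status == "rendered"

    def test_registration_slices_identical_across_modalities(self, clean_study, tmp_path):
        rec, _ = clean_study
        snaps = render_study(rec, tmp_path)
        reg = [p for p in snaps.panels if p.kind == "registration_check"]
        for plane in ("axial", "sagittal"):
            indices = {p.slice_index for p in reg if p.plane == plane}
            assert len(indices) == 1

    def test_rerender_is_byte_identical(self, clean_study, tmp_path):
        rec, _ = clean_study
        def digests(d):
            render_study(rec, d)
            return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(Path(d).glob("*.png"))}
        assert digests(tmp_path / "a") == digests(tmp_path / "b")


def test_misregistration_visible_in_mask_image_overlap(tmp_path):
    """A 10-degree rotated modality agrees less with the brain-mask overlay
    than the co-registered original does."""
    from mrdqc.niftiio import read_label_map, read_volume, reorient_canonical, reorient_label_map
    from mrdqc.phantom import FailureMode, PhantomParams, inject_failure, make_phantom_study

    def overlap(rec):
        img = reorient_canonical(read_volume(rec.anatomical["FLAIR"]))
        brain = reorient_label_map(read_label_map(rec.annotations["brain_mask"]))
        fg = brain.grid.data != 0
        support = img.data > np.percentile(img.data, 60)
        return (fg & support).sum() / fg.sum()

    rec, truth = make_phantom_study(PhantomParams(seed=7), tmp_path, "s")
    clean = overlap(rec)
    rec2, _ = inject_failure(rec, FailureMode(mode="misregistration", rotation_deg=10),
                             seed=1, truth=truth)
    assert overlap(rec2) < clean
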