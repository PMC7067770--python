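"""Segmentation steps: oracle equivalence on small volumes plus pipeline behaviour."""

import numpy as np
import pytest
from dataclasses import replace

from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from myotomo.phantom import PhantomSpec, generate_phantom
from myotomo.preprocess import denoise
from myotomo.segment import (
    SegmentationError,
    SegmentationParams,
    apply_manual_overrides,
    auto_seed,
    bundle_contour,
    close_mask,
    fill_holes,
    invert_mask,
    region_grow,
    remove_islands,
    segment_pipeline,
    subtract_masks,
    tophat_refine,
)

from oracles import close_bf, fill_holes_bf, region_grow_bf, remove_islands_bf

small_masks = hnp.arrays(bool, (4, 5, 5))


class TestRegionGrow:
    def test_constant_volume_grows_everywhere(self):
        vol = np.full((4, 5, 5), 80.0)
        assert region_grow(vol, [(1, 2, 2)], tolerance=0.0).all()

    def test_two_level_step_selects_only_seed_side(self):
        vol = np.full((4, 6, 6), 50.0)
        vol[:, :, 3:] = 200.0
        grown = region_grow(vol, [(0, 0, 0)], tolerance=10.0)
        assert np.array_equal(grown, vol == 50.0)

    def test_zero_tolerance_on_unique_values_keeps_seed_only(self):
        vol = np.arange(27, dtype=float).reshape(3, 3, 3) * 10
        grown = region_grow(vol, [(1, 1, 1)], tolerance=0.0)
        # the seed stays in its region even when nothing matches its
        # neighbourhood mean exactly
        assert grown[1, 1, 1]
        assert grown.sum() == 1

    def test_seed_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            region_grow(np.zeros((3, 3, 3)), [(5, 0, 0)], 1.0)

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            region_grow(np.zeros((3, 3, 3)), [], 1.0)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_flood_fill_oracle(self, rng, connectivity):
        for _ in range(10):
            vol = rng.integers(0, 4, size=(6, 6, 6)).astype(float) * 50
            seed = tuple(rng.integers(0, 6, size=3))
            ours = region_grow(vol, [seed], 25.0, connectivity)
            ref = region_grow_bf(vol, seed, 25.0, connectivity)
            assert np.array_equal(ours, ref)


class TestMaskAlgebra:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(small_masks)
    def test_invert_is_an_involution_and_partitions(self, m):
        assert np.array_equal(invert_mask(invert_mask(m)), m)
        assert m.sum() + invert_mask(m).sum() == m.size

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(small_masks, small_masks)
    def test_subtract_set_algebra(self, c, f):
        s = subtract_masks(c, f)
        assert s.sum() == c.sum() - (c & f).sum()
        assert not (s & f).any()

    def test_subtract_identities(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert not subtract_masks(m, m).any()
        assert np.array_equal(subtract_masks(m, np.zeros_like(m)), m)

    def test_subtract_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_masks(np.ones((2, 2, 2), bool), np.ones((3, 3, 3), bool))


class TestRemoveIslands:
    def test_min_island_one_is_identity(self, rng):
        m = rng.random((5, 5, 5)) < 0.3
        assert np.array_equal(remove_islands(m, 1), m)

    def test_keeps_only_large_components(self):
        m = np.zeros((4, 10, 10), dtype=bool)
        m[1, 1:6, 1:3] = True  # 10-voxel slab
        m[3, 8, 6:9] = True  # 3-voxel strip
        out = remove_islands(m, 5, 26)
        assert out[1].sum() == 10 and not out[3].any()

    def test_empty_mask_passthrough(self):
        m = np.zeros((3, 3, 3), bool)
        assert not remove_islands(m, 5).any()

    def test_matches_component_labelling_oracle(self, rng):
        for _ in range(10):
            m = rng.random((6, 6, 6)) < 0.25
            assert np.array_equal(remove_islands(m, 4, 26), remove_islands_bf(m, 4, 26))


class TestCloseMask:
    def test_convex_solid_unchanged(self):
        m = np.zeros((9, 9, 9), bool)
        m[3:6, 3:6, 3:6] = True
        assert np.array_equal(close_mask(m, 1), m)

    def test_idempotent(self, rng):
        m = rng.random((7, 7, 7)) < 0.3
        once = close_mask(m, 2)
        assert np.array_equal(close_mask(once, 2), once)

    def test_one_voxel_gap_bridged(self):
        m = np.zeros((5, 5, 9), bool)
        m[1:4, 1:4, 1:4] = True
        m[1:4, 1:4, 5:8] = True
        out = close_mask(m, 1)
        assert out[2, 2, 4]

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(small_masks)
    def test_extensive(self, m):
        assert (close_mask(m, 1) | m).sum() == close_mask(m, 1).sum()

    def test_matches_minkowski_oracle(self, rng):
        for radius in (1, 2):
            for _ in range(5):
                m = rng.random((7, 7, 7)) < 0.2
                assert np.array_equal(close_mask(m, radius), close_bf(m, radius))


class TestFillHoles:
    def test_hollow_cube_becomes_solid(self):
        m = np.zeros((7, 7, 7), bool)
        m[1:6, 1:6, 1:6] = True
        m[2:5, 2:5, 2:5] = False
        out = fill_holes(m)
        assert out[1:6, 1:6, 1:6].all()

    def test_border_connected_channel_not_filled(self):
        m = np.zeros((7, 7, 7), bool)
        m[1:6, 1:6, 1:6] = True
        m[2:5, 2:5, 2:5] = False
        m[3, 3, 0:5] = False  # open channel from the cavity to the border
        assert np.array_equal(fill_holes(m), m)

    def test_idempotent(self, rng):
        m = rng.random((7, 7, 7)) < 0.4
        once = fill_holes(m)
        assert np.array_equal(fill_holes(once), once)

    def test_matches_border_flood_fill_oracle(self, rng):
        for _ in range(10):
            m = rng.random((6, 6, 6)) < 0.45
            assert np.array_equal(fill_holes(m, 6), fill_holes_bf(m, 6))


class TestBundleContour:
    def test_contains_fibers_and_recovers_truth(self, small_phantom):
        contour = bundle_contour(small_phantom.truth_fiber)
        assert (small_phantom.truth_fiber & ~contour).sum() == 0
        inter = (contour & small_phantom.truth_contour).sum()
        union = (contour | small_phantom.truth_contour).sum()
        assert inter / union >= 0.90

    def test_empty_fiber_mask_gives_empty_contour(self):
        assert not bundle_contour(np.zeros((4, 6, 6), bool)).any()


class TestTophatRefine:
    def test_constant_volume_gives_empty_refinement(self):
        vol = np.full((4, 20, 20), 77.0)
        space = np.ones((4, 20, 20), bool)
        assert not tophat_refine(vol, space).any()

    def test_refined_is_subset_of_candidate(self, small_phantom):
        den = denoise(small_phantom.intensity)
        params = SegmentationParams(apply_tophat=False)
        res = segment_pipeline(den, params)
        refined = tophat_refine(den, res.space, SegmentationParams(), region=res.contour)
        assert not (refined & ~res.space).any()

    @pytest.mark.parametrize("noise_sigma", [10.0, 20.0])
    def test_refinement_does_not_degrade_truth_overlap(self, noise_sigma):
        spec = PhantomSpec(shape=(12, 64, 64), n_fibers=12, noise_sigma=noise_sigma, seed=31)
        p = generate_phantom(spec)
        den = denoise(p.intensity)
        res = segment_pipeline(den, SegmentationParams(apply_tophat=False))
        refined = tophat_refine(den, res.space, SegmentationParams(), region=res.contour)

        def jaccard(a, b):
            return (a & b).sum() / (a | b).sum()

        assert jaccard(refined, p.truth_space) >= jaccard(res.space, p.truth_space)


class TestManualOverrides:
    def test_empty_overrides_are_identity(self, rng):
        m = rng.random((4, 4, 4)) < 0.5
        assert np.array_equal(apply_manual_overrides(m), m)

    def test_added_blob_increases_count_exactly(self):
        m = np.zeros((4, 6, 6), bool)
        m[0, 0, 0] = True
        add = np.zeros_like(m)
        add[1, 1:6, 1] = True  # 5-voxel blob
        add[0, 0, 0] = True  # already set
        out = apply_manual_overrides(m, add=add)
        assert out.sum() == m.sum() + 5

    def test_overlapping_add_remove_rejected(self):
        m = np.zeros((3, 3, 3), bool)
        add = np.zeros_like(m)
        rem = np.zeros_like(m)
        add[1, 1, 1] = rem[1, 1, 1] = True
        with pytest.raises(ValueError, match="ambiguous"):
            apply_manual_overrides(m, add, rem)


class TestSegmentPipeline:
    def test_noise_free_recovery_is_exact_inside_contour(self):
        p = generate_phantom(PhantomSpec(noise_sigma=0.0, seed=5))
        res = segment_pipeline(p.intensity)
        assert np.array_equal(res.space, p.truth_space & res.contour)

    def test_provenance_lists_steps_in_order(self, small_phantom):
        res = segment_pipeline(denoise(small_phantom.intensity))
        steps = [s["step"] for s in res.provenance]
        core = [
            "region_grow",
            "invert",
            "remove_islands",
            "bundle_contour",
            "subtract",
            "tophat_refine",
        ]
        assert [s for s in steps if s in core] == core

    def test_result_masks_partition(self, small_phantom):
        res = segment_pipeline(denoise(small_phantom.intensity))
        assert not (res.fiber & res.space).any()
        assert np.array_equal(res.fiber | res.space, res.contour)

    def test_space_fraction_recovered_on_default_phantom(self):
        spec = PhantomSpec(shape=(16, 96, 96), noise_sigma=10.0, seed=17)
        p = generate_phantom(spec)
        res = segment_pipeline(denoise(p.intensity))
        est = res.space.sum() / res.contour.sum()
        assert abs(est - p.truth_space_fraction) <= 0.05

    def test_featureless_volume_raises_segmentation_error(self):
        vol = np.full((8, 32, 32), 120.0, dtype=np.float32)
        with pytest.raises(SegmentationError):
            segment_pipeline(vol)

    def test_auto_seed_finds_dark_voxel(self, small_phantom):
        z, y, x = auto_seed(small_phantom.intensity)
        data = small_phantom.intensity.data
        assert data[z, y, x] <= np.percentile(data, 2)
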