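"""Draw-and-refine threshold methods, including the background-adaptive rule."""

import numpy as np
import pytest

from petseg import (
    EmptyMaskError,
    GridMismatchError,
    ROIMask,
    SegmentationWarning,
    compute_nestle_threshold,
    dice,
    rasterize_sketch,
    segment_absolute_threshold,
    segment_nestle,
    segment_relative_threshold,
)
from conftest import full_mask, make_grid, make_mask, make_volume


def line_volume(uptakes, spacing=(1.0, 1.0, 1.0)):
    """A 1 x 1 x n volume whose z-profile is the given uptake list."""
    return make_volume(np.asarray(uptakes, dtype=float).reshape(1, 1, -1), spacing)


class TestAbsoluteThreshold:
    def test_all_above_threshold_retained(self):
        vol = make_volume(np.full((5, 5, 5), 10.0))
        out = segment_absolute_threshold(vol, full_mask(vol.grid), 2.5)
        assert out.voxel_count == 125

    def test_tie_rule_retains_exact_threshold(self):
        vol = line_volume([1, 2, 2.5, 3, 4])
        out = segment_absolute_threshold(vol, full_mask(vol.grid), 2.5)
        assert out.voxel_count == 3
        assert list(np.flatnonzero(out.indicator.ravel())) == [2, 3, 4]

    def test_nothing_above_threshold_warns_and_returns_empty(self):
        vol = make_volume(np.full((4, 4, 4), 1.0))
        with pytest.warns(SegmentationWarning):
            out = segment_absolute_threshold(vol, full_mask(vol.grid), 2.5)
        assert out.is_empty

    def test_grid_mismatch_and_empty_sketch_rejected(self):
        vol = make_volume(np.full((4, 4, 4), 5.0))
        other = make_volume(np.full((5, 5, 5), 5.0))
        with pytest.raises(GridMismatchError):
            segment_absolute_threshold(vol, full_mask(other.grid))
        with pytest.raises(EmptyMaskError):
            segment_absolute_threshold(vol, make_mask(vol.grid, []))

    def test_invariant_to_uptake_outside_sketch(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 10, (6, 6, 6))
        sketch = make_mask(make_grid((6, 6, 6)), [(2, 2, 2), (3, 3, 3), (1, 4, 2)])
        out1 = segment_absolute_threshold(make_volume(base), sketch, 2.5)
        modified = base.copy()
        modified[~sketch.indicator] = rng.uniform(0, 100, (~sketch.indicator).sum())
        out2 = segment_absolute_threshold(make_volume(modified), sketch, 2.5)
        assert np.array_equal(out1.indicator, out2.indicator)


class TestRelativeThreshold:
    def test_uniform_sketch_fully_retained(self):
        vol = make_volume(np.full((4, 4, 4), 7.0))
        out = segment_relative_threshold(vol, full_mask(vol.grid), 0.9)
        assert out.voxel_count == 64

    def test_half_max_inclusive(self):
        vol = line_volume([10, 6, 5, 3, 1])
        out = segment_relative_threshold(vol, full_mask(vol.grid), 0.5)
        assert list(np.flatnonzero(out.indicator.ravel())) == [0, 1, 2]

    def test_contains_argmax_and_nesting(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            vol = make_volume(rng.uniform(0, 12, (7, 7, 7)))
            sketch = ROIMask(vol.grid, rng.random(vol.grid.shape) < 0.5)
            if sketch.is_empty:
                continue
            r40 = segment_relative_threshold(vol, sketch, 0.4)
            r50 = segment_relative_threshold(vol, sketch, 0.5)
            assert r50.issubset(r40)
            assert r40.issubset(sketch)
            masked = np.where(sketch.indicator, vol.values, -np.inf)
            assert r50.indicator[np.unravel_index(np.argmax(masked), vol.grid.shape)]


class TestNestleThreshold:
    def test_uniform_lesion_zero_background(self, uniform_sphere_case):
        case = uniform_sphere_case
        sketch = rasterize_sketch(case.sketch, case.volume.grid)
        res = compute_nestle_threshold(case.volume, sketch, beta=0.30)
        assert res.imax == 10.0
        assert res.i70 == 10.0
        assert res.ibgd == 0.0
        assert res.tn == pytest.approx(3.0)
        assert res.tn == res.beta * res.i70 + res.ibgd

    def test_arithmetic_i70_8_ibgd_1(self):
        # lesion plateau 8.0 occupying the centre, background exactly 1.0:
        # I70 = 8.0 (only plateau voxels exceed 5.6), Ibgd = 1.0, tN = 3.4
        grid = make_grid((31, 31, 31), (2.0, 2.0, 2.0))
        values = np.full(grid.shape, 1.0)
        values[14:17, 14:17, 14:17] = 8.0
        vol = make_volume(values, (2.0, 2.0, 2.0))
        region = ROIMask(grid, values == 8.0)
        res = compute_nestle_threshold(vol, region, beta=0.30)
        assert res.i70 == pytest.approx(8.0)
        assert res.ibgd == pytest.approx(1.0)
        assert res.tn == pytest.approx(0.30 * 8.0 + 1.0)

    def test_hot_background_empties_shell(self):
        grid = make_grid((31, 31, 31), (2.0, 2.0, 2.0))
        values = np.full(grid.shape, 3.0)  # everywhere above the 2.5 exclusion
        values[14:17, 14:17, 14:17] = 10.0
        vol = make_volume(values, (2.0, 2.0, 2.0))
        region = ROIMask(grid, values == 10.0)
        with pytest.warns(SegmentationWarning):
            res = compute_nestle_threshold(vol, region, beta=0.30)
        assert res.ibgd == 0.0
        assert res.excluded_count > 0
        assert res.tn == pytest.approx(0.30 * res.i70)

    def test_beta_zero_gives_background_threshold(self):
        grid = make_grid((25, 25, 25), (2.0, 2.0, 2.0))
        values = np.full(grid.shape, 1.2)
        values[11:14, 11:14, 11:14] = 9.0
        vol = make_volume(values, (2.0, 2.0, 2.0))
        region = ROIMask(grid, values == 9.0)
        res = compute_nestle_threshold(vol, region, beta=0.0)
        assert res.tn == res.ibgd

    def test_shell_band_distances(self):
        # retained shell voxels must sit in [12, 16) mm of the 70% core
        grid = make_grid((31, 31, 31), (2.0, 2.0, 2.0))
        values = np.full(grid.shape, 1.0)
        values[14:17, 14:17, 14:17] = 8.0
        vol = make_volume(values, (2.0, 2.0, 2.0))
        region = ROIMask(grid, values == 8.0)
        res = compute_nestle_threshold(vol, region)
        from petseg import distance_from_region

        d = distance_from_region(region)  # region == its own 70% core here
        sel = res.shell.indicator
        assert sel.any()
        assert d[sel].min() >= 12.0
        assert d[sel].max() < 16.0

    def test_segment_nestle_recovers_uniform_sphere(self, uniform_sphere_case):
        case = uniform_sphere_case
        sketch = rasterize_sketch(case.sketch, case.volume.grid)
        mask, details = segment_nestle(case.volume, sketch, with_details=True)
        assert details.tn == pytest.approx(3.0)
        assert dice(mask, case.gt_mask) == 1.0

    def test_threshold_above_imax_gives_empty_mask_with_warning(self):
        vol = line_volume([2.0, 2.0, 2.4, 2.0, 2.0])
        # background shell is off-grid -> Ibgd 0; force tn > imax with huge beta
        with pytest.warns(SegmentationWarning):
            mask = segment_nestle(vol, full_mask(vol.grid), beta=1.5)
        assert mask.is_empty


def test_all_methods_return_subsets_of_sketch():
    rng = np.random.default_rng(21)
    for _ in range(10):
        vol = make_volume(rng.uniform(0, 15, (8, 8, 8)))
        sketch = ROIMask(vol.grid, rng.random(vol.grid.shape) < 0.4)
        if sketch.is_empty:
            continue
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SegmentationWarning)
            results = [
                segment_absolute_threshold(vol, sketch, 2.5),
                segment_relative_threshold(vol, sketch, 0.4),
                segment_relative_threshold(vol, sketch, 0.5),
                segment_nestle(vol, sketch),
            ]
        for out in results:
            assert out.issubset(sketch)
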