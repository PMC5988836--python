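import numpy as np
import pytest
from skimage.filters import median as skimage_median

from erkpulse import (
    ImageStack,
    LabelMask,
    RatioStack,
    compute_ratio_stack,
    extract_cell_traces,
    max_intensity_projection,
    median_filter,
    render_imd,
)


def make_stack(cfp, fret, **kw):
    return ImageStack(cfp=np.asarray(cfp, float), fret=np.asarray(fret, float), **kw)


class TestComputeRatio:
    def test_uniform_double_fret_gives_two(self):
        cfp = np.full((4, 8, 8), 100.0)
        rs = compute_ratio_stack(make_stack(cfp, 2 * cfp))
        assert np.allclose(rs.values, 2.0)

    def test_cfp_at_floor_all_invalid_raises(self):
        cfp = np.full((2, 4, 4), 5.0)
        with pytest.raises(ValueError):
            compute_ratio_stack(make_stack(cfp, cfp), cfp_floor=5.0)

    def test_background_subtraction_recovers_exact_ratio(self):
        rng = np.random.default_rng(0)
        intensity = rng.uniform(50, 200, size=(3, 6, 6))
        ratio = 1.7
        stack = make_stack(intensity + 20.0, ratio * intensity + 20.0)
        rs = compute_ratio_stack(
            stack, background_cfp=20.0, background_fret=20.0, cfp_floor=1.0
        )
        assert np.allclose(rs.values, ratio)

    def test_invalid_pixels_flagged_not_zeroed(self):
        cfp = np.full((2, 4, 4), 100.0)
        cfp[:, 0, 0] = 0.0
        rs = compute_ratio_stack(make_stack(cfp, cfp), cfp_floor=1.0)
        assert np.isnan(rs.values[:, 0, 0]).all()
        assert np.isfinite(rs.values[:, 1:, :]).all()

    def test_commutes_with_uniform_channel_scaling(self):
        rng = np.random.default_rng(1)
        cfp = rng.uniform(10, 100, size=(2, 5, 5))
        fret = rng.uniform(10, 100, size=(2, 5, 5))
        a = compute_ratio_stack(make_stack(cfp, fret), cfp_floor=0.1)
        b = compute_ratio_stack(make_stack(3 * cfp, 3 * fret), cfp_floor=0.1)
        assert np.allclose(a.values, b.values)

    def test_z_stacks_projected_before_division(self):
        cfp = np.zeros((1, 2, 4, 4))
        cfp[0, 0] = 100.0
        cfp[0, 1] = 50.0
        fret = np.zeros((1, 2, 4, 4))
        fret[0, 0] = 150.0
        fret[0, 1] = 300.0
        rs = compute_ratio_stack(make_stack(cfp, fret), cfp_floor=1.0)
        # max projection picks cfp=100, fret=300 independently
        assert np.allclose(rs.values, 3.0)


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 4.2)
        assert np.allclose(median_filter(img), 4.2)

    def test_impulse_removed(self):
        img = np.full((9, 9), 1.0)
        img[4, 4] = 100.0
        assert np.allclose(median_filter(img), 1.0)

    def test_interior_matches_skimage_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, size=(12, 12))
        ours = median_filter(img, 5)
        ref = skimage_median(img, footprint=np.ones((5, 5), bool))
        assert np.allclose(ours[2:-2, 2:-2], ref[2:-2, 2:-2])

    def test_checkerboard_majority_value(self):
        img = np.indices((7, 7)).sum(axis=0) % 2.0
        out = median_filter(img, 5)
        # direct 25-element median at the center
        assert out[3, 3] == np.median(img[1:6, 1:6])

    def test_nan_pixels_excluded_from_window(self):
        img = np.full((7, 7), 2.0)
        img[3, 3] = np.nan
        out = median_filter(img, 5)
        assert np.allclose(out[~np.isnan(out)], 2.0)

    def test_idempotent_on_piecewise_constant(self):
        img = np.ones((10, 10))
        img[:, 5:] = 3.0
        once = median_filter(img, 3)
        twice = median_filter(once, 3)
        assert np.allclose(once, twice)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.ones((3, 3)), 5)


class TestMaxProjection:
    def test_single_slice_identity(self):
        img = np.random.default_rng(0).uniform(size=(1, 5, 5))
        assert np.array_equal(max_intensity_projection(img), img[0])

    def test_dominating_slice_wins(self):
        a = np.full((4, 4), 9.0)
        b = np.full((4, 4), 1.0)
        assert np.array_equal(max_intensity_projection(np.stack([a, b])), a)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        stack = rng.uniform(size=(3, 6, 6))
        out = max_intensity_projection(stack)
        for y in range(6):
            for x in range(6):
                assert out[y, x] == max(stack[z, y, x] for z in range(3))

    def test_monotone_in_slices(self):
        rng = np.random.default_rng(3)
        stack = rng.uniform(size=(2, 5, 5))
        extra = rng.uniform(size=(1, 5, 5))
        bigger = max_intensity_projection(np.concatenate([stack, extra]))
        assert np.all(bigger >= max_intensity_projection(stack))


class TestRenderIMD:
    def test_low_ratio_is_blue_high_is_red(self):
        lo = np.full((4, 4), 1.0)
        intensity = np.full((4, 4), 100.0)
        rgb = render_imd(lo, intensity, (1.0, 2.0))
        r, g, b = rgb[0, 0]
        assert b > r  # blue end
        rgb_hi = render_imd(np.full((4, 4), 2.0), intensity, (1.0, 2.0))
        r, g, b = rgb_hi[0, 0]
        assert r > b  # red end

    def test_zero_intensity_renders_black(self):
        rgb = render_imd(np.full((3, 3), 1.5), np.zeros((3, 3)), (1.0, 2.0))
        assert np.all(rgb == 0)

    def test_invalid_ratio_pixels_black(self):
        ratio = np.full((3, 3), 1.5)
        ratio[1, 1] = np.nan
        rgb = render_imd(ratio, np.full((3, 3), 10.0), (1.0, 2.0))
        assert np.all(rgb[1, 1] == 0)
        assert np.any(rgb[0, 0] > 0)

    def test_depends_only_on_bin_indices(self):
        intensity = np.full((2, 2), 100.0)
        # two ratios falling in the same of 8 bins render identically
        a = render_imd(np.full((2, 2), 1.01), intensity, (1.0, 2.0))
        b = render_imd(np.full((2, 2), 1.11), intensity, (1.0, 2.0))
        assert np.array_equal(a, b)

    def test_out_of_range_clipped_to_end_bins(self):
        intensity = np.full((2, 2), 100.0)
        below = render_imd(np.full((2, 2), 0.5), intensity, (1.0, 2.0))
        at_lo = render_imd(np.full((2, 2), 1.0), intensity, (1.0, 2.0))
        assert np.array_equal(below, at_lo)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            render_imd(np.ones((2, 2)), np.ones((2, 2)), (2.0, 2.0))


class TestExtractTraces:
    def _ratio_stack(self, values):
        return RatioStack(values=np.asarray(values, float), interval=1.5)

    def test_uniform_ratio_gives_constant_trace(self):
        values = np.full((5, 6, 6), 1.5)
        mask = LabelMask(labels=np.ones((6, 6), dtype=int))
        (trace,) = extract_cell_traces(self._ratio_stack(values), mask)
        assert np.allclose(trace.values, 1.5)

    def test_two_labels_two_traces(self):
        values = np.ones((4, 4, 6))
        values[:, :, 3:] = 2.0
        labels = np.ones((4, 6), dtype=int)
        labels[:, 3:] = 2
        traces = extract_cell_traces(self._ratio_stack(values), LabelMask(labels=labels))
        assert np.allclose(traces[0].values, 1.0)
        assert np.allclose(traces[1].values, 2.0)

    def test_frames_without_valid_pixels_become_nan(self):
        values = np.full((4, 4, 4), 1.2)
        values[2] = np.nan
        mask = LabelMask(labels=np.ones((4, 4), dtype=int))
        (trace,) = extract_cell_traces(self._ratio_stack(values), mask)
        assert np.isnan(trace.values[2])
        assert np.isfinite(trace.values[[0, 1, 3]]).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_cell_traces(
                self._ratio_stack(np.ones((4, 4, 4))),
                LabelMask(labels=np.zeros((4, 4), dtype=int)),
            )
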