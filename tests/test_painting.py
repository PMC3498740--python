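import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atlaspaint.errors import TemplateError
from atlaspaint.painting import (
    BLUE,
    RED,
    WHITE,
    ColorScale,
    build_color_scale,
    invert_color,
    paint_all,
    paint_gene,
    value_to_color,
)
from atlaspaint.segmentation import segment_mask
from conftest import make_dataset


def dataset_of(values, gene="G1", condition="c"):
    return make_dataset(
        [(gene, f"T{i+1}", condition, "", 1, v) for i, v in enumerate(values)]
    )


class TestBuildColorScale:
    def test_global_domain_is_min_max(self):
        scale = build_color_scale(dataset_of([1.0, 2.0, 9.0]), "global")
        assert (scale.domain_min, scale.domain_max) == (1.0, 9.0)

    def test_symmetric_domain(self):
        scale = build_color_scale(dataset_of([-2.0, 3.0]), "symmetric")
        assert (scale.domain_min, scale.domain_max) == (-3.0, 3.0)
        assert scale.effective_midpoint() == 0.0

    def test_per_gene_domains(self):
        # oracle: groupwise min/max
        rows = [
            ("A", "T1", "c", "", 1, 1.0),
            ("A", "T2", "c", "", 1, 5.0),
            ("B", "T1", "c", "", 1, -4.0),
            ("B", "T2", "c", "", 1, 0.5),
        ]
        scales = build_color_scale(make_dataset(rows), "per_gene")
        assert (scales["A"].domain_min, scales["A"].domain_max) == (1.0, 5.0)
        assert (scales["B"].domain_min, scales["B"].domain_max) == (-4.0, 0.5)

    def test_no_present_values_is_error(self):
        with pytest.raises(TemplateError, match="no present values"):
            build_color_scale(dataset_of([math.nan, math.nan]))

    def test_degenerate_domain_warns(self):
        with pytest.warns(UserWarning, match="equal"):
            scale = build_color_scale(dataset_of([3.0, 3.0]))
        assert value_to_color(scale, 3.0) == scale.mid_color


class TestValueToColor:
    def test_endpoints_hit_exact_colors(self):
        scale = ColorScale(0.0, 10.0, mode="sequential")
        assert value_to_color(scale, 10.0) == RED
        assert value_to_color(scale, 0.0) == BLUE

    def test_diverging_midpoint_pins_mid_color(self):
        scale = ColorScale(-5.0, 5.0, mode="diverging")
        assert value_to_color(scale, 0.0) == WHITE
        assert value_to_color(scale, -5.0) == BLUE
        assert value_to_color(scale, 5.0) == RED

    def test_sequential_interpolation_round_half_up(self):
        # oracle: per-channel linear interpolation with round-half-up
        scale = ColorScale(
            0.0, 1.0, mode="sequential", low_color=(0, 0, 255), high_color=(255, 0, 0)
        )
        assert value_to_color(scale, 0.5) == (128, 0, 128)

    def test_missing_value_keep_source(self):
        scale = ColorScale(0.0, 1.0)
        assert value_to_color(scale, None) is None
        assert value_to_color(scale, math.nan) is None

    def test_missing_color_alternative(self):
        scale = ColorScale(0.0, 1.0, missing_color=(128, 128, 128))
        assert value_to_color(scale, None) == (128, 128, 128)

    def test_out_of_domain_clamped(self):
        scale = ColorScale(0.0, 1.0, mode="sequential")
        assert value_to_color(scale, 99.0) == RED
        assert value_to_color(scale, -99.0) == BLUE

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.0, 10.0, allow_nan=False))
    def test_inversion_recovers_value(self, v):
        scale = ColorScale(0.0, 10.0, mode="sequential")
        rgb = value_to_color(scale, v)
        assert abs(invert_color(scale, rgb) - v) <= 10.0 / 255

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-7.0, 7.0, allow_nan=False))
    def test_diverging_inversion_recovers_value(self, v):
        scale = ColorScale(-7.0, 7.0, mode="diverging")
        rgb = value_to_color(scale, v)
        # each half spans 7 units over 255 channel steps
        assert abs(invert_color(scale, rgb) - v) <= 7.0 / 255

    @settings(max_examples=50, deadline=None)
    @given(
        st.tuples(st.floats(0, 10), st.floats(0, 10)).map(sorted)
    )
    def test_sequential_monotone_red_up_blue_down(self, pair):
        lo, hi = pair
        scale = ColorScale(0.0, 10.0, mode="sequential")
        c_lo, c_hi = value_to_color(scale, lo), value_to_color(scale, hi)
        assert c_hi[0] >= c_lo[0]  # red channel non-decreasing
        assert c_hi[2] <= c_lo[2]  # blue channel non-increasing


class TestPaintGene:
    def test_constant_values_give_constant_color(self, three_segment_image):
        ds = dataset_of([4.0, 4.0, 4.0])
        scale = ColorScale(0.0, 8.0, mode="sequential")
        painted = paint_gene(three_segment_image, ds, "G1", "c", scale)
        colors = set()
        for sid in three_segment_image.legend.spatial_ids():
            mask = segment_mask(three_segment_image, sid)
            colors.update(map(tuple, painted.raster[mask]))
        assert len(colors) == 1

    def test_unmeasured_gene_copies_source(self, three_segment_image):
        ds = make_dataset(
            [("G1", "T1", "c", "", 1, math.nan),
             ("G1", "T2", "c", "", 1, math.nan),
             ("G1", "T3", "c", "", 1, math.nan),
             ("G2", "T1", "c", "", 1, 1.0)]
        )
        scale = ColorScale(0.0, 1.0)
        painted = paint_gene(three_segment_image, ds, "G1", "c", scale)
        np.testing.assert_array_equal(painted.raster, three_segment_image.source)
        assert painted.unpainted_ids == ["T1", "T2", "T3"]

    def test_segment_colors_equal_value_to_color(self, three_segment_image):
        # oracle: value_to_color applied per segment
        scale = ColorScale(0.0, 10.0, mode="sequential")
        ds = dataset_of([0.0, 5.0, 10.0])
        painted = paint_gene(three_segment_image, ds, "G1", "c", scale)
        for sid, v in zip(["T1", "T2", "T3"], [0.0, 5.0, 10.0]):
            mask = segment_mask(three_segment_image, sid)
            expected = np.array(value_to_color(scale, v), np.uint8)
            assert (painted.raster[mask] == expected).all()

    def test_pixels_outside_segments_untouched(self, three_segment_image):
        ds = dataset_of([1.0, 2.0, 3.0])
        painted = paint_gene(
            three_segment_image, ds, "G1", "c", ColorScale(0.0, 3.0)
        )
        outside = np.all(three_segment_image.labels == 255, axis=-1)
        np.testing.assert_array_equal(
            painted.raster[outside], three_segment_image.source[outside]
        )

    def test_blend_alpha_mixes_with_source(self, three_segment_image):
        ds = dataset_of([10.0, 10.0, 10.0])
        scale = ColorScale(0.0, 10.0, mode="sequential")
        painted = paint_gene(
            three_segment_image, ds, "G1", "c", scale, blend_alpha=0.5
        )
        mask = segment_mask(three_segment_image, "T1")
        # source is flat 90 gray; high color is (255, 0, 0)
        expected = np.floor(0.5 * np.array([255, 0, 0]) + 0.5 * 90 + 0.5).astype(np.uint8)
        assert (painted.raster[mask] == expected).all()

    def test_unknown_gene_and_condition_errors(self, three_segment_image):
        ds = dataset_of([1.0, 2.0, 3.0])
        with pytest.raises(TemplateError, match="unknown gene"):
            paint_gene(three_segment_image, ds, "nope", "c", ColorScale(0, 1))
        with pytest.raises(TemplateError, match="unknown condition"):
            paint_gene(three_segment_image, ds, "G1", "nope", ColorScale(0, 1))


class TestPaintAll:
    def test_one_image_per_gene_lexicographic(self, three_segment_image):
        rows = [
            ("B", "T1", "default", "", 1, 1.0),
            ("A", "T1", "default", "", 1, 2.0),
        ]
        images = paint_all(three_segment_image, make_dataset(rows))
        assert [im.gene_id for im in images] == ["A", "B"]

    def test_global_policy_equal_value_equal_color(self, three_segment_image):
        rows = [
            ("A", "T1", "default", "", 1, 7.0),
            ("A", "T2", "default", "", 1, 0.0),
            ("B", "T3", "default", "", 1, 7.0),
            ("B", "T1", "default", "", 1, 10.0),
        ]
        im_a, im_b = paint_all(three_segment_image, make_dataset(rows), "global")
        mask_a = segment_mask(three_segment_image, "T1")
        mask_b = segment_mask(three_segment_image, "T3")
        assert set(map(tuple, im_a.raster[mask_a])) == set(
            map(tuple, im_b.raster[mask_b])
        )
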