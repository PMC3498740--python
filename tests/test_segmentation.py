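import numpy as np
import pytest
from PIL import Image

from atlaspaint.errors import ImageError, LegendError
from atlaspaint.fixtures import FixtureSpec, make_segmented_image
from atlaspaint.segmentation import (
    LegendEntry,
    SegmentLegend,
    SegmentedImage,
    compose_montage,
    extract_segments,
    load_segmented_image,
    read_legend,
    segment_mask,
    write_legend,
)
from conftest import C_BLUE, C_GREEN, C_RED


class TestLegend:
    def test_duplicate_color_rejected(self):
        with pytest.raises(LegendError, match="used twice"):
            SegmentLegend([LegendEntry(C_RED, "T1"), LegendEntry(C_RED, "T2")])

    def test_duplicate_spatial_id_rejected(self):
        with pytest.raises(LegendError, match="'T1'"):
            SegmentLegend([LegendEntry(C_RED, "T1"), LegendEntry(C_GREEN, "T1")])

    def test_background_clash_rejected(self):
        with pytest.raises(LegendError, match="background"):
            SegmentLegend([LegendEntry((255, 255, 255), "T1")])

    def test_tsv_round_trip(self, tmp_path):
        legend = SegmentLegend(
            [
                LegendEntry(C_RED, "S1:embryo", stage="S1", display_name="Embryo"),
                LegendEntry(C_GREEN, "S2:embryo", stage="S2"),
            ]
        )
        p = write_legend(legend, tmp_path / "legend.tsv")
        back = read_legend(p)
        assert back.entries == legend.entries


class TestSegmentedImage:
    def test_valid_construction(self, two_segment_image):
        assert two_segment_image.size == (10, 10)

    def test_dimension_mismatch_reports_both_sizes(self):
        legend = SegmentLegend([LegendEntry(C_RED, "T1")])
        with pytest.raises(ImageError, match="10x10.*12x10|12x10.*10x10"):
            SegmentedImage(
                source=np.zeros((10, 10, 3), np.uint8),
                labels=np.zeros((10, 12, 3), np.uint8),
                legend=legend,
            )

    def test_load_from_files_flattens_alpha(self, tmp_path):
        rgba = np.zeros((6, 6, 4), np.uint8)  # fully transparent -> white
        Image.fromarray(rgba, "RGBA").save(tmp_path / "src.png")
        labels = np.full((6, 6, 3), C_RED, np.uint8)
        Image.fromarray(labels, "RGB").save(tmp_path / "lab.png")
        legend = SegmentLegend([LegendEntry(C_RED, "T1")])
        write_legend(legend, tmp_path / "legend.tsv")
        si = load_segmented_image(
            tmp_path / "src.png", tmp_path / "lab.png", tmp_path / "legend.tsv"
        )
        assert (si.source == 255).all()

    def test_jpeg_labelfield_warns(self, tmp_path):
        arr = np.full((6, 6, 3), C_RED, np.uint8)
        Image.fromarray(arr, "RGB").save(tmp_path / "lab.jpg", quality=95)
        Image.fromarray(arr, "RGB").save(tmp_path / "src.png")
        legend = SegmentLegend([LegendEntry(C_RED, "T1")])
        with pytest.warns(UserWarning, match="JPEG"):
            load_segmented_image(tmp_path / "src.png", tmp_path / "lab.jpg", legend)


class TestExtractSegments:
    def test_half_and_half_counts(self, two_segment_image):
        stats = extract_segments(two_segment_image)
        assert stats.counts == {"T1": 50, "T2": 50}
        assert stats.background_pixels == 0
        assert stats.unknown_pixels == 0
        assert stats.bboxes["T1"] == (0, 0, 5, 10)
        assert stats.bboxes["T2"] == (5, 0, 10, 10)

    def test_all_background_gives_empty_legend_entries(self):
        labels = np.full((8, 8, 3), 255, np.uint8)
        si = SegmentedImage(
            source=labels.copy(),
            labels=labels,
            legend=SegmentLegend([LegendEntry(C_RED, "T1"), LegendEntry(C_GREEN, "T2")]),
        )
        stats = extract_segments(si)
        assert stats.empty_segments() == ["T1", "T2"]
        assert stats.unknown_pixels == 0
        assert stats.background_pixels == 64

    def test_off_legend_pixels_counted_unknown(self, two_segment_image):
        two_segment_image.labels[0, 0] = (1, 2, 3)
        stats = extract_segments(two_segment_image)
        assert stats.unknown_pixels == 1
        assert stats.counts["T1"] == 49

    def test_generated_mosaic_matches_generator_tally(self):
        spec = FixtureSpec(seed=1, n_tissues=3, n_stages=1, image_size=(40, 40))
        si, truth = make_segmented_image(spec)
        stats = extract_segments(si)
        assert stats.counts == truth.counts
        assert stats.unknown_pixels == 0

    def test_partition_conserves_pixels(self, three_segment_image):
        stats = extract_segments(three_segment_image)
        assert (
            sum(stats.counts.values()) + stats.background_pixels + stats.unknown_pixels
            == stats.total_pixels
        )

    def test_deterministic_loading(self, flower_bundle):
        a = extract_segments(
            load_segmented_image(
                flower_bundle["source"], flower_bundle["labels"], flower_bundle["legend"]
            )
        )
        b = extract_segments(
            load_segmented_image(
                flower_bundle["source"], flower_bundle["labels"], flower_bundle["legend"]
            )
        )
        assert a == b


class TestSegmentMask:
    def test_masks_partition_raster(self, three_segment_image):
        si = three_segment_image
        union = np.zeros(si.labels.shape[:2], bool)
        for sid in si.legend.spatial_ids():
            mask = segment_mask(si, sid)
            assert not (union & mask).any()  # pairwise disjoint
            union |= mask
        background = np.all(si.labels == 255, axis=-1)
        assert (union | background).all()

    def test_mask_count_matches_stats(self, three_segment_image):
        stats = extract_segments(three_segment_image)
        for sid in three_segment_image.legend.spatial_ids():
            assert segment_mask(three_segment_image, sid).sum() == stats.counts[sid]

    def test_unknown_id_lists_legend(self, two_segment_image):
        with pytest.raises(LegendError, match="T1.*T2"):
            segment_mask(two_segment_image, "nope")


class TestComposeMontage:
    def test_vertical_geometry(self, two_segment_image, three_segment_image):
        part_a = two_segment_image  # 10x10
        montage, remap = compose_montage(
            [(part_a, "S1"), (part_a, "S2")], axis="vertical"
        )
        assert montage.size == (10, 20)
        # same colors in both parts -> second part remapped
        assert set(remap) == {("S2", C_RED), ("S2", C_GREEN)}

    def test_single_part_annotates_stage(self, two_segment_image):
        montage, remap = compose_montage([(two_segment_image, "S1")])
        assert montage.legend.spatial_ids() == ["S1:T1", "S1:T2"]
        assert remap == {}
        np.testing.assert_array_equal(montage.labels, two_segment_image.labels)

    def test_stage_tissue_product(self):
        spec = FixtureSpec(seed=2, n_tissues=3, n_stages=4, image_size=(80, 24))
        si, _ = make_segmented_image(spec)
        assert len(si.legend) == 12
        assert si.legend.stages() == ["S1", "S2", "S3", "S4"]

    def test_montage_stats_equal_concatenated_part_stats(self, two_segment_image):
        part_stats = extract_segments(two_segment_image)
        montage, _ = compose_montage(
            [(two_segment_image, "S1"), (two_segment_image, "S2")]
        )
        stats = extract_segments(montage)
        for stage in ("S1", "S2"):
            for sid, n in part_stats.counts.items():
                assert stats.counts[f"{stage}:{sid}"] == n

    def test_duplicate_stage_labels_rejected(self, two_segment_image):
        with pytest.raises(LegendError, match="duplicate stage"):
            compose_montage([(two_segment_image, "S1"), (two_segment_image, "S1")])

    def test_padding_smaller_part(self, two_segment_image):
        small = SegmentedImage(
            source=np.full((6, 6, 3), 10, np.uint8),
            labels=np.full((6, 6, 3), C_BLUE, np.uint8),
            legend=SegmentLegend([LegendEntry(C_BLUE, "T9")]),
        )
        montage, _ = compose_montage(
            [(two_segment_image, "S1"), (small, "S2")], axis="horizontal"
        )
        assert montage.size == (16, 10)
        stats = extract_segments(montage)
        assert stats.counts["S2:T9"] == 36
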