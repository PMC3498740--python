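import numpy as np
import pytest

from atlaspaint.expression_io import ExpressionDataset, ExperimentMetadata
from atlaspaint.segmentation import LegendEntry, SegmentLegend, SegmentedImage

import pandas as pd

# label colors chosen away from the white/black background defaults
C_RED = (200, 30, 30)
C_GREEN = (30, 200, 30)
C_BLUE = (30, 30, 200)


def make_dataset(rows, metadata=None):
    """Build an ExpressionDataset from (gene, spatial, cond, time, rep, value) tuples."""
    frame = pd.DataFrame(
        rows, columns=["gene_id", "spatial_id", "condition", "time", "replicate", "value"]
    )
    return ExpressionDataset(frame, metadata or ExperimentMetadata())


@pytest.fixture
def two_segment_image():
    """10x10 raster: left half tissue T1 (red), right half T2 (green)."""
    labels = np.full((10, 10, 3), 255, dtype=np.uint8)
    labels[:, :5] = C_RED
    labels[:, 5:] = C_GREEN
    source = np.tile(
        np.linspace(40, 200, 10, dtype=np.uint8)[None, :, None], (10, 1, 3)
    )
    legend = SegmentLegend(
        [LegendEntry(C_RED, "T1"), LegendEntry(C_GREEN, "T2")]
    )
    return SegmentedImage(source=source, labels=labels, legend=legend)


@pytest.fixture
def three_segment_image():
    """12x12 raster with three 4-column tissue bands and a white border."""
    labels = np.full((12, 12, 3), 255, dtype=np.uint8)
    labels[1:11, 0:4] = C_RED
    labels[1:11, 4:8] = C_GREEN
    labels[1:11, 8:12] = C_BLUE
    source = np.full((12, 12, 3), 90, dtype=np.uint8)
    legend = SegmentLegend(
        [LegendEntry(C_RED, "T1"), LegendEntry(C_GREEN, "T2"), LegendEntry(C_BLUE, "T3")]
    )
    return SegmentedImage(source=source, labels=labels, legend=legend)


@pytest.fixture(scope="session")
def flower_bundle(tmp_path_factory):
    from atlaspaint.fixtures import make_usecase_bundle

    out = tmp_path_factory.mktemp("flower")
    return make_usecase_bundle("flower_like", seed=5, out_dir=out)


@pytest.fixture(scope="session")
def seed_bundle(tmp_path_factory):
    from atlaspaint.fixtures import make_usecase_bundle

    out = tmp_path_factory.mktemp("seed")
    return make_usecase_bundle("seed_like", seed=7, out_dir=out)
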