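"""Labelfield images, legends, segment statistics and stage montages.

A *labelfield* is a second raster, pixel-aligned with the source
anatomical image, in which every region of interest is flat-filled with
one unique RGB color.  A legend side file maps each label color to a
spatial identifier (and optionally a developmental stage)::

    color_hex   spatial_id   stage   display_name
    #e41a1c     sepal                Sepal

Label matching is exact RGB equality with tolerance zero: labelfields
are flat paint images, and any anti-aliased or off-legend pixel is
classified "unknown" and never painted.  Coordinates use the raster
convention (origin top-left, x rightward, y downward); bounding boxes
are half-open ``(x0, y0, x1, y1)``.

In a stage montage the composite segment identity is ``stage:tissue``;
that composite string is the spatial identifier the expression template
must use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image

from atlaspaint.errors import ImageError, LegendError

RGB = tuple[int, int, int]

DEFAULT_BACKGROUND: frozenset[RGB] = frozenset({(255, 255, 255), (0, 0, 0)})


def _hex_to_rgb(text: str) -> RGB:
    text = text.strip().lstrip("#")
    if len(text) != 6:
        raise LegendError(f"bad color hex {text!r}")
    return tuple(int(text[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _rgb_to_hex(rgb: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


@dataclass(frozen=True)
class LegendEntry:
    color: RGB
    spatial_id: str
    stage: str = ""
    display_name: str = ""


@dataclass
class SegmentLegend:
    """Maps label colors to spatial identifiers.

    Colors and spatial ids must each be pairwise distinct, and no label
    color may coincide with a background color.
    """

    entries: list[LegendEntry]
    background_colors: frozenset[RGB] = field(default_factory=lambda: DEFAULT_BACKGROUND)

    def __post_init__(self) -> None:
        colors = [e.color for e in self.entries]
        ids = [e.spatial_id for e in self.entries]
        if len(set(colors)) != len(colors):
            seen: set[RGB] = set()
            dup = next(c for c in colors if c in seen or seen.add(c))  # type: ignore[func-returns-value]
            raise LegendError(f"label color {_rgb_to_hex(dup)} used twice")
        if len(set(ids)) != len(ids):
            seen_ids: set[str] = set()
            dup_id = next(i for i in ids if i in seen_ids or seen_ids.add(i))  # type: ignore[func-returns-value]
            raise LegendError(f"spatial_id {dup_id!r} used twice")
        clash = set(colors) & self.background_colors
        if clash:
            raise LegendError(
                f"label color(s) {sorted(map(_rgb_to_hex, clash))} are background colors"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def spatial_ids(self) -> list[str]:
        return [e.spatial_id for e in self.entries]

    def stages(self) -> list[str]:
        """Distinct stages in first-appearance order (empty string filtered)."""
        seen: list[str] = []
        for e in self.entries:
            if e.stage and e.stage not in seen:
                seen.append(e.stage)
        return seen

    def entry_for(self, spatial_id: str) -> LegendEntry:
        for e in self.entries:
            if e.spatial_id == spatial_id:
                return e
        raise LegendError(
            f"unknown spatial_id {spatial_id!r}; legend has {self.spatial_ids()}"
        )


def read_legend(path: str | Path) -> SegmentLegend:
    """Read a legend TSV (columns color_hex, spatial_id, stage, display_name)."""
    # note: no comment char — the color_hex column itself starts with '#'
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "color_hex" not in frame or "spatial_id" not in frame:
        raise LegendError(
            f"legend needs color_hex and spatial_id columns; found {list(frame.columns)}"
        )
    entries = [
        LegendEntry(
            color=_hex_to_rgb(row.color_hex),
            spatial_id=row.spatial_id.strip(),
            stage=getattr(row, "stage", "").strip(),
            display_name=getattr(row, "display_name", "").strip(),
        )
        for row in frame.itertuples(index=False)
    ]
    return SegmentLegend(entries)


def write_legend(legend: SegmentLegend, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("color_hex\tspatial_id\tstage\tdisplay_name\n")
        for e in legend.entries:
            fh.write(
                f"{_rgb_to_hex(e.color)}\t{e.spatial_id}\t{e.stage}\t{e.display_name}\n"
            )
    return path


@dataclass
class SegmentedImage:
    """A source raster, its pixel-aligned labelfield and the legend."""

    source: np.ndarray  # (H, W, 3) uint8
    labels: np.ndarray  # (H, W, 3) uint8
    legend: SegmentLegend

    def __post_init__(self) -> None:
        self.source = np.ascontiguousarray(self.source, dtype=np.uint8)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.source.shape != self.labels.shape:
            raise ImageError(
                f"source {self.source.shape[1]}x{self.source.shape[0]} and labelfield "
                f"{self.labels.shape[1]}x{self.labels.shape[0]} dimensions differ"
            )
        if self.source.ndim != 3 or self.source.shape[2] != 3:
            raise ImageError("rasters must be (H, W, 3) RGB")

    @property
    def size(self) -> tuple[int, int]:
        """(width, height)."""
        return self.source.shape[1], self.source.shape[0]


@dataclass
class SegmentStats:
    """Per-segment pixel tallies from exact-color classification.

    ``counts``/``bboxes``/``stages`` are keyed by spatial_id; legend
    entries with zero pixels appear with count 0 and bbox None.  Pixels
    matching no legend or background color are tallied as ``unknown``.
    """

    counts: dict[str, int]
    bboxes: dict[str, tuple[int, int, int, int] | None]
    stages: dict[str, str]
    background_pixels: int
    unknown_pixels: int
    total_pixels: int

    def empty_segments(self) -> list[str]:
        return [sid for sid, n in self.counts.items() if n == 0]

    def unknown_fraction(self) -> float:
        return self.unknown_pixels / self.total_pixels if self.total_pixels else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.counts:
            bbox = self.bboxes[sid]
            rows.append(
                {
                    "spatial_id": sid,
                    "stage": self.stages[sid],
                    "pixels": self.counts[sid],
                    "bbox": "" if bbox is None else ",".join(map(str, bbox)),
                }
            )
        rows.append({"spatial_id": "<background>", "stage": "", "pixels": self.background_pixels, "bbox": ""})
        rows.append({"spatial_id": "<unknown>", "stage": "", "pixels": self.unknown_pixels, "bbox": ""})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loading and classification


def _load_rgb(path: str | Path) -> np.ndarray:
    """Load an image as RGB uint8, flattening any alpha against white."""
    with Image.open(path) as im:
        if im.format == "JPEG":
            warnings.warn(
                f"{path}: JPEG compression perturbs label colors; use PNG/BMP "
                "for labelfields",
                stacklevel=3,
            )
        if "A" in im.getbands():
            background = Image.new("RGBA", im.size, (255, 255, 255, 255))
            im = Image.alpha_composite(background, im.convert("RGBA"))
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def load_segmented_image(
    source_path: str | Path,
    labels_path: str | Path,
    legend_path: str | Path | SegmentLegend,
) -> SegmentedImage:
    """Load a source/labelfield pair and attach the legend."""
    source = _load_rgb(source_path)
    labels = _load_rgb(labels_path)
    legend = (
        legend_path
        if isinstance(legend_path, SegmentLegend)
        else read_legend(legend_path)
    )
    return SegmentedImage(source=source, labels=labels, legend=legend)


def _pack(colors: np.ndarray) -> np.ndarray:
    """Pack (..., 3) uint8 RGB into int32 codes for fast exact matching."""
    colors = colors.astype(np.int32)
    return (colors[..., 0] << 16) | (colors[..., 1] << 8) | colors[..., 2]


def extract_segments(si: SegmentedImage) -> SegmentStats:
    """Classify every labelfield pixel and tally per-segment statistics.

    Problems (unknown colors, empty legend entries) surface in the
    returned report, never as exceptions.
    """
    codes = _pack(si.labels)
    h, w = codes.shape
    counts: dict[str, int] = {}
    bboxes: dict[str, tuple[int, int, int, int] | None] = {}
    stages: dict[str, str] = {}
    classified = np.zeros((h, w), dtype=bool)
    for entry in si.legend.entries:
        code = (entry.color[0] << 16) | (entry.color[1] << 8) | entry.color[2]
        mask = codes == code
        n = int(mask.sum())
        counts[entry.spatial_id] = n
        stages[entry.spatial_id] = entry.stage
        if n:
            ys, xs = np.nonzero(mask)
            bboxes[entry.spatial_id] = (
                int(xs.min()),
                int(ys.min()),
                int(xs.max()) + 1,
                int(ys.max()) + 1,
            )
            classified |= mask
        else:
            bboxes[entry.spatial_id] = None
    background = np.zeros((h, w), dtype=bool)
    for color in si.legend.background_colors:
        code = (color[0] << 16) | (color[1] << 8) | color[2]
        background |= codes == code
    background &= ~classified
    n_background = int(background.sum())
    n_unknown = h * w - int(classified.sum()) - n_background
    return SegmentStats(
        counts=counts,
        bboxes=bboxes,
        stages=stages,
        background_pixels=n_background,
        unknown_pixels=n_unknown,
        total_pixels=h * w,
    )


def segment_mask(si: SegmentedImage, spatial_id: str) -> np.ndarray:
    """Boolean raster, true exactly where the labelfield carries this id's color."""
    entry = si.legend.entry_for(spatial_id)
    return np.all(si.labels == np.array(entry.color, dtype=np.uint8), axis=-1)


# ---------------------------------------------------------------------------
# montages


def _fresh_color(used: set[RGB], background: frozenset[RGB]) -> RGB:
    """Deterministic replacement color not yet used and not background."""
    for r in range(8, 256, 8):
        for g in range(8, 256, 16):
            for b in range(8, 256, 16):
                c = (r, g, b)
                if c not in used and c not in background:
                    return c
    raise LegendError("color space exhausted while remapping montage labels")


def compose_montage(
    parts: list[tuple[SegmentedImage, str]],
    axis: Literal["horizontal", "vertical"] = "horizontal",
) -> tuple[SegmentedImage, dict[tuple[str, RGB], RGB]]:
    """Concatenate stage panels into one montage labelfield.

    Each part becomes one stage; its legend ids are rewritten to the
    composite ``stage:tissue`` form.  Smaller parts are padded with
    background (white).  Label colors that collide across parts are
    remapped to fresh unique colors; the remap table (keyed by
    ``(stage, original color)``) is returned alongside the montage.
    """
    if not parts:
        raise ImageError("montage needs at least one part")
    stages_seen = [stage for _, stage in parts]
    if len(set(stages_seen)) != len(stages_seen):
        raise LegendError(f"duplicate stage labels in montage: {stages_seen}")

    background = frozenset().union(*(p.legend.background_colors for p, _ in parts))
    if not background:
        background = DEFAULT_BACKGROUND
    used_colors: set[RGB] = set()
    remap: dict[tuple[str, RGB], RGB] = {}
    entries: list[LegendEntry] = []
    new_labels: list[np.ndarray] = []
    new_sources: list[np.ndarray] = []

    perp = max(
        (p.size[1] if axis == "horizontal" else p.size[0]) for p, _ in parts
    )
    for part, stage in parts:
        labels = part.labels.copy()
        for entry in part.legend.entries:
            color = entry.color
            if color in used_colors:
                fresh = _fresh_color(used_colors | set(remap.values()), background)
                mask = np.all(labels == np.array(color, dtype=np.uint8), axis=-1)
                labels[mask] = fresh
                remap[(stage, color)] = fresh
                color = fresh
            used_colors.add(color)
            composite = f"{stage}:{entry.spatial_id}" if stage else entry.spatial_id
            entries.append(
                LegendEntry(
                    color=color,
                    spatial_id=composite,
                    stage=stage,
                    display_name=entry.display_name or entry.spatial_id,
                )
            )
        source = part.source
        w, h = part.size
        if axis == "horizontal" and h < perp:
            pad = ((0, perp - h), (0, 0), (0, 0))
            labels = np.pad(labels, pad, constant_values=255)
            source = np.pad(source, pad, constant_values=255)
        elif axis == "vertical" and w < perp:
            pad = ((0, 0), (0, perp - w), (0, 0))
            labels = np.pad(labels, pad, constant_values=255)
            source = np.pad(source, pad, constant_values=255)
        new_labels.append(labels)
        new_sources.append(source)

    cat_axis = 1 if axis == "horizontal" else 0
    legend = SegmentLegend(entries, background_colors=background)
    montage = SegmentedImage(
        source=np.concatenate(new_sources, axis=cat_axis),
        labels=np.concatenate(new_labels, axis=cat_axis),
        legend=legend,
    )
    return montage, remap


def save_image(raster: np.ndarray, path: str | Path) -> Path:
    """Write an RGB raster as PNG (lossless, deterministic bytes)."""
    path = Path(path)
    Image.fromarray(np.ascontiguousarray(raster, dtype=np.uint8), "RGB").save(
        path, format="PNG"
    )
    return path
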