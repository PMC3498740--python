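"""Map expression values to colors and paint labelfield segments.

One *global* color scale is shared by every gene, segment and stage, so
equal expression means equal color everywhere — the property that makes
per-gene images comparable at a glance.  The default scale is a
diverging blue-white-red ramp (blue = low, red = high); a symmetric
variant centred on zero serves condition-difference datasets so that
"no change" always paints the midpoint color.

Channel interpolation is linear with round-half-up to 8-bit integers,
which makes painted colors exactly invertible back to values up to the
1/255 channel quantization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from atlaspaint.errors import AtlasPaintError, TemplateError
from atlaspaint.expression_io import ExpressionDataset, aggregate_replicates
from atlaspaint.segmentation import RGB, SegmentedImage, segment_mask

#: Default diverging endpoints: blue (low) -> white (mid) -> red (high).
BLUE: RGB = (0, 0, 255)
WHITE: RGB = (255, 255, 255)
RED: RGB = (255, 0, 0)


@dataclass(frozen=True)
class ColorScale:
    """A value -> color transform with an explicit domain.

    ``sequential`` interpolates low_color -> high_color linearly over
    [domain_min, domain_max]; ``diverging`` interpolates low -> mid on
    [domain_min, midpoint] and mid -> high on [midpoint, domain_max].
    Out-of-domain values are clamped, never an error.  ``missing_color``
    None means "keep-source": unmeasured segments stay anatomical.
    """

    domain_min: float
    domain_max: float
    mode: Literal["sequential", "diverging"] = "diverging"
    low_color: RGB = BLUE
    high_color: RGB = RED
    mid_color: RGB = WHITE
    midpoint: float | None = None
    missing_color: RGB | None = None
    policy: Literal["global", "per_gene", "symmetric"] = "global"

    def __post_init__(self) -> None:
        if self.domain_min > self.domain_max:
            raise AtlasPaintError("domain_min must not exceed domain_max")

    @property
    def degenerate(self) -> bool:
        return self.domain_min == self.domain_max

    def effective_midpoint(self) -> float:
        if self.midpoint is not None:
            return self.midpoint
        if self.domain_min < 0.0 < self.domain_max:
            return 0.0
        return 0.5 * (self.domain_min + self.domain_max)


def _round_half_up(x: np.ndarray | float) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def _lerp(lo: RGB, hi: RGB, t: float) -> RGB:
    lo_a, hi_a = np.array(lo, float), np.array(hi, float)
    return tuple(int(c) for c in _round_half_up(lo_a + t * (hi_a - lo_a)))  # type: ignore[return-value]


def build_color_scale(
    ds: ExpressionDataset,
    policy: Literal["global", "per_gene", "symmetric"] = "global",
    mode: Literal["sequential", "diverging"] = "diverging",
    **kwargs,
) -> ColorScale | dict[str, ColorScale]:
    """Build the shared scale (or one per gene) from a dataset's values.

    * ``global`` — domain is [min, max] over all genes/segments/conditions.
    * ``symmetric`` — domain is [-m, +m] with m = max |value|; used for
      difference datasets so zero maps to the midpoint color.
    * ``per_gene`` — returns a dict of gene -> scale with per-gene domains.
    """
    values = ds.frame["value"].dropna()
    if values.empty:
        raise TemplateError("cannot build a color scale: no present values")
    if policy == "per_gene":
        scales: dict[str, ColorScale] = {}
        for gene, group in ds.frame.groupby("gene_id"):
            vals = group["value"].dropna()
            if vals.empty:
                continue
            scales[str(gene)] = ColorScale(
                domain_min=float(vals.min()),
                domain_max=float(vals.max()),
                mode=mode,
                policy="per_gene",
                **kwargs,
            )
        return scales
    if policy == "symmetric":
        m = float(values.abs().max())
        lo, hi, midpoint = -m, m, 0.0
    else:
        lo, hi, midpoint = float(values.min()), float(values.max()), None
    scale = ColorScale(
        domain_min=lo,
        domain_max=hi,
        mode=mode,
        midpoint=midpoint,
        policy=policy,
        **kwargs,
    )
    if scale.degenerate:
        warnings.warn(
            "all expression values are equal; every segment maps to the "
            "midpoint color",
            stacklevel=2,
        )
    return scale


def value_to_color(scale: ColorScale, v: float | None) -> RGB | None:
    """Color for one value; None for missing under keep-source policy."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return scale.missing_color  # None signals keep-source
    if scale.degenerate:
        return scale.mid_color
    v = min(max(float(v), scale.domain_min), scale.domain_max)
    if scale.mode == "sequential":
        t = (v - scale.domain_min) / (scale.domain_max - scale.domain_min)
        return _lerp(scale.low_color, scale.high_color, t)
    mid = scale.effective_midpoint()
    if v <= mid:
        span = mid - scale.domain_min
        t = 1.0 if span == 0 else (v - scale.domain_min) / span
        return _lerp(scale.low_color, scale.mid_color, t)
    span = scale.domain_max - mid
    t = 1.0 if span == 0 else (v - mid) / span
    return _lerp(scale.mid_color, scale.high_color, t)


def invert_color(scale: ColorScale, rgb: RGB) -> float:
    """Recover the value a painted color encodes (inverse of value_to_color).

    Uses the channel with the widest span on each ramp; exact up to the
    8-bit channel quantization, i.e. within (domain span)/255 for the
    default full-span endpoints.
    """
    if scale.degenerate:
        return scale.domain_min

    def _solve(lo: RGB, hi: RGB, lo_v: float, hi_v: float) -> tuple[float, float]:
        spans = [abs(h - l) for l, h in zip(lo, hi)]
        ch = int(np.argmax(spans))
        if spans[ch] == 0:
            return lo_v, float("inf")
        t = (rgb[ch] - lo[ch]) / (hi[ch] - lo[ch])
        t_clamped = min(max(t, 0.0), 1.0)
        value = lo_v + t_clamped * (hi_v - lo_v)
        # residual: how far the forward map lands from the observed color
        forward = _lerp(lo, hi, t_clamped)
        residual = sum(abs(a - b) for a, b in zip(forward, rgb))
        return value, residual

    if scale.mode == "sequential":
        value, _ = _solve(
            scale.low_color, scale.high_color, scale.domain_min, scale.domain_max
        )
        return value
    mid = scale.effective_midpoint()
    lo_val, lo_res = _solve(scale.low_color, scale.mid_color, scale.domain_min, mid)
    hi_val, hi_res = _solve(scale.mid_color, scale.high_color, mid, scale.domain_max)
    return lo_val if lo_res <= hi_res else hi_val


@dataclass
class PaintedImage:
    """The color-coded raster for one (gene, condition) plus provenance."""

    raster: np.ndarray  # (H, W, 3) uint8
    gene_id: str
    condition: str
    time: str
    scale: ColorScale
    unpainted_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> tuple[int, int]:
        return self.raster.shape[1], self.raster.shape[0]


def paint_gene(
    si: SegmentedImage,
    ds: ExpressionDataset,
    gene_id: str,
    condition: str = "default",
    scale: ColorScale | None = None,
    blend_alpha: float = 1.0,
    time: str | None = None,
) -> PaintedImage:
    """Paint every measured segment with the gene's expression color.

    Segments with missing or absent values, background and unknown
    pixels are copied from the source unchanged; ``unpainted_ids``
    records the gaps.  ``blend_alpha`` < 1 alpha-blends the expression
    color over the source so anatomical texture shows through.
    """
    if gene_id not in set(ds.frame["gene_id"]):
        raise TemplateError(f"unknown gene {gene_id!r}")
    if condition not in ds.conditions():
        raise TemplateError(
            f"unknown condition {condition!r}; available: {ds.conditions()}"
        )
    if not 0.0 <= blend_alpha <= 1.0:
        raise AtlasPaintError("blend_alpha must lie in [0, 1]")
    if scale is None:
        scale = build_color_scale(ds)  # type: ignore[assignment]
    raster = si.source.copy()
    unpainted: list[str] = []
    for entry in si.legend.entries:
        value = ds.value_for(gene_id, entry.spatial_id, condition, time)
        color = value_to_color(scale, value)
        if color is None:
            unpainted.append(entry.spatial_id)
            continue
        mask = segment_mask(si, entry.spatial_id)
        if blend_alpha >= 1.0:
            raster[mask] = color
        else:
            blended = (
                blend_alpha * np.array(color, float)
                + (1.0 - blend_alpha) * si.source[mask].astype(float)
            )
            raster[mask] = np.floor(blended + 0.5).astype(np.uint8)
    return PaintedImage(
        raster=raster,
        gene_id=gene_id,
        condition=condition,
        time="" if time is None else time,
        scale=scale,
        unpainted_ids=unpainted,
    )


def paint_all(
    si: SegmentedImage,
    ds: ExpressionDataset,
    scale_policy: Literal["global", "per_gene", "symmetric"] = "global",
    condition: str = "default",
    mode: Literal["sequential", "diverging"] = "diverging",
    blend_alpha: float = 1.0,
) -> list[PaintedImage]:
    """One painted image per gene, in lexicographic gene order."""
    ds = aggregate_replicates(ds)
    scales = build_color_scale(ds, policy=scale_policy, mode=mode)
    images: list[PaintedImage] = []
    for gene in ds.genes():
        scale = scales.get(gene) if isinstance(scales, dict) else scales
        if scale is None:  # per_gene policy, gene with no present values
            scale = ColorScale(0.0, 0.0, mode=mode, policy="per_gene")
        images.append(
            paint_gene(si, ds, gene, condition, scale, blend_alpha=blend_alpha)
        )
    return images


def scale_legend_raster(
    scale: ColorScale, width: int = 256, height: int = 24
) -> np.ndarray:
    """A horizontal color-bar raster for the scale (low left, high right)."""
    raster = np.empty((height, width, 3), dtype=np.uint8)
    if scale.degenerate:
        raster[:] = scale.mid_color
        return raster
    for x in range(width):
        v = scale.domain_min + (scale.domain_max - scale.domain_min) * x / (width - 1)
        raster[:, x] = value_to_color(scale, v)
    return raster
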