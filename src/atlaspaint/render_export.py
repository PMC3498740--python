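"""Static deliverables: network renders, grids, stacks, HTML gallery.

All exports are deterministic — no timestamps, no unordered iteration —
so a fixed input always yields byte-identical output, which makes the
figures reproducible and diffable.  SVG renders embed the painted
rasters losslessly as base64 PNG; PNG renders draw the same scene with
Pillow.  Nodes are rounded rectangles (glyph vocabularies of upstream
editors are carried as a class string but not re-drawn); activation
edges end in an arrowhead, inhibition edges in a bar.

The grid export is the static home of "visual clustering": the caller
supplies the image order, typically arranged so similar spatial
patterns sit together, and the grid lays them out row-major.
"""

from __future__ import annotations

import base64
import html
import io
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from atlaspaint.errors import RenderError
from atlaspaint.networks import OmicsNetwork
from atlaspaint.painting import PaintedImage

#: Interaction strings rendered with a flat-bar head instead of an arrow.
INHIBITION_WORDS = {"inhibition", "inhibits", "repression", "represses", "-1"}


@dataclass
class RenderStyle:
    node_padding: float = 6.0
    node_width: float = 80.0
    node_height: float = 60.0
    edge_color: str = "#555555"
    edge_width: float = 1.5
    font_size: int = 11
    background: str = "#ffffff"
    canvas_margin: float = 40.0

    def __post_init__(self) -> None:
        for name in ("node_padding", "node_width", "node_height", "edge_width",
                     "font_size", "canvas_margin"):
            if getattr(self, name) <= 0:
                raise RenderError(f"style dimension {name} must be positive")


@dataclass
class GalleryEntry:
    image_path: str
    caption: str = ""
    hyperlink: str | None = None


@dataclass
class GallerySpec:
    title: str
    entries: list[GalleryEntry] = field(default_factory=list)


# ---------------------------------------------------------------------------
# network rendering


def _png_bytes(raster_or_path: np.ndarray | str | Path) -> bytes:
    if isinstance(raster_or_path, (str, Path)):
        path = Path(raster_or_path)
        if not path.exists():
            raise RenderError(f"image file not found: {path}")
        with Image.open(path) as im:
            buf = io.BytesIO()
            im.convert("RGB").save(buf, format="PNG")
            return buf.getvalue()
    buf = io.BytesIO()
    Image.fromarray(np.ascontiguousarray(raster_or_path, dtype=np.uint8), "RGB").save(
        buf, format="PNG"
    )
    return buf.getvalue()


def _node_geometry(net: OmicsNetwork, style: RenderStyle):
    """Resolved (x, y, w, h) per node, positions centred on (x, y)."""
    geo = {}
    for node in net.nodes:
        w, h = node.size if node.size else (style.node_width, style.node_height)
        x, y = node.position  # grid fallback applied by caller
        geo[node.id] = (float(x), float(y), float(w), float(h))
    return geo


def _canvas_extent(geo, style: RenderStyle) -> tuple[float, float, float, float]:
    xs0 = [x - w / 2 for x, y, w, h in geo.values()]
    ys0 = [y - h / 2 - style.font_size - 4 for x, y, w, h in geo.values()]
    xs1 = [x + w / 2 for x, y, w, h in geo.values()]
    ys1 = [y + h / 2 + style.font_size + 6 for x, y, w, h in geo.values()]
    m = style.canvas_margin
    return min(xs0) - m, min(ys0) - m, max(xs1) + m, max(ys1) + m


def _edge_endpoints(geo, edge, loop_radius: float = 28.0):
    """Straight segment clipped to node boxes; self-loops get an arc."""
    x0, y0, w0, h0 = geo[edge.source_id]
    x1, y1, w1, h1 = geo[edge.target_id]
    if edge.source_id == edge.target_id:
        return None  # drawn as a loop arc by the caller
    dx, dy = x1 - x0, y1 - y0
    norm = max((dx * dx + dy * dy) ** 0.5, 1e-9)
    ux, uy = dx / norm, dy / norm

    def clip(cx, cy, w, h, ux, uy):
        # distance from centre to box border along (ux, uy)
        tx = (w / 2) / abs(ux) if ux else float("inf")
        ty = (h / 2) / abs(uy) if uy else float("inf")
        t = min(tx, ty)
        return cx + ux * t, cy + uy * t

    sx, sy = clip(x0, y0, w0, h0, ux, uy)
    ex, ey = clip(x1, y1, w1, h1, -ux, -uy)
    return sx, sy, ex, ey


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_network(
    net: OmicsNetwork,
    images: Mapping[str, np.ndarray | str | Path] | None = None,
    style: RenderStyle | None = None,
    format: Literal["png", "svg"] = "svg",
    out_path: str | Path | None = None,
) -> bytes | Path:
    """Render the network with painted images inside matched nodes.

    ``images`` optionally overrides node ``image_ref`` paths with
    in-memory rasters keyed by node id.  Returns the bytes, or writes
    them to ``out_path`` when given.
    """
    style = style or RenderStyle()
    if not net.has_layout() or any(n.position is None for n in net.nodes):
        net.apply_grid_layout()
    geo = _node_geometry(net, style)
    if format == "svg":
        data = _render_svg(net, images or {}, style, geo)
    elif format == "png":
        data = _render_png(net, images or {}, style, geo)
    else:
        raise RenderError(f"unsupported render format {format!r}")
    if out_path is not None:
        out_path = Path(out_path)
        out_path.write_bytes(data)
        return out_path
    return data


def _node_image_bytes(node, images) -> bytes | None:
    if node.id in images:
        return _png_bytes(images[node.id])
    if node.image_ref:
        path = Path(node.image_ref)
        if not path.exists():
            raise RenderError(f"node {node.id!r}: image file not found: {path}")
        return _png_bytes(path)
    return None


def _render_svg(net, images, style, geo) -> bytes:
    x0, y0, x1, y1 = _canvas_extent(geo, style)
    width, height = x1 - x0, y1 - y0
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'xmlns:xlink="http://www.w3.org/1999/xlink" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="{_fmt(x0)} {_fmt(y0)} {_fmt(width)} {_fmt(height)}">'
    )
    out.append(
        "<defs>"
        '<marker id="arrow" viewBox="0 0 10 10" refX="9" refY="5" '
        'markerWidth="8" markerHeight="8" orient="auto-start-reverse">'
        f'<path d="M 0 0 L 10 5 L 0 10 z" fill="{style.edge_color}"/></marker>'
        '<marker id="bar" viewBox="0 0 4 10" refX="3" refY="5" '
        'markerWidth="5" markerHeight="10" orient="auto-start-reverse">'
        f'<rect x="0" y="0" width="3" height="10" fill="{style.edge_color}"/></marker>'
        "</defs>"
    )
    out.append(
        f'<rect x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" fill="{style.background}"/>'
    )
    for edge in net.edges:
        marker = "bar" if edge.interaction.lower() in INHIBITION_WORDS else "arrow"
        marker_attr = f' marker-end="url(#{marker})"' if net.directed else ""
        if edge.source_id == edge.target_id:
            x, y, w, h = geo[edge.source_id]
            r = 22.0
            cx, cy = x + w / 2, y - h / 2
            out.append(
                f'<path class="edge" d="M {_fmt(x + w / 2 - 6)} {_fmt(cy + 6)} '
                f"A {r} {r} 0 1 1 {_fmt(cx + 6)} {_fmt(y - h / 2 + 6)}\" "
                f'fill="none" stroke="{style.edge_color}" '
                f'stroke-width="{style.edge_width}"{marker_attr}/>'
            )
            continue
        sx, sy, ex, ey = _edge_endpoints(geo, edge)
        out.append(
            f'<line class="edge" x1="{_fmt(sx)}" y1="{_fmt(sy)}" '
            f'x2="{_fmt(ex)}" y2="{_fmt(ey)}" stroke="{style.edge_color}" '
            f'stroke-width="{style.edge_width}"{marker_attr}/>'
        )
    for node in net.nodes:
        x, y, w, h = geo[node.id]
        left, top = x - w / 2, y - h / 2
        dashed = ' stroke-dasharray="4 2"' if node.node_class else ""
        out.append(
            f'<rect x="{_fmt(left)}" y="{_fmt(top)}" width="{_fmt(w)}" '
            f'height="{_fmt(h)}" rx="6" fill="#ffffff" stroke="#333333" '
            f'stroke-width="1"{dashed}/>'
        )
        png = _node_image_bytes(node, images)
        if png is not None:
            pad = style.node_padding
            b64 = base64.b64encode(png).decode("ascii")
            out.append(
                f'<image x="{_fmt(left + pad)}" y="{_fmt(top + pad)}" '
                f'width="{_fmt(w - 2 * pad)}" height="{_fmt(h - 2 * pad)}" '
                f'preserveAspectRatio="xMidYMid meet" '
                f'xlink:href="data:image/png;base64,{b64}"/>'
            )
        label = html.escape(node.label)
        out.append(
            f'<text x="{_fmt(x)}" y="{_fmt(top + h + style.font_size + 2)}" '
            f'text-anchor="middle" font-family="sans-serif" '
            f'font-size="{style.font_size}">{label}</text>'
        )
    out.append("</svg>")
    return ("\n".join(out) + "\n").encode("utf-8")


def _render_png(net, images, style, geo, scale: float = 1.0) -> bytes:
    x0, y0, x1, y1 = _canvas_extent(geo, style)
    width, height = int(round((x1 - x0) * scale)), int(round((y1 - y0) * scale))
    canvas = Image.new("RGB", (width, height), style.background)
    draw = ImageDraw.Draw(canvas)

    def to_px(x: float, y: float) -> tuple[float, float]:
        return (x - x0) * scale, (y - y0) * scale

    for edge in net.edges:
        if edge.source_id == edge.target_id:
            x, y, w, h = geo[edge.source_id]
            cx, cy = to_px(x + w / 2, y - h / 2)
            r = 16 * scale
            draw.arc(
                [cx - r, cy - r, cx + r, cy + r],
                start=90,
                end=360,
                fill=style.edge_color,
                width=max(1, int(style.edge_width)),
            )
            continue
        sx, sy, ex, ey = _edge_endpoints(geo, edge)
        p0, p1 = to_px(sx, sy), to_px(ex, ey)
        draw.line([p0, p1], fill=style.edge_color, width=max(1, int(style.edge_width)))
        # head: arrow triangle or inhibition bar
        vx, vy = p1[0] - p0[0], p1[1] - p0[1]
        norm = max((vx * vx + vy * vy) ** 0.5, 1e-9)
        ux, uy = vx / norm, vy / norm
        px, py = -uy, ux
        if edge.interaction.lower() in INHIBITION_WORDS:
            draw.line(
                [(p1[0] - 5 * px, p1[1] - 5 * py), (p1[0] + 5 * px, p1[1] + 5 * py)],
                fill=style.edge_color,
                width=max(2, int(style.edge_width)),
            )
        elif net.directed:
            tip = p1
            left = (p1[0] - 8 * ux + 4 * px, p1[1] - 8 * uy + 4 * py)
            right = (p1[0] - 8 * ux - 4 * px, p1[1] - 8 * uy - 4 * py)
            draw.polygon([tip, left, right], fill=style.edge_color)
    for node in net.nodes:
        x, y, w, h = geo[node.id]
        l, t = to_px(x - w / 2, y - h / 2)
        r, b = to_px(x + w / 2, y + h / 2)
        draw.rounded_rectangle([l, t, r, b], radius=6, fill="#ffffff", outline="#333333")
        png = _node_image_bytes(node, images)
        if png is not None:
            with Image.open(io.BytesIO(png)) as im:
                pad = int(style.node_padding * scale)
                box_w, box_h = int(r - l) - 2 * pad, int(b - t) - 2 * pad
                if box_w > 0 and box_h > 0:
                    ratio = min(box_w / im.width, box_h / im.height)
                    new = im.convert("RGB").resize(
                        (max(1, int(im.width * ratio)), max(1, int(im.height * ratio))),
                        Image.NEAREST,
                    )
                    ox = int(l) + pad + (box_w - new.width) // 2
                    oy = int(t) + pad + (box_h - new.height) // 2
                    canvas.paste(new, (ox, oy))
        tw = draw.textlength(node.label)
        draw.text(((l + r) / 2 - tw / 2, b + 3), node.label, fill="#000000")
    buf = io.BytesIO()
    canvas.save(buf, format="PNG")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# grids, stacks, gallery

_CAPTION_STRIP = 16  # px reserved under each cell for the caption


def compose_grid(
    images: Sequence[PaintedImage],
    columns: int,
    captions: bool = True,
) -> np.ndarray:
    """Row-major sheet of painted images with uniform cell size.

    The cell is the maximum image size plus a caption strip; the last
    row may contain blank cells.  The caller's ordering is preserved —
    arranging similar patterns next to each other is how visual
    clustering is expressed here.
    """
    if columns < 1:
        raise RenderError("columns must be >= 1")
    if not images:
        raise RenderError("compose_grid needs at least one image")
    columns = min(columns, len(images))  # no empty trailing columns
    cell_w = max(im.size[0] for im in images)
    cell_h = max(im.size[1] for im in images)
    strip = _CAPTION_STRIP if captions else 0
    rows = -(-len(images) // columns)  # ceil division
    sheet = Image.new("RGB", (columns * cell_w, rows * (cell_h + strip)), "#ffffff")
    draw = ImageDraw.Draw(sheet)
    for i, painted in enumerate(images):
        row, col = divmod(i, columns)
        ox = col * cell_w + (cell_w - painted.size[0]) // 2
        oy = row * (cell_h + strip)
        sheet.paste(Image.fromarray(painted.raster, "RGB"), (ox, oy))
        if captions:
            text = painted.gene_id
            if painted.condition not in ("", "default"):
                text += f" [{painted.condition}]"
            tw = draw.textlength(text)
            draw.text(
                (col * cell_w + (cell_w - tw) / 2, row * (cell_h + strip) + cell_h + 2),
                text,
                fill="#000000",
            )
    return np.asarray(sheet, dtype=np.uint8)


def compose_stack(images: Sequence[PaintedImage], captions: bool = True) -> np.ndarray:
    """Vertical strip of painted images, one per row with its caption —
    the static stand-in for side-panel stacking of a node selection."""
    if not images:
        raise RenderError("compose_stack needs at least one image")
    return compose_grid(images, columns=1, captions=captions)


_GALLERY_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; background: #fafafa; }}
.gallery {{ display: flex; flex-wrap: wrap; gap: 1em; }}
figure {{ margin: 0; padding: 0.5em; background: #fff; border: 1px solid #ddd; }}
figcaption {{ text-align: center; font-size: 0.9em; margin-top: 0.3em; }}
img {{ image-rendering: pixelated; max-width: 320px; }}
</style>
</head>
<body>
<h1>{title}</h1>
<div class="gallery">
{figures}
</div>
</body>
</html>
"""


def export_gallery(spec: GallerySpec, out_dir: str | Path) -> Path:
    """Write a self-contained static gallery site (index.html + images).

    Every entry's image is copied next to the page; entries with a
    hyperlink wrap the image in an anchor so the gallery can link out
    to other networks or external database records.
    """
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise RenderError(f"cannot create gallery directory {out_dir}: {exc}") from exc
    figures: list[str] = []
    for i, entry in enumerate(spec.entries):
        src = Path(entry.image_path)
        if not src.exists():
            raise RenderError(f"gallery entry {i}: image not found: {src}")
        dest_name = f"{i:03d}_{src.name}"
        shutil.copyfile(src, out_dir / "images" / dest_name)
        img = (
            f'<img src="images/{html.escape(dest_name)}" '
            f'alt="{html.escape(entry.caption or src.stem)}">'
        )
        if entry.hyperlink:
            img = f'<a href="{html.escape(entry.hyperlink)}">{img}</a>'
        caption = f"<figcaption>{html.escape(entry.caption)}</figcaption>" if entry.caption else ""
        figures.append(f"<figure>{img}{caption}</figure>")
    page = _GALLERY_PAGE.format(
        title=html.escape(spec.title), figures="\n".join(figures)
    )
    index = out_dir / "index.html"
    index.write_text(page, encoding="utf-8", newline="\n")
    return index
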