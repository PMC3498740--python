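"""Deterministic synthetic bundles: labelfield + legend + template + network.

The generator emulates the two study designs the method targets:

* ``flower_like`` — a single-stage organ image segmented into the four
  floral whorls (sepal, petal, stamen, carpel) with ~10 regulator genes
  whose expression is whorl-specific or ubiquitous;
* ``seed_like`` — a four-stage developmental montage, each stage panel
  segmented into seven seed tissues, with 100 regulator genes showing
  tissue-specific, stage-specific, graded or ubiquitous patterns.

Every random choice (label colors, pattern assignment, noise) derives
from one integer seed through a single :class:`numpy.random.Generator`
stream, so identical seeds give byte-identical bundles.  The generator
records its own ground truth (pixel tallies, pattern labels) as it
paints, which the analysis modules are tested against.

Synthetic values are idealized: flat within a segment, two-level
high/low patterns, optional Gaussian noise clipped to the value range.
They do not emulate microarray noise models or realistic expression
distributions.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from atlaspaint.errors import AtlasPaintError
from atlaspaint.expression_io import (
    COLUMNS,
    ExperimentMetadata,
    ExpressionDataset,
    write_template,
)
from atlaspaint.networks import NetworkEdge, NetworkNode, OmicsNetwork, write_network
from atlaspaint.segmentation import (
    RGB,
    LegendEntry,
    SegmentLegend,
    SegmentStats,
    SegmentedImage,
    compose_montage,
    save_image,
    write_legend,
)

PATTERNS = ("tissue_specific", "stage_specific", "ubiquitous", "graded")

FLOWER_TISSUES = ("sepal", "petal", "stamen", "carpel")
FLOWER_GENES = ("AG", "AGL11", "AP1", "AP2", "AP3", "LFY", "PI", "SEP1", "SEP2", "SEP3")
SEED_TISSUES = (
    "embryo",
    "suspensor",
    "endosperm_micropylar",
    "endosperm_peripheral",
    "endosperm_chalazal",
    "seed_coat",
    "seed_coat_chalazal",
)
SEED_STAGES = ("globular", "heart", "linear_cotyledon", "green_mature")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic bundle."""

    seed: int = 0
    n_tissues: int = 4
    n_stages: int = 1
    n_genes: int = 10
    image_size: tuple[int, int] = (120, 120)
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {
            "tissue_specific": 0.5,
            "stage_specific": 0.2,
            "ubiquitous": 0.1,
            "graded": 0.2,
        }
    )
    noise_sd: float = 0.0
    value_range: tuple[float, float] = (0.0, 10.0)
    tissue_names: tuple[str, ...] | None = None
    stage_names: tuple[str, ...] | None = None
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_tissues < 1 or self.n_stages < 1:
            raise AtlasPaintError("need at least one tissue and one stage")
        if self.noise_sd < 0:
            raise AtlasPaintError("noise_sd must be >= 0")
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise AtlasPaintError(f"pattern_mix proportions sum to {total}, not 1")
        if self.n_stages == 1:
            # stage-structured patterns are meaningless on one panel
            bulk = self.pattern_mix.get("stage_specific", 0.0) + self.pattern_mix.get(
                "graded", 0.0
            )
            if bulk:
                mix = dict(self.pattern_mix)
                mix["tissue_specific"] = mix.get("tissue_specific", 0.0) + bulk
                mix["stage_specific"] = 0.0
                mix["graded"] = 0.0
                self.pattern_mix = mix

    def tissues(self) -> tuple[str, ...]:
        if self.tissue_names:
            return self.tissue_names[: self.n_tissues]
        return tuple(f"T{i + 1}" for i in range(self.n_tissues))

    def stages(self) -> tuple[str, ...]:
        if self.stage_names:
            return self.stage_names[: self.n_stages]
        return tuple(f"S{i + 1}" for i in range(self.n_stages))

    def genes(self) -> tuple[str, ...]:
        if self.gene_names:
            names = self.gene_names[: self.n_genes]
            if len(names) == self.n_genes:
                return names
        return tuple(f"G{i + 1:03d}" for i in range(self.n_genes))


def _label_colors(n: int, rng: np.random.Generator) -> list[RGB]:
    """n maximally spaced hues on a color wheel, phase-shifted by seed."""
    phase = float(rng.uniform(0.0, 1.0))
    colors: list[RGB] = []
    for i in range(n):
        h = (phase + i / n) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.78, 0.88)
        colors.append((int(round(r * 255)), int(round(g * 255)), int(round(b * 255))))
    if len(set(colors)) != n:
        raise AtlasPaintError(f"color wheel produced non-unique colors for n={n}")
    return colors


def _panel(
    width: int,
    height: int,
    tissues: tuple[str, ...],
    colors: list[RGB],
    rng: np.random.Generator,
) -> tuple[SegmentedImage, dict[str, int]]:
    """One stage panel: horizontal tissue strips inside a white margin.

    Returns the panel and its exact per-tissue pixel tally.
    """
    margin = max(2, min(width, height) // 20)
    labels = np.full((height, width, 3), 255, dtype=np.uint8)
    inner_h = height - 2 * margin
    inner_w = width - 2 * margin
    if inner_h < len(tissues) or inner_w < 1:
        raise AtlasPaintError(f"panel {width}x{height} too small for {len(tissues)} tissues")
    counts: dict[str, int] = {}
    bounds = np.linspace(margin, margin + inner_h, len(tissues) + 1).astype(int)
    for i, tissue in enumerate(tissues):
        y0, y1 = int(bounds[i]), int(bounds[i + 1])
        labels[y0:y1, margin : margin + inner_w] = colors[i]
        counts[tissue] = (y1 - y0) * inner_w
    # source: smooth deterministic texture so "copied from source" is checkable
    yy, xx = np.mgrid[0:height, 0:width]
    base = 120 + 80 * np.sin(xx / 11.0) * np.cos(yy / 7.0)
    jitter = rng.integers(-10, 11, size=(height, width))
    gray = np.clip(base + jitter, 0, 255).astype(np.uint8)
    source = np.stack([gray, gray, np.clip(gray + 20, 0, 255).astype(np.uint8)], axis=-1)
    legend = SegmentLegend(
        [LegendEntry(color=colors[i], spatial_id=t) for i, t in enumerate(tissues)]
    )
    return SegmentedImage(source=source, labels=labels, legend=legend), counts


def make_segmented_image(spec: FixtureSpec) -> tuple[SegmentedImage, SegmentStats]:
    """Generate the labelfield/source pair plus the generator's own tally.

    Multi-stage specs produce a horizontal montage of stage panels with
    composite ``stage:tissue`` identifiers; a single-stage spec keeps
    plain tissue identifiers.
    """
    rng = np.random.default_rng(spec.seed)
    width, height = spec.image_size
    tissues = spec.tissues()
    stages = spec.stages()
    colors = _label_colors(spec.n_stages * spec.n_tissues, rng)

    panel_w = width // spec.n_stages
    parts: list[tuple[SegmentedImage, str]] = []
    counts: dict[str, int] = {}
    for s, stage in enumerate(stages):
        part, part_counts = _panel(
            panel_w,
            height,
            tissues,
            colors[s * spec.n_tissues : (s + 1) * spec.n_tissues],
            rng,
        )
        if spec.n_stages == 1:
            si = part
            counts.update(part_counts)
        else:
            parts.append((part, stage))
            for tissue, n in part_counts.items():
                counts[f"{stage}:{tissue}"] = n
    if spec.n_stages > 1:
        si, remap = compose_montage(parts, axis="horizontal")
        if remap:
            raise AtlasPaintError("generator colors collided across stages")
    stats = SegmentStats(
        counts=counts,
        bboxes={sid: None for sid in counts},
        stages={
            sid: (sid.split(":", 1)[0] if ":" in sid else "") for sid in counts
        },
        background_pixels=si.size[0] * si.size[1] - sum(counts.values()),
        unknown_pixels=0,
        total_pixels=si.size[0] * si.size[1],
    )
    return si, stats


def make_dataset(
    spec: FixtureSpec, legend: SegmentLegend
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Assign a spatial pattern to every gene and emit the value table.

    Patterns (drawn per ``pattern_mix``): ``tissue_specific`` — high in
    1–2 chosen tissues across all stages, low elsewhere;
    ``stage_specific`` — high in every tissue of one stage;
    ``ubiquitous`` — the same mid-high value everywhere; ``graded`` —
    values rise linearly along the stage order.  Gaussian noise of sd
    ``noise_sd`` is added and clipped to ``value_range``.  The returned
    truth table records each gene's pattern and target segments.
    """
    rng = np.random.default_rng(spec.seed + 1)
    lo, hi = spec.value_range
    mid = lo + 0.6 * (hi - lo)
    tissues = spec.tissues()
    stages = spec.stages() if spec.n_stages > 1 else ("",)
    segment_ids = legend.spatial_ids()

    def seg_id(stage: str, tissue: str) -> str:
        return f"{stage}:{tissue}" if stage else tissue

    names = list(PATTERNS)
    probs = np.array([spec.pattern_mix.get(p, 0.0) for p in names])
    rows: list[dict[str, object]] = []
    truth_rows: list[dict[str, str]] = []
    for gene in spec.genes():
        pattern = str(rng.choice(names, p=probs))
        targets: list[str] = []
        values: dict[str, float] = {}
        if pattern == "tissue_specific":
            k = int(rng.integers(1, min(2, len(tissues)) + 1))
            chosen = sorted(rng.choice(len(tissues), size=k, replace=False).tolist())
            chosen_tissues = {tissues[i] for i in chosen}
            for stage in stages:
                for tissue in tissues:
                    high = tissue in chosen_tissues
                    values[seg_id(stage, tissue)] = hi if high else lo
            targets = sorted(
                seg_id(stage, t) for stage in stages for t in chosen_tissues
            )
        elif pattern == "stage_specific":
            stage_i = int(rng.integers(0, len(stages)))
            for s, stage in enumerate(stages):
                for tissue in tissues:
                    values[seg_id(stage, tissue)] = hi if s == stage_i else lo
            targets = sorted(seg_id(stages[stage_i], t) for t in tissues)
        elif pattern == "ubiquitous":
            for stage in stages:
                for tissue in tissues:
                    values[seg_id(stage, tissue)] = mid
            targets = sorted(values)
        else:  # graded
            for s, stage in enumerate(stages):
                level = lo + (hi - lo) * (s + 1) / len(stages)
                for tissue in tissues:
                    values[seg_id(stage, tissue)] = level
            targets = sorted(seg_id(stages[-1], t) for t in tissues)
        for sid in segment_ids:
            v = values[sid]
            if spec.noise_sd > 0:
                v = float(np.clip(v + rng.normal(0.0, spec.noise_sd), lo, hi))
            rows.append(
                {
                    "gene_id": gene,
                    "spatial_id": sid,
                    "condition": "default",
                    "time": "",
                    "replicate": 1,
                    "value": v,
                }
            )
        truth_rows.append(
            {"gene_id": gene, "pattern": pattern, "targets": ";".join(targets)}
        )
    frame = pd.DataFrame(rows, columns=COLUMNS)
    meta = ExperimentMetadata(
        project_name=f"synthetic bundle seed={spec.seed}",
        subjects=f"{spec.n_stages} stage(s) x {spec.n_tissues} tissue(s)",
        source_note="synthetic data from atlaspaint.fixtures",
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "pattern", "targets"])
    return ExpressionDataset(frame, meta), truth


def classify_pattern(
    values: dict[str, float], legend: SegmentLegend, tol: float = 0.05
) -> str:
    """Label a gene's per-segment values with one of the four patterns.

    The decision rule mirrors how a biologist reads the painted image:
    near-constant color means ubiquitous; a strictly rising stage
    profile means graded; otherwise the high segments are compared to
    whole-stage and whole-tissue footprints.  ``tol`` is relative to
    the value spread.
    """
    ids = legend.spatial_ids()
    vs = np.array([values[sid] for sid in ids])
    spread = float(vs.max() - vs.min())
    if spread < tol * max(abs(vs).max(), 1.0):
        return "ubiquitous"
    stages = legend.stages()
    if len(stages) >= 3:
        stage_means = [
            np.mean([values[e.spatial_id] for e in legend.entries if e.stage == s])
            for s in stages
        ]
        diffs = np.diff(stage_means)
        if np.all(diffs > tol * spread) or np.all(diffs < -tol * spread):
            return "graded"
    threshold = vs.min() + spread / 2
    high = {sid for sid in ids if values[sid] > threshold}
    if stages:
        for s in stages:
            stage_ids = {e.spatial_id for e in legend.entries if e.stage == s}
            if high == stage_ids:
                return "stage_specific"
        tissue_of = {sid: sid.split(":", 1)[1] if ":" in sid else sid for sid in ids}
        high_tissues = {tissue_of[sid] for sid in high}
        footprint = {sid for sid in ids if tissue_of[sid] in high_tissues}
        if high == footprint:
            return "tissue_specific"
        return "other"
    return "tissue_specific"


def make_network(spec: FixtureSpec, n_nodes: int | None = None) -> OmicsNetwork:
    """A small regulatory topology over the bundle's gene identifiers.

    One hub regulator with out-edges to every other node, a three-gene
    feedback cycle, and a positive autoregulatory self-loop — the motif
    vocabulary of developmental regulator networks.  Node positions lie
    on a circle; fully deterministic under the fixture seed.
    """
    genes = list(spec.genes())
    if n_nodes is None:
        n_nodes = min(len(genes), 8)
    if n_nodes < 2:
        raise AtlasPaintError("network needs at least 2 nodes")
    chosen = genes[:n_nodes]
    nodes: list[NetworkNode] = []
    for i, gene in enumerate(chosen):
        angle = 2.0 * np.pi * i / n_nodes
        nodes.append(
            NetworkNode(
                id=gene,
                label=gene,
                position=(
                    float(round(250.0 + 180.0 * np.cos(angle), 1)),
                    float(round(250.0 + 180.0 * np.sin(angle), 1)),
                ),
                size=(80.0, 60.0),
                node_class="macromolecule",
            )
        )
    hub = chosen[0]
    edges = [
        NetworkEdge(source_id=hub, target_id=g, interaction="activation")
        for g in chosen[1:]
    ]
    if n_nodes >= 4:
        a, b, c = chosen[1], chosen[2], chosen[3]
        edges.append(NetworkEdge(source_id=a, target_id=b, interaction="activation"))
        edges.append(NetworkEdge(source_id=b, target_id=c, interaction="inhibition"))
        edges.append(NetworkEdge(source_id=c, target_id=a, interaction="activation"))
    edges.append(
        NetworkEdge(source_id=chosen[1], target_id=chosen[1], interaction="activation")
    )
    return OmicsNetwork(nodes=nodes, edges=edges, directed=True, source_format="generated")


_USECASES: dict[str, dict] = {
    "flower_like": dict(
        n_tissues=4,
        n_stages=1,
        n_genes=10,
        image_size=(120, 120),
        tissue_names=FLOWER_TISSUES,
        gene_names=FLOWER_GENES,
        pattern_mix={
            "tissue_specific": 0.8,
            "stage_specific": 0.0,
            "ubiquitous": 0.2,
            "graded": 0.0,
        },
    ),
    "seed_like": dict(
        n_tissues=7,
        n_stages=4,
        n_genes=100,
        image_size=(400, 100),
        tissue_names=SEED_TISSUES,
        stage_names=SEED_STAGES,
        pattern_mix={
            "tissue_specific": 0.4,
            "stage_specific": 0.3,
            "ubiquitous": 0.1,
            "graded": 0.2,
        },
    ),
}


def usecase_spec(
    which: Literal["flower_like", "seed_like"], seed: int, **overrides
) -> FixtureSpec:
    if which not in _USECASES:
        raise AtlasPaintError(
            f"unknown usecase {which!r}; choose from {sorted(_USECASES)}"
        )
    params = dict(_USECASES[which])
    params.update(overrides)
    if "gene_names" in params and params.get("n_genes", 0) > len(
        params["gene_names"] or ()
    ):
        params["gene_names"] = None
    return FixtureSpec(seed=seed, **params)


def make_usecase_bundle(
    which: Literal["flower_like", "seed_like"],
    seed: int,
    out_dir: str | Path,
    **overrides,
) -> dict[str, Path]:
    """Write a complete synthetic bundle into a directory.

    Files: ``template.tsv``, ``source.png``, ``labels.png``,
    ``legend.tsv``, ``network.gml``, ``truth.tsv``.  Returns the path of
    each file keyed by its role.
    """
    spec = usecase_spec(which, seed, **overrides)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    si, _stats = make_segmented_image(spec)
    ds, truth = make_dataset(spec, si.legend)
    net = make_network(spec)
    paths = {
        "template": write_template(ds, out_dir / "template.tsv"),
        "source": save_image(si.source, out_dir / "source.png"),
        "labels": save_image(si.labels, out_dir / "labels.png"),
        "legend": write_legend(si.legend, out_dir / "legend.tsv"),
        "network": write_network(net, out_dir / "network.gml", format="gml"),
    }
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out_dir / "truth.tsv"
    return paths
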