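# Methods

## Data model

The expression template is a long-format table with one (possibly
missing) value per `(gene_id, spatial_id, condition, time, replicate)`
cell, preceded by a commented metadata header (`#project_name: …`).
Plain TSV is the canonical format; CSV and `.xlsx` are convenience
dialects translated into the same in-memory model (a pandas DataFrame
behind `ExpressionDataset`).  A missing value is an explicit state
(NaN), never zero: "not measured" and "not expressed" must stay
distinguishable, and painting treats them differently (a missing
segment keeps its anatomical appearance).

Replicates are averaged (mean by default, median selectable) before
painting, because exactly one value can be assigned to a segment.
Aggregation is idempotent, skips missing replicates, and leaves an
all-missing group missing.

Condition contrasts are materialised as a derived dataset with
condition label `a-b` and values `value(a) − value(b)` per
`(gene, spatial, time)`; a pair missing on either side is missing in
the difference.  The operation is antisymmetric on present pairs.

## Labelfields and legends

A segmented image is a pair of pixel-aligned rasters — the source
anatomical image and its labelfield, in which every region of interest
is flat-filled with one unique RGB color — plus a legend TSV
(`color_hex, spatial_id, stage, display_name`).  The original
interactive color↔tissue assignment step is replaced here by this
declarative side file.

Label matching is **exact RGB equality, tolerance zero**.  Labelfields
are flat paint images; a tolerance would turn anti-aliased boundary
pixels into spurious segment members.  Pixels matching neither a legend
color nor a background color (pure white and pure black by default) are
classified *unknown*, reported as a count and fraction, and never
painted.  A high unknown fraction is the diagnostic signature of a
lossy (JPEG) labelfield, and loading a JPEG labelfield warns for the
same reason.  Alpha channels are flattened against white at load time.

Coordinates follow the raster convention: origin top-left, x rightward,
y downward, half-open bounding boxes `(x0, y0, x1, y1)`.

Developmental series use a **montage**: per-stage panels concatenated
along one axis so a single labelfield covers every stage.  The
composite segment identity is `stage:tissue`, which is also the
spatial identifier the template must carry (split on the first colon).
This keeps legend spatial ids globally unique while the same tissue
recurs in every stage.  Label colors that collide across panels are
remapped deterministically to fresh colors, and the remap table is
returned so external references can be updated.  Smaller panels are
padded with background.

## Color scales and painting

The default scale is a diverging blue → white → red ramp: red encodes
high and blue low expression, and white is our choice of midpoint color
for print legibility.  Three domain policies exist:

* **global** (default): domain = [min, max] over every value in the
  dataset.  This is the load-bearing choice — one shared scale makes
  equal values paint equal colors across genes, segments and stages,
  which is what makes a grid of per-gene images comparable at a glance.
* **symmetric**: domain = [−m, +m] with m = max |value|, midpoint
  pinned to 0.  Used for difference datasets so "no change" is always
  the midpoint color.
* **per_gene**: one scale per gene (each gene's own min/max), for
  within-gene contrast at the cost of between-gene comparability.

Interpolation is linear per 8-bit channel with **round-half-up**; the
rounding rule is stated because it makes painted colors exactly
predictable and invertible.  `invert_color` solves the interpolation on
the widest-span channel, so with full-span endpoints a recovered value
is within (domain span)/255 of the original — the quantization floor of
an 8-bit encoding.  Out-of-domain values are clamped rather than
rejected (they arise legitimately when a global scale is reused on a
subset).  A degenerate domain (all values equal) maps everything to the
midpoint color and warns.  `blend_alpha` < 1 alpha-blends the
expression color over the source so anatomical texture (e.g. an
electron-microscopy image) remains visible; the default 1.0 replaces
segment pixels outright.

Painting copies the source raster and recolors only the masks of
segments with present values; background, unknown pixels and
missing-value segments are untouched, so everything outside the painted
segments is bit-identical to the source.

## Networks

GML is the lossless interchange format: layout (`graphics [ x y w h ]`),
class strings, image references and unknown keys all survive a
write/read cycle.  Parsing and serialisation are delegated to
networkx's GML reader/writer behind the module surface; one consequence
is that edge *order* within the file follows adjacency storage, so
round-trip guarantees are stated (and tested) on the edge multiset, not
the sequence.  SIF and edge-list CSV carry topology only; writing SIF
from a network with layout warns about the documented loss.  SBML is
consumed as topology: species become nodes and each reaction becomes
one intermediate process node with reactant→reaction→product edges
(reaction-centric hyperedge expansion keeps the node/edge model
simple).  SBGN-style maps are accepted as GML exports; the glyph class
is carried verbatim in `node_class` but glyph shapes are not re-drawn —
nodes render as rounded rectangles (dashed border when classed),
because the embedded pictograph, not the glyph, is the visual payload
here.

Image attachment matches the manifest's gene ids against the node
**label** by default (network files usually carry display names like
"AP1", not locus ids), with `match_attr="id"` and an opt-in
case-folding flag as alternatives.  Matching is a pure set
intersection: unmatched nodes and unused images are report content,
never errors, and the operation is idempotent.  Matched nodes are
resized to the image aspect ratio at a fixed 60 px node height.  The
CLI stores image references relative to the output GML's directory so
that identical pipelines run in different directories produce
byte-identical files.

## Rendering and export

All exports are deterministic by construction: no timestamps, sorted
iteration, fixed fonts.  SVG is built as plain XML with painted rasters
embedded losslessly as base64 PNG; edges carry `class="edge"` (which
also makes the rendered edge count machine-checkable), activation-like
interactions end in an arrowhead and inhibition-like ones in a bar.
PNG renders draw the same scene with Pillow.  Nodes without positions
receive a deterministic grid layout.

Grid sheets implement visual clustering as an *input*: the caller's
image order (typically arranged so similar patterns sit together) is
laid out row-major in uniform cells of the maximum image size plus a
16 px caption strip; a stack is a one-column grid, the static
replacement for interactive side-panel stacking of a node selection.
The HTML gallery is a self-contained directory (index page + copied
images) whose entries may wrap their image in a hyperlink, enabling
links out to other networks or database records; it renders without
network access.

## Synthetic bundles

The generator emulates the two study designs end to end.  Defaults:

| parameter | flower_like | seed_like |
|---|---|---|
| stages × tissues | 1 × 4 (sepal, petal, stamen, carpel) | 4 × 7 seed tissues |
| genes | 10 floral regulators (AP1 … SEP3, LFY) | 100 (`G001` …) |
| image | 120 × 120 px | 400 × 100 px (4 panels of 100 px) |
| pattern mix | 0.8 tissue-specific, 0.2 ubiquitous | 0.4 / 0.3 / 0.1 / 0.2 tissue / stage / ubiquitous / graded |
| noise sd | 0 | 0 |
| value range | 0–10 | 0–10 |

Stage panels are white-margined strips of flat-colored tissue bands;
label colors come from a maximally spaced hue wheel (phase-shifted by
the seed) so they are pairwise distinct and never collide with the
white/black background.  The generator records its own pixel tally as
it paints, which `extract_segments` is tested against.  Expression
patterns are two-level (high in the target segments, low elsewhere),
with `graded` rising linearly along the stage order and `ubiquitous`
constant at 60 % of the range; Gaussian noise (sd = `noise_sd`) is
added and clipped to the value range.  All randomness flows from one
`numpy.random.Generator` seeded with the single bundle seed, so equal
seeds give byte-identical bundles.  On a single-stage spec the
stage-structured pattern mass is folded into tissue-specific, since a
stage pattern is undefined there.

What the synthetic data does *not* emulate: realistic expression
distributions, measurement noise models, irregular segment shapes,
anti-aliased labelfields, or identifier mismatches between template and
legend.  Passing tests therefore demonstrate the correctness of the
pipeline's transformations (value→color→value fidelity, pixel
conservation, montage equivalence, format round-trips, determinism),
not robustness to dirty real-world inputs — except where tests
construct dirty inputs explicitly (unknown pixels, JPEG labelfields,
malformed files).

## Problem sizes and numerical choices

The quantitative checks run on the seed-style bundle at its native
scale (100 genes × 28 segments on a 400 × 100 px montage) and a
20-node network; the template-shape check generates a 400-gene
template.  The whole verification suite completes in well under a
minute on one core.  Tolerances: color inversion is exact up to
(domain span)/255; every raster comparison is exact (bit-identical);
tie-breaks (round-half-up, lexicographic gene order, first-appearance
stage order, deterministic fresh-color search) are fixed so that no
output depends on iteration order or platform.

## Known limitations

* One value per segment: no within-segment gradients or per-pixel maps.
* Exact-color matching presumes losslessly stored labelfields.
* GML numeric node ids are regenerated on write; files whose node
  identity lives only in non-label attributes need those attributes
  (they are preserved verbatim, but not used as ids).
* Difference views compare exactly two conditions; factorial designs
  must be reduced pairwise.
* Network layouts are consumed, not computed; the grid fallback is a
  placeholder, not an aesthetic layout.
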