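# atlaspaint

Paint anatomical image segments from expression values, and embed the
resulting per-gene pictographs into biological networks.

## The problem

Spatially resolved transcriptome datasets — expression measured per
tissue, per developmental stage, per condition — are usually read off
heatmaps, which discard the anatomy the samples came from.  A far more
intuitive display colors the anatomical diagram itself: every segment
of a 2D image of the organ is filled with a color encoding the
expression level measured in that tissue, giving one small pictograph
per gene (the familiar style of tissue-expression "electronic
pictograph" browsers).  Laid out as a grid, hundreds of genes can be
screened at a glance; embedded into the nodes of a gene-regulatory
network, the spatial patterns appear directly in their regulatory
context.

`atlaspaint` implements that two-step integration as a scriptable
library and CLI:

1. **expression → image.** A long-format template (gene, spatial id,
   condition, time, replicate, value) is joined to a *labelfield* — a
   second raster, pixel-aligned with the source image, in which every
   region of interest is flat-filled with a unique color — through a
   legend that maps label colors to spatial identifiers.  Every pixel
   of a measured segment is recolored through a **global color scale**
   (diverging blue → white → red by default; blue = low, red = high),
   so equal expression means equal color across all genes, segments
   and stages.  Developmental series are handled by concatenating
   stage panels into a single **montage** whose segment identity is
   `stage:tissue`; condition contrasts are painted as per-segment
   differences on a symmetric diverging scale centred on zero.
2. **image → network.** Painted images are attached to the nodes of a
   network (GML / SIF / edge-list CSV / SBML topology) by exact
   gene-identifier matching, and the mapped network is rendered to
   SVG/PNG with the pictographs drawn inside the node boxes.  Grids,
   stacked strips and a static HTML gallery cover publication and
   web export.

Formally, a sequential scale maps a value $v$ on domain
$[v_{\min}, v_{\max}]$ to the color
$c(v) = c_{\mathrm{low}} + \tfrac{v - v_{\min}}{v_{\max} - v_{\min}}
(c_{\mathrm{high}} - c_{\mathrm{low}})$, rounded half-up per 8-bit
channel; the diverging scale applies the same interpolation piecewise
on either side of the midpoint.  Because the rounding is the only loss,
painted colors are invertible back to values within $1/255$ of the
domain span — painting is a lossless visual encoding up to color
quantization, and the test suite checks exactly that.

A deterministic synthetic-data generator (`atlaspaint.fixtures`)
produces complete bundles — labelfield, legend, template, regulatory
network, ground truth — emulating two canonical study designs: a
four-whorl flower image with ~10 floral regulators, and a four-stage ×
seven-tissue seed-development montage with 100 regulatory genes.

## Worked example

```
$ atlaspaint simulate --usecase flower_like --seed 5 -o bundle
template: bundle/template.tsv
source: bundle/source.png
labels: bundle/labels.png
legend: bundle/legend.tsv
network: bundle/network.gml
truth: bundle/truth.tsv

$ atlaspaint template validate bundle/template.tsv
bundle/template.tsv: 40 records, 10 genes, 4 spatial ids, conditions ['default']

$ atlaspaint segments bundle/source.png bundle/labels.png --legend bundle/legend.tsv
  spatial_id stage  pixels         bbox
       sepal          2916   6,6,114,33
       petal          2916  6,33,114,60
      stamen          2916  6,60,114,87
      carpel          2916 6,87,114,114
<background>          2736
   <unknown>             0

$ atlaspaint paint bundle/template.tsv bundle/source.png bundle/labels.png \
      --legend bundle/legend.tsv --out painted
painted 10 gene image(s) into painted

$ atlaspaint map-network bundle/network.gml --images painted/manifest.tsv -o mapped.gml
matched 8/8 nodes; 2 unused image(s); wrote mapped.gml

$ atlaspaint render mapped.gml -o figure.svg
wrote figure.svg
```

The `segments` report shows the four floral whorls, each 2916 px, with
zero unknown pixels — a clean, lossless labelfield.  `paint` writes one
PNG per gene (`AP1__default.png`, …) plus a `manifest.tsv` and a
color-bar legend; `map-network` matches the painted genes to the eight
network nodes by display label (the two unused images belong to genes
absent from the network) and records the mapping; `render` produces a
deterministic SVG with each gene's pictograph embedded in its node.
`atlaspaint grid`, `atlaspaint gallery` and `atlaspaint diff` cover
grid sheets, the static web gallery, and condition-difference views.

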