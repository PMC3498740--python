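"""Biological network IO and image-to-node mapping.

Supported formats: classic key-value GML (topology + ``graphics`` layout
+ arbitrary attributes, round-trip safe), SIF and edge-list CSV
(topology only), and the topology subset of SBML (species become nodes,
each reaction becomes one intermediate process node with
reactant->reaction->product edges).

Painted images are attached to nodes by gene-identifier equality —
against the display label by default, since network files usually carry
display names like "AP1" rather than locus ids — with an opt-in
case-folding flag.  Gaps (unmatched nodes, unused images) are report
content, never errors.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import networkx as nx
import pandas as pd

from atlaspaint.errors import NetworkFormatError


@dataclass
class NetworkNode:
    id: str
    label: str = ""
    position: tuple[float, float] | None = None
    size: tuple[float, float] | None = None
    node_class: str = ""
    image_ref: str | None = None
    attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label:
            self.label = self.id


@dataclass
class NetworkEdge:
    source_id: str
    target_id: str
    interaction: str = ""
    attrs: dict[str, str] = field(default_factory=dict)


@dataclass
class OmicsNetwork:
    """Attributed nodes and edges with optional layout."""

    nodes: list[NetworkNode]
    edges: list[NetworkEdge]
    directed: bool = True
    source_format: str = ""

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise NetworkFormatError(f"duplicate node id {dup!r}")
        id_set = set(ids)
        for e in self.edges:
            for end in (e.source_id, e.target_id):
                if end not in id_set:
                    raise NetworkFormatError(
                        f"edge {e.source_id}->{e.target_id} references missing node {end!r}"
                    )

    def node(self, node_id: str) -> NetworkNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise NetworkFormatError(f"no node with id {node_id!r}")

    def has_layout(self) -> bool:
        return any(n.position is not None for n in self.nodes)

    def apply_grid_layout(self, spacing: float = 120.0) -> None:
        """Assign a deterministic grid layout to position-less nodes."""
        import math

        cols = max(1, math.ceil(math.sqrt(len(self.nodes))))
        for i, node in enumerate(self.nodes):
            if node.position is None:
                node.position = (spacing * (i % cols), spacing * (i // cols))


@dataclass
class MappingReport:
    matched: list[str]
    unmatched: list[str]
    unused_images: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "matched", "id": m} for m in self.matched]
        rows += [{"kind": "unmatched_node", "id": m} for m in self.unmatched]
        rows += [{"kind": "unused_image", "id": m} for m in self.unused_images]
        return pd.DataFrame(rows, columns=["kind", "id"])


# ---------------------------------------------------------------------------
# readers

_RESERVED_NODE_KEYS = {"label", "graphics", "image_ref", "node_class"}


def _read_gml(path: Path) -> OmicsNetwork:
    try:
        g = nx.read_gml(path, label="id")
    except Exception as exc:  # nx raises various parse errors
        raise NetworkFormatError(f"cannot parse GML {path}: {exc}") from exc
    nodes: list[NetworkNode] = []
    id_map: dict[object, str] = {}
    for gml_id, data in g.nodes(data=True):
        label = str(data.get("label", gml_id))
        node_id = label if label else str(gml_id)
        # GML node ids are numeric; the label is the biological identifier
        if node_id in id_map.values():
            node_id = f"{node_id}#{gml_id}"
        id_map[gml_id] = node_id
        graphics = data.get("graphics", {}) or {}
        position = None
        size = None
        if "x" in graphics and "y" in graphics:
            position = (float(graphics["x"]), float(graphics["y"]))
        if "w" in graphics and "h" in graphics:
            size = (float(graphics["w"]), float(graphics["h"]))
        attrs = {
            str(k): str(v) for k, v in data.items() if k not in _RESERVED_NODE_KEYS
        }
        for k, v in graphics.items():
            if k not in {"x", "y", "w", "h"}:
                attrs[f"graphics.{k}"] = str(v)
        nodes.append(
            NetworkNode(
                id=node_id,
                label=label,
                position=position,
                size=size,
                node_class=str(data.get("node_class", "")),
                image_ref=data.get("image_ref"),
                attrs=attrs,
            )
        )
    edges = [
        NetworkEdge(
            source_id=id_map[u],
            target_id=id_map[v],
            interaction=str(data.get("label", data.get("interaction", ""))),
            attrs={
                str(k): str(v)
                for k, v in data.items()
                if k not in {"label", "interaction"}
            },
        )
        for u, v, data in g.edges(data=True)
    ]
    return OmicsNetwork(
        nodes=nodes, edges=edges, directed=g.is_directed(), source_format="gml"
    )


def _read_sif(path: Path) -> OmicsNetwork:
    nodes: dict[str, NetworkNode] = {}
    edges: list[NetworkEdge] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1:
                nodes.setdefault(fields[0], NetworkNode(id=fields[0]))
                continue
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: SIF line needs source, interaction, target(s)"
                )
            src, interaction, targets = fields[0], fields[1], fields[2:]
            nodes.setdefault(src, NetworkNode(id=src))
            for tgt in targets:
                nodes.setdefault(tgt, NetworkNode(id=tgt))
                edges.append(
                    NetworkEdge(source_id=src, target_id=tgt, interaction=interaction)
                )
    return OmicsNetwork(
        nodes=list(nodes.values()), edges=edges, directed=True, source_format="sif"
    )


def _read_edge_csv(path: Path) -> OmicsNetwork:
    frame = pd.read_csv(path, dtype=str).fillna("")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "source" not in frame or "target" not in frame:
        raise NetworkFormatError(
            f"edge CSV needs source,target columns; found {list(frame.columns)}"
        )
    nodes: dict[str, NetworkNode] = {}
    edges: list[NetworkEdge] = []
    for row in frame.itertuples(index=False):
        src, tgt = row.source.strip(), row.target.strip()
        nodes.setdefault(src, NetworkNode(id=src))
        nodes.setdefault(tgt, NetworkNode(id=tgt))
        edges.append(
            NetworkEdge(
                source_id=src,
                target_id=tgt,
                interaction=getattr(row, "interaction", ""),
            )
        )
    return OmicsNetwork(
        nodes=list(nodes.values()), edges=edges, directed=True, source_format="edge_csv"
    )


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_sbml_topology(path: Path) -> OmicsNetwork:
    """Species -> nodes; each reaction -> one process node with
    reactant->reaction->product edges (hyperedge expansion)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise NetworkFormatError(f"cannot parse SBML {path}: {exc}") from exc
    root = tree.getroot()
    nodes: dict[str, NetworkNode] = {}
    edges: list[NetworkEdge] = []
    for elem in root.iter():
        if _localname(elem.tag) != "species":
            continue
        sid = elem.get("id", "")
        if not sid:
            raise NetworkFormatError(f"{path}: species element without id")
        nodes[sid] = NetworkNode(
            id=sid, label=elem.get("name", sid), node_class="species"
        )
    for elem in root.iter():
        if _localname(elem.tag) != "reaction":
            continue
        rid = elem.get("id", "")
        if not rid:
            raise NetworkFormatError(f"{path}: reaction element without id")
        nodes[rid] = NetworkNode(
            id=rid, label=elem.get("name", rid), node_class="reaction"
        )
        reactants, products = [], []
        for lst in elem:
            lname = _localname(lst.tag)
            if lname in {"listOfReactants", "listOfProducts"}:
                refs = [
                    ref.get("species")
                    for ref in lst
                    if _localname(ref.tag) == "speciesReference"
                ]
                (reactants if lname == "listOfReactants" else products).extend(refs)
        for sp in reactants:
            if sp not in nodes:
                raise NetworkFormatError(
                    f"{path}: reaction {rid} references missing species {sp!r}"
                )
            edges.append(NetworkEdge(source_id=sp, target_id=rid, interaction="reactant"))
        for sp in products:
            if sp not in nodes:
                raise NetworkFormatError(
                    f"{path}: reaction {rid} references missing species {sp!r}"
                )
            edges.append(NetworkEdge(source_id=rid, target_id=sp, interaction="product"))
    return OmicsNetwork(
        nodes=list(nodes.values()),
        edges=edges,
        directed=True,
        source_format="sbml_topology",
    )


_READERS = {
    "gml": _read_gml,
    "sif": _read_sif,
    "edge_csv": _read_edge_csv,
    "sbml_topology": _read_sbml_topology,
}

_EXT_FORMAT = {
    ".gml": "gml",
    ".sif": "sif",
    ".csv": "edge_csv",
    ".sbml": "sbml_topology",
    ".xml": "sbml_topology",
}


def read_network(
    path: str | Path,
    format: Literal["gml", "sif", "edge_csv", "sbml_topology"] | None = None,
) -> OmicsNetwork:
    """Read a network file; the format is inferred from the extension
    when not given."""
    path = Path(path)
    if not path.exists():
        raise NetworkFormatError(f"network file not found: {path}")
    if format is None:
        format = _EXT_FORMAT.get(path.suffix.lower())
        if format is None:
            raise NetworkFormatError(f"cannot infer network format from {path.name!r}")
    if format not in _READERS:
        raise NetworkFormatError(f"unsupported network format {format!r}")
    return _READERS[format](path)


# ---------------------------------------------------------------------------
# writers


def _to_nx(net: OmicsNetwork) -> nx.DiGraph | nx.Graph:
    g: nx.DiGraph | nx.Graph = nx.DiGraph() if net.directed else nx.Graph()
    for node in net.nodes:
        data: dict[str, object] = {"label": node.label}
        graphics: dict[str, object] = {}
        if node.position is not None:
            graphics["x"], graphics["y"] = map(float, node.position)
        if node.size is not None:
            graphics["w"], graphics["h"] = map(float, node.size)
        for k, v in sorted(node.attrs.items()):
            if k.startswith("graphics."):
                graphics[k.split(".", 1)[1]] = v
            else:
                data[k] = v
        if graphics:
            data["graphics"] = graphics
        if node.node_class:
            data["node_class"] = node.node_class
        if node.image_ref:
            data["image_ref"] = node.image_ref
        g.add_node(node.id, **data)
    for edge in net.edges:
        data = dict(sorted(edge.attrs.items()))
        if edge.interaction:
            data["label"] = edge.interaction
        g.add_edge(edge.source_id, edge.target_id, **data)
    return g


def write_network(
    net: OmicsNetwork, path: str | Path, format: Literal["gml", "sif"] = "gml"
) -> Path:
    """Write GML (lossless round-trip) or SIF (topology only)."""
    path = Path(path)
    if format == "gml":
        nx.write_gml(_to_nx(net), path)
        return path
    if format == "sif":
        if net.has_layout():
            warnings.warn(
                "SIF carries topology only; layout information is dropped",
                stacklevel=2,
            )
        linked: set[str] = set()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for e in net.edges:
                fh.write(f"{e.source_id}\t{e.interaction or 'interacts'}\t{e.target_id}\n")
                linked.update((e.source_id, e.target_id))
            for n in net.nodes:
                if n.id not in linked:
                    fh.write(f"{n.id}\n")
        return path
    raise NetworkFormatError(f"unsupported output format {format!r}")


# ---------------------------------------------------------------------------
# image mapping


def attach_images(
    net: OmicsNetwork,
    images: Mapping[str, str],
    match_attr: Literal["id", "label"] = "label",
    case_fold: bool = False,
) -> tuple[OmicsNetwork, MappingReport]:
    """Attach painted images to nodes with equal gene identifiers.

    ``images`` maps gene_id -> image path.  Matched nodes receive
    ``image_ref`` and are resized to a height-60 box preserving the
    image aspect ratio recorded in the manifest path's raster when the
    file exists (otherwise the node size is left unchanged).  Returns a
    new network plus a report of matched/unmatched nodes and unused
    images; idempotent.
    """
    from PIL import Image

    key_of = (lambda s: s.casefold()) if case_fold else (lambda s: s)
    manifest = {key_of(k): (k, v) for k, v in images.items()}
    if len(manifest) != len(images):
        raise NetworkFormatError("image manifest keys collide under case folding")

    matched: list[str] = []
    unmatched: list[str] = []
    used: set[str] = set()
    new_nodes: list[NetworkNode] = []
    for node in net.nodes:
        token = node.id if match_attr == "id" else node.label
        hit = manifest.get(key_of(token))
        if hit is None:
            unmatched.append(node.id)
            new_nodes.append(replace(node, attrs=dict(node.attrs)))
            continue
        gene, image_path = hit
        used.add(gene)
        matched.append(node.id)
        size = node.size
        p = Path(image_path)
        if p.exists():
            with Image.open(p) as im:
                w, h = im.size
            height = 60.0
            size = (height * w / h, height)
        new_nodes.append(
            replace(node, image_ref=str(image_path), size=size, attrs=dict(node.attrs))
        )
    report = MappingReport(
        matched=matched,
        unmatched=unmatched,
        unused_images=sorted(set(images) - used),
    )
    out = OmicsNetwork(
        nodes=new_nodes,
        edges=[replace(e, attrs=dict(e.attrs)) for e in net.edges],
        directed=net.directed,
        source_format=net.source_format,
    )
    return out, report


def relativize_image_refs(net: OmicsNetwork, base: str | Path) -> None:
    """Rewrite image_ref paths relative to ``base`` (in place).

    Keeps written network files free of absolute paths, so identical
    pipelines in different directories emit identical bytes.
    """
    import os

    base = Path(base)
    for node in net.nodes:
        if node.image_ref:
            node.image_ref = os.path.relpath(node.image_ref, base)


def resolve_image_refs(net: OmicsNetwork, base: str | Path) -> None:
    """Resolve relative image_ref paths against ``base`` (in place)."""
    base = Path(base)
    for node in net.nodes:
        if node.image_ref and not Path(node.image_ref).is_absolute():
            node.image_ref = str(base / node.image_ref)
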