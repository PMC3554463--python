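"""Attributed region-adjacency graphs (ARG/RAG) for segmented tissue images.

A segmented image is described by a graph G = (V, E, alpha, beta): one node
per connected region, carrying area, perimeter, tissue label (alpha) and
centroid; one undirected edge per pair of regions sharing a 4-connected
boundary, carrying centroid distance and common boundary length (beta).
Area/perimeter/distance/boundary-length are globally normalized to [0, 1]
against min/max statistics of the whole database; labels are categorical and
never normalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "NodeAttributes",
    "EdgeAttributes",
    "AttributedGraph",
    "NormalizationStats",
    "build_rag",
    "common_boundary_length",
    "centroid_distance",
    "compute_norm_stats",
    "normalize_graph",
    "write_graph",
    "read_graph",
    "to_networkx",
    "from_networkx",
]

NODE_FEATURES = ("area", "perimeter")
EDGE_FEATURES = ("dist", "blen")


@dataclass(frozen=True)
class NodeAttributes:
    """Attributes of one graph node (region).

    ``area`` and ``perimeter`` are raw pixel measurements; ``area_n`` /
    ``perimeter_n`` are their database-normalized values in [0, 1] (set by
    :func:`normalize_graph`).  ``label`` is the tissue class and is never
    normalized.
    """

    area: float
    perimeter: float
    label: int
    centroid: tuple[float, float]
    area_n: float | None = None
    perimeter_n: float | None = None

    @property
    def a(self) -> tuple[float, float]:
        """Attribute vector (area, perimeter) — normalized when available."""
        if self.area_n is not None:
            return (self.area_n, self.perimeter_n)  # type: ignore[return-value]
        return (self.area, self.perimeter)


@dataclass(frozen=True)
class EdgeAttributes:
    """Attributes of one undirected edge between adjacent regions."""

    dist: float
    blen: float
    dist_n: float | None = None
    blen_n: float | None = None

    @property
    def b(self) -> tuple[float, float]:
        if self.dist_n is not None:
            return (self.dist_n, self.blen_n)  # type: ignore[return-value]
        return (self.dist, self.blen)


def _edge_key(u: int, v: int) -> tuple[int, int]:
    if u == v:
        raise ValueError("self-loops are not allowed")
    return (u, v) if u < v else (v, u)


@dataclass
class AttributedGraph:
    """An attributed region-adjacency graph.

    Nodes are keyed by region id; edges by the unordered id pair.
    """

    nodes: dict[int, NodeAttributes] = field(default_factory=dict)
    edges: dict[tuple[int, int], EdgeAttributes] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for (u, v) in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) references a missing node")
            if u >= v:
                raise ValueError("edge keys must be sorted (u < v)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def add_node(self, node_id: int, attrs: NodeAttributes) -> None:
        self.nodes[node_id] = attrs

    def add_edge(self, u: int, v: int, attrs: EdgeAttributes) -> None:
        key = _edge_key(u, v)
        if key[0] not in self.nodes or key[1] not in self.nodes:
            raise ValueError(f"edge {key} references a missing node")
        self.edges[key] = attrs

    def edge(self, u: int, v: int) -> EdgeAttributes | None:
        return self.edges.get(_edge_key(u, v))

    def has_edge(self, u: int, v: int) -> bool:
        return _edge_key(u, v) in self.edges

    def neighbors(self, node_id: int) -> list[int]:
        out = []
        for (u, v) in self.edges:
            if u == node_id:
                out.append(v)
            elif v == node_id:
                out.append(u)
        return sorted(out)

    def label_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for attrs in self.nodes.values():
            counts[attrs.label] = counts.get(attrs.label, 0) + 1
        return counts

    def is_normalized(self) -> bool:
        return all(n.area_n is not None for n in self.nodes.values()) and all(
            e.dist_n is not None for e in self.edges.values()
        )


@dataclass(frozen=True)
class NormalizationStats:
    """Global per-feature min/max over every node and edge of a database."""

    area: tuple[float, float]
    perimeter: tuple[float, float]
    dist: tuple[float, float]
    blen: tuple[float, float]

    def __post_init__(self) -> None:
        for name in (*NODE_FEATURES, *EDGE_FEATURES):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name}: max < min")

    def scale(self, feature: str, x: float) -> float:
        """Map a raw value to [0, 1]; degenerate features (min == max) map
        to 0.0; out-of-range query values are clipped."""
        lo, hi = getattr(self, feature)
        if hi == lo:
            return 0.0
        return float(min(1.0, max(0.0, (x - lo) / (hi - lo))))

    def to_dict(self) -> dict:
        return {
            name: list(getattr(self, name))
            for name in (*NODE_FEATURES, *EDGE_FEATURES)
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(**{k: tuple(v) for k, v in d.items()})


def centroid_distance(
    c1: tuple[float, float], c2: tuple[float, float]
) -> float:
    """Euclidean distance between two (row, col) centroids, in pixels."""
    return float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))


def _adjacency_counts(assignment: np.ndarray) -> dict[tuple[int, int], int]:
    """Count 4-adjacent pixel pairs straddling two different regions."""
    counts: dict[tuple[int, int], int] = {}
    for a, b in (
        (assignment[:, :-1], assignment[:, 1:]),
        (assignment[:-1, :], assignment[1:, :]),
    ):
        m = (a != b) & (a > 0) & (b > 0)
        if not m.any():
            continue
        lo = np.minimum(a[m], b[m])
        hi = np.maximum(a[m], b[m])
        pairs, n = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        for (u, v), c in zip(pairs, n):
            key = (int(u), int(v))
            counts[key] = counts.get(key, 0) + int(c)
    return counts


def common_boundary_length(assignment: np.ndarray, i: int, j: int) -> int:
    """Number of 4-adjacent pixel pairs with one pixel in region i, one in j."""
    if i == j:
        raise ValueError("a region has no common boundary with itself")
    present = np.unique(assignment)
    for rid in (i, j):
        if rid not in present:
            raise ValueError(f"unknown region id {rid}")
    return _adjacency_counts(assignment).get(_edge_key(i, j), 0)


def build_rag(rm) -> AttributedGraph:
    """Build the region-adjacency graph of a (filtered) RegionMap.

    One node per region; one undirected edge per region pair with a positive
    common 4-connected boundary length.
    """
    g = AttributedGraph()
    for r in rm.regions:
        g.add_node(
            r.id,
            NodeAttributes(
                area=float(r.area),
                perimeter=float(r.perimeter),
                label=r.label,
                centroid=r.centroid,
            ),
        )
    by_id = {r.id: r for r in rm.regions}
    for (u, v), blen in _adjacency_counts(rm.assignment).items():
        g.add_edge(
            u,
            v,
            EdgeAttributes(
                dist=centroid_distance(by_id[u].centroid, by_id[v].centroid),
                blen=float(blen),
            ),
        )
    return g


def compute_norm_stats(graphs: list[AttributedGraph]) -> NormalizationStats:
    """Global min/max of every node/edge feature over a graph database."""
    areas: list[float] = []
    perims: list[float] = []
    dists: list[float] = []
    blens: list[float] = []
    for g in graphs:
        for n in g.nodes.values():
            areas.append(n.area)
            perims.append(n.perimeter)
        for e in g.edges.values():
            dists.append(e.dist)
            blens.append(e.blen)
    if not areas:
        raise ValueError("database contains no nodes")

    def mm(vals: list[float]) -> tuple[float, float]:
        return (min(vals), max(vals)) if vals else (0.0, 0.0)

    return NormalizationStats(
        area=mm(areas), perimeter=mm(perims), dist=mm(dists), blen=mm(blens)
    )


def normalize_graph(
    g: AttributedGraph, stats: NormalizationStats
) -> AttributedGraph:
    """Return a copy of ``g`` with normalized attribute fields filled in.

    Raw values are retained so the graph can be re-normalized against a
    different database.  Labels and centroids are untouched.
    """
    out = AttributedGraph(provenance=g.provenance)
    for nid, n in g.nodes.items():
        out.add_node(
            nid,
            replace(
                n,
                area_n=stats.scale("area", n.area),
                perimeter_n=stats.scale("perimeter", n.perimeter),
            ),
        )
    for (u, v), e in g.edges.items():
        out.add_edge(
            u,
            v,
            replace(
                e,
                dist_n=stats.scale("dist", e.dist),
                blen_n=stats.scale("blen", e.blen),
            ),
        )
    return out


# -- serialization ------------------------------------------------------------


def write_graph(g: AttributedGraph, path: str | Path | None = None) -> dict:
    """Serialize a graph to a JSON-compatible dict (and optionally a file)."""
    doc = {
        "provenance": g.provenance,
        "nodes": [
            {
                "id": nid,
                "label": n.label,
                "area": n.area,
                "perimeter": n.perimeter,
                "row": n.centroid[0],
                "col": n.centroid[1],
                "area_n": n.area_n,
                "perimeter_n": n.perimeter_n,
            }
            for nid, n in sorted(g.nodes.items())
        ],
        "edges": [
            {
                "u": u,
                "v": v,
                "dist": e.dist,
                "blen": e.blen,
                "dist_n": e.dist_n,
                "blen_n": e.blen_n,
            }
            for (u, v), e in sorted(g.edges.items())
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc


def read_graph(doc: dict | str | Path) -> AttributedGraph:
    """Deserialize a graph written by :func:`write_graph`."""
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    g = AttributedGraph(provenance=doc.get("provenance", ""))
    try:
        for n in doc["nodes"]:
            g.add_node(
                int(n["id"]),
                NodeAttributes(
                    area=float(n["area"]),
                    perimeter=float(n["perimeter"]),
                    label=int(n["label"]),
                    centroid=(float(n["row"]), float(n["col"])),
                    area_n=n.get("area_n"),
                    perimeter_n=n.get("perimeter_n"),
                ),
            )
        for e in doc["edges"]:
            g.add_edge(
                int(e["u"]),
                int(e["v"]),
                EdgeAttributes(
                    dist=float(e["dist"]),
                    blen=float(e["blen"]),
                    dist_n=e.get("dist_n"),
                    blen_n=e.get("blen_n"),
                ),
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed graph document: {exc}") from exc
    return g


def to_networkx(g: AttributedGraph):
    """Export to a ``networkx.Graph`` (e.g. for GraphML interoperability)."""
    import networkx as nx

    G = nx.Graph(provenance=g.provenance)
    for nid, n in g.nodes.items():
        G.add_node(
            nid,
            label=n.label,
            area=n.area,
            perimeter=n.perimeter,
            row=n.centroid[0],
            col=n.centroid[1],
        )
    for (u, v), e in g.edges.items():
        G.add_edge(u, v, dist=e.dist, blen=e.blen)
    return G


def from_networkx(G) -> AttributedGraph:
    """Import from a ``networkx.Graph`` carrying the standard attributes."""
    g = AttributedGraph(provenance=G.graph.get("provenance", ""))
    for nid, d in G.nodes(data=True):
        g.add_node(
            int(nid),
            NodeAttributes(
                area=float(d["area"]),
                perimeter=float(d["perimeter"]),
                label=int(d["label"]),
                centroid=(float(d["row"]), float(d["col"])),
            ),
        )
    for u, v, d in G.edges(data=True):
        g.add_edge(
            int(u), int(v), EdgeAttributes(dist=float(d["dist"]), blen=float(d["blen"]))
        )
    return g
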