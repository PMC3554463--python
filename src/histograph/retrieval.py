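"""Database building and query answering for graph-based tissue retrieval.

Two query modes are supported, mirroring the two experimental configurations
of graph-based histological CBIR:

* **Inexact tile matching** — whole-slide masks are split into fixed-size
  tiles (optionally overlapping); a query tile's ARG is matched against the
  ARG of every candidate tile and tiles are ranked by matching cost.
* **Subgraph querying** — a rectangular selection on a whole-slide mask
  picks up every region it touches; the regions are extended to full extent,
  their ARG is matched into whole-image ARGs and the recovered mapping
  designates the matched subgraph.

A 4-bin tissue-proportion histogram signature with the same exponential
distance serves as the classical CBIR baseline.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graphrep import (
    AttributedGraph,
    NormalizationStats,
    build_rag,
    compute_norm_stats,
    normalize_graph,
    read_graph,
    write_graph,
)
from .imageprep import LabelMask, RegionMap, prepare_mask
from .matching import INF, MatchConfig, astar_match

__all__ = [
    "IndexConfig",
    "TileRecord",
    "RetrievalIndex",
    "RankedResult",
    "HistogramSignature",
    "tile_image",
    "build_database",
    "build_wsi_database",
    "query_inexact",
    "query_histogram",
    "extend_query_regions",
    "query_subgraph",
    "label_histogram",
    "histogram_distance",
]


@dataclass(frozen=True)
class IndexConfig:
    """Database construction parameters."""

    tile_size: int = 128
    overlap: float = 0.5
    n_labels: int = 4
    struct_radius: int = 2
    min_area: int = 50
    connectivity: int = 8
    node_cap: int = 25  # tiles above this get the expansion-budget guard


@dataclass(frozen=True)
class HistogramSignature:
    """Per-tissue-label pixel proportions over non-background pixels."""

    proportions: tuple[float, ...]
    empty: bool = False

    def __len__(self) -> int:
        return len(self.proportions)


@dataclass
class TileRecord:
    tile_id: int
    provenance: str
    offset: tuple[int, int]
    size: int
    graph: AttributedGraph  # normalized with the index's stats
    histogram: HistogramSignature
    meta: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.graph.n_nodes == 0


@dataclass
class RankedResult:
    """Retrieval ranking: (tile id, matching cost), costs non-decreasing."""

    hits: list[tuple[int, float]]
    mappings: dict[int, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hits)

    def tile_ids(self) -> list[int]:
        return [t for t, _ in self.hits]

    def costs(self) -> list[float]:
        return [c for _, c in self.hits]


@dataclass
class RetrievalIndex:
    """A queryable database of normalized tile graphs + histogram signatures."""

    records: list[TileRecord]
    stats: NormalizationStats
    config: IndexConfig
    whole_image: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": self.config.__dict__,
            "whole_image": self.whole_image,
            "stats": self.stats.to_dict(),
            "tiles": [
                {
                    "tile_id": r.tile_id,
                    "provenance": r.provenance,
                    "offset": list(r.offset),
                    "size": r.size,
                    "histogram": list(r.histogram.proportions),
                    "histogram_empty": r.histogram.empty,
                    "meta": r.meta,
                    "graph_file": f"tile_{r.tile_id:06d}.json",
                }
                for r in self.records
            ],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest))
        gdir = directory / "graphs"
        gdir.mkdir(exist_ok=True)
        for r in self.records:
            write_graph(r.graph, gdir / f"tile_{r.tile_id:06d}.json")

    @classmethod
    def load(cls, directory: str | Path) -> "RetrievalIndex":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = IndexConfig(**manifest["config"])
        stats = NormalizationStats.from_dict(manifest["stats"])
        records = []
        for t in manifest["tiles"]:
            records.append(
                TileRecord(
                    tile_id=t["tile_id"],
                    provenance=t["provenance"],
                    offset=tuple(t["offset"]),
                    size=t["size"],
                    graph=read_graph(directory / "graphs" / t["graph_file"]),
                    histogram=HistogramSignature(
                        tuple(t["histogram"]), t["histogram_empty"]
                    ),
                    meta=t["meta"],
                )
            )
        return cls(records, stats, config, manifest.get("whole_image", False))


def tile_image(
    mask: LabelMask, tile_size: int, overlap_fraction: float = 0.5
) -> list[tuple[LabelMask, tuple[int, int]]]:
    """Split a mask into square tiles on a regular (possibly overlapping) grid.

    The stride is ``round(tile_size * (1 - overlap_fraction))``; the mask is
    implicitly cropped so the grid fits exactly (offsets run while
    offset + tile_size <= dimension), trading border loss against overlap
    redundancy.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if tile_size > mask.height or tile_size > mask.width:
        raise ValueError("tile larger than image")
    stride = max(1, round(tile_size * (1.0 - overlap_fraction)))
    tiles = []
    for r in range(0, mask.height - tile_size + 1, stride):
        for c in range(0, mask.width - tile_size + 1, stride):
            sub = mask.pixels[r : r + tile_size, c : c + tile_size].copy()
            tiles.append(
                (
                    LabelMask(sub, n_labels=mask.n_labels, pixel_size=mask.pixel_size),
                    (r, c),
                )
            )
    return tiles


def label_histogram(tile: LabelMask) -> HistogramSignature:
    """Tissue-proportion signature: one bin per label, normalized over
    non-background pixels; all-background tiles yield a flagged zero vector."""
    counts = np.bincount(tile.pixels.ravel(), minlength=tile.n_labels + 1)[1:]
    total = counts.sum()
    if total == 0:
        return HistogramSignature((0.0,) * tile.n_labels, empty=True)
    return HistogramSignature(tuple((counts / total).tolist()))


def histogram_distance(h1: HistogramSignature, h2: HistogramSignature) -> float:
    """Exponential distance between signatures: sum_b e^{|h1_b - h2_b|} - B."""
    if len(h1) != len(h2):
        raise ValueError("signatures differ in length")
    return sum(
        math.exp(abs(x - y)) - 1.0 for x, y in zip(h1.proportions, h2.proportions)
    )


def _tile_graph(mask: LabelMask, config: IndexConfig, provenance: str) -> AttributedGraph:
    rm = prepare_mask(
        mask,
        struct_radius=config.struct_radius,
        min_area=config.min_area,
        connectivity=config.connectivity,
    )
    g = build_rag(rm)
    g.provenance = provenance
    return g


def build_database(
    masks: list[LabelMask],
    config: IndexConfig | None = None,
    provenances: list[str] | None = None,
    metas: list[dict] | None = None,
) -> RetrievalIndex:
    """Off-line database construction for the tile-matching approach.

    Tiles every mask, builds each tile's ARG and histogram signature,
    computes global normalization statistics over all tile graphs and stores
    everything normalized.  Tiles whose graph is empty are kept (never
    matchable) so offsets stay consistent with the tiling grid.
    """
    config = config or IndexConfig()
    if not masks:
        raise ValueError("empty database input")
    provenances = provenances or [f"mask{i}" for i in range(len(masks))]
    metas = metas or [{} for _ in masks]

    raw: list[TileRecord] = []
    tid = 0
    for mask, prov, meta in zip(masks, provenances, metas):
        for tile, offset in tile_image(mask, config.tile_size, config.overlap):
            g = _tile_graph(tile, config, f"{prov}@{offset[0]},{offset[1]}")
            raw.append(
                TileRecord(
                    tile_id=tid,
                    provenance=prov,
                    offset=offset,
                    size=config.tile_size,
                    graph=g,
                    histogram=label_histogram(tile),
                    meta=dict(meta),
                )
            )
            tid += 1
    nonempty = [r.graph for r in raw if r.graph.n_nodes > 0]
    if not nonempty:
        raise ValueError("no tile produced a non-empty graph")
    stats = compute_norm_stats(nonempty)
    for r in raw:
        r.graph = normalize_graph(r.graph, stats)
    return RetrievalIndex(raw, stats, config)


def build_wsi_database(
    masks: list[LabelMask],
    config: IndexConfig | None = None,
    provenances: list[str] | None = None,
) -> RetrievalIndex:
    """Whole-image index for the subgraph-query approach: one full-extent
    graph per mask, no tiling."""
    config = config or IndexConfig()
    if not masks:
        raise ValueError("empty database input")
    provenances = provenances or [f"wsi{i}" for i in range(len(masks))]
    raw = []
    for tid, (mask, prov) in enumerate(zip(masks, provenances)):
        g = _tile_graph(mask, config, prov)
        raw.append(
            TileRecord(
                tile_id=tid,
                provenance=prov,
                offset=(0, 0),
                size=max(mask.shape),
                graph=g,
                histogram=label_histogram(mask),
            )
        )
    stats = compute_norm_stats([r.graph for r in raw if r.graph.n_nodes > 0])
    for r in raw:
        r.graph = normalize_graph(r.graph, stats)
    return RetrievalIndex(raw, stats, config, whole_image=True)


def _label_count_feasible(query: AttributedGraph, model: AttributedGraph) -> bool:
    """Necessary condition for a label-consistent injection: the model must
    offer at least as many nodes of every label as the query demands."""
    mc = model.label_counts()
    return all(mc.get(lbl, 0) >= n for lbl, n in query.label_counts().items())


def _rank_graphs(
    index: RetrievalIndex,
    query_graph: AttributedGraph,
    top_k: int,
    match_config: MatchConfig,
    keep_mappings: bool = False,
) -> RankedResult:
    costs: list[tuple[float, int]] = []
    mappings: dict[int, dict] = {}
    for r in index.records:
        if r.empty or not _label_count_feasible(query_graph, r.graph):
            continue
        res = astar_match(query_graph, r.graph, match_config)
        if res.cost < INF:
            costs.append((res.cost, r.tile_id))
            if keep_mappings:
                mappings[r.tile_id] = res.mapping
    costs.sort()  # (cost, tile id): deterministic total order
    hits = [(tid, cost) for cost, tid in costs[:top_k]]
    if not hits:
        warnings.warn("query matched no database tile with finite cost")
    return RankedResult(hits, {t: mappings[t] for t, _ in hits if t in mappings})


def query_inexact(
    index: RetrievalIndex,
    query_mask: LabelMask,
    top_k: int = 10,
    match_config: MatchConfig | None = None,
) -> RankedResult:
    """Rank database tiles by A* matching cost against a same-size query tile.

    The query graph is built with the index's preparation settings and
    normalized against the index statistics (clipped to [0, 1]); tiles that
    cannot host a label-consistent injection are skipped (infinite cost).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if query_mask.height != index.config.tile_size or (
        query_mask.width != index.config.tile_size
    ):
        raise ValueError("query size must equal the index tile size")
    match_config = match_config or MatchConfig()
    qg = _tile_graph(query_mask, index.config, "query")
    if qg.n_nodes == 0:
        raise ValueError("unmatchable query: no regions survive preparation")
    qg = normalize_graph(qg, index.stats)
    return _rank_graphs(index, qg, top_k, match_config)


def query_histogram(
    index: RetrievalIndex, query_mask: LabelMask, top_k: int = 10
) -> RankedResult:
    """Baseline ranking by exponential distance between 4-bin histograms."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    qh = label_histogram(query_mask)
    costs = sorted(
        (histogram_distance(qh, r.histogram), r.tile_id)
        for r in index.records
        if not r.histogram.empty
    )
    return RankedResult([(tid, cost) for cost, tid in costs[:top_k]])


def extend_query_regions(
    rm: RegionMap, rect: tuple[int, int, int, int]
) -> RegionMap:
    """Select every region touching a rectangle and restore its full extent.

    ``rect`` is (row, col, height, width) on the whole-slide mask.  A region
    overlapping the rectangle by even a single pixel is included whole —
    retrieved structures therefore follow region extent, not query extent.
    """
    r0, c0, h, w = rect
    H, W = rm.shape
    if h < 1 or w < 1 or r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise ValueError("rect out of mask bounds")
    sub = rm.assignment[r0 : r0 + h, c0 : c0 + w]
    ids = set(int(i) for i in np.unique(sub) if i > 0)
    regions = [r for r in rm.regions if r.id in ids]
    assignment = np.where(np.isin(rm.assignment, list(ids)), rm.assignment, 0)
    return RegionMap(regions, assignment, n_labels=rm.n_labels)


def query_subgraph(
    index: RetrievalIndex,
    wsi_regions: RegionMap,
    rect: tuple[int, int, int, int],
    top_k: int = 10,
    match_config: MatchConfig | None = None,
) -> RankedResult:
    """Subgraph-style query: match the extended-region ARG of a rectangular
    selection into every whole-image graph of the index.

    The model graphs are the large whole-image ARGs; the recovered node
    mapping designates the matched subgraph in each.  Querying the source
    image itself recovers the query regions at the cost floor.
    """
    if not index.whole_image:
        raise ValueError("query_subgraph needs a whole-image index")
    match_config = match_config or MatchConfig()
    qrm = extend_query_regions(wsi_regions, rect)
    if len(qrm) == 0:
        raise ValueError("unmatchable query: rectangle touches no region")
    qg = build_rag(qrm)
    qg.provenance = "query"
    qg = normalize_graph(qg, index.stats)
    return _rank_graphs(index, qg, top_k, match_config, keep_mappings=True)
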