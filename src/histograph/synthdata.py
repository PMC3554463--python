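"""Synthetic labeled tissue masks with known ground truth.

Real segmented breast-biopsy whole-slide images are not redistributable, so
this module generates label masks that emulate their salient geometry: ducts
(a lumen wrapped in an epithelial ring against connective background),
lobule clusters, layered stripes and Voronoi mosaics, using the four-class
label convention

    1 = lobules, 2 = fibrous connective tissue,
    3 = epithelial lining, 4 = lumen-&-fat.

Every tile carries generator metadata (motif family, layout variant, size
tier, dominant tissue) that downstream evaluation uses as objective ground
truth in place of human relevance judgments.  Generation is fully
deterministic per (spec, seed).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imageprep import LabelMask, write_mask

__all__ = [
    "MotifSpec",
    "generate_tile",
    "generate_dataset",
    "make_wedge_pair",
    "random_attributed_graph",
    "standard_tile_mixture",
    "wedge_experiment_tiles",
    "SIZE_TIERS",
    "MOTIFS",
]

SIZE_TIERS = {64: 0, 128: 1, 256: 2, 512: 3}
MOTIFS = ("duct", "lobule_cluster", "stripes", "random_voronoi")

LOBULE, CONNECTIVE, EPITHELIUM, LUMEN_FAT = 1, 2, 3, 4


@dataclass(frozen=True)
class MotifSpec:
    """Recipe for one synthetic tile.

    ``variant`` distinguishes layouts within a motif family (e.g. different
    stripe label orders); ``params`` holds motif-specific geometry knobs.
    """

    motif: str
    seed: int
    variant: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}")


def _polar_radius(rng, n_angles: int, base: float, jitter: float) -> np.ndarray:
    """Smooth angle-dependent radius: base * (1 + jitter * low-freq noise).

    The perturbation is a sum of a few random-phase harmonics, which keeps
    the contour simply connected (a star-shaped region)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    noise = np.zeros(n_angles)
    for k in range(2, 5):
        noise += rng.normal(0, 1) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    noise /= 3.0
    return base * (1.0 + jitter * noise)


def _blob(size: int, center, base_radius: float, rng, jitter: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    dr, dc = rr - center[0], cc - center[1]
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    n_ang = 720
    radii = _polar_radius(rng, n_ang, base_radius, jitter)
    idx = ((theta + np.pi) / (2 * np.pi) * n_ang).astype(int) % n_ang
    return dist <= radii[idx]


def _duct(size: int, rng, params: dict) -> np.ndarray:
    lumen_r = params.get("lumen_radius", size * 0.12)
    ring_w = params.get("ring_width", size * 0.08)
    jitter = params.get("jitter", 0.08)
    n_lobules = params.get("n_lobules", 2)
    if lumen_r + ring_w > size / 2:
        raise ValueError("ring radius exceeds half the tile size")
    px = np.full((size, size), CONNECTIVE, dtype=np.int32)
    center = (
        size / 2 + rng.uniform(-size * 0.05, size * 0.05),
        size / 2 + rng.uniform(-size * 0.05, size * 0.05),
    )
    ring = _blob(size, center, lumen_r + ring_w, rng, jitter)
    lumen = _blob(size, center, lumen_r, rng, jitter)
    px[ring] = EPITHELIUM
    px[ring & lumen] = LUMEN_FAT
    blob_r = params.get("lobule_radius", size * 0.07)
    for _ in range(n_lobules):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(lumen_r + ring_w + blob_r * 1.6, size * 0.48)
        bc = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
        if not (blob_r < bc[0] < size - blob_r and blob_r < bc[1] < size - blob_r):
            continue
        blob = _blob(size, bc, blob_r, rng, jitter)
        px[blob & (px == CONNECTIVE)] = LOBULE
    return px


def _lobule_cluster(size: int, rng, params: dict) -> np.ndarray:
    n_blobs = params.get("n_blobs", 3)
    blob_r = params.get("blob_radius", size * 0.10)
    jitter = params.get("jitter", 0.08)
    px = np.full((size, size), CONNECTIVE, dtype=np.int32)
    for i in range(n_blobs):
        bc = (
            rng.uniform(blob_r * 1.2, size - blob_r * 1.2),
            rng.uniform(blob_r * 1.2, size - blob_r * 1.2),
        )
        label = LUMEN_FAT if (i == n_blobs - 1 and params.get("with_fat", True)) else LOBULE
        blob = _blob(size, bc, blob_r, rng, jitter)
        px[blob & (px == CONNECTIVE)] = label
    return px


def _stripes(size: int, rng, params: dict) -> np.ndarray:
    order = params.get("order", [CONNECTIVE, EPITHELIUM, LUMEN_FAT])
    widths = params.get("widths")
    width_jitter = params.get("width_jitter", 0.0)
    n = len(order)
    if widths is None:
        w = np.full(n, size / n)
        if width_jitter > 0:
            w = w * (1.0 + rng.uniform(-width_jitter, width_jitter, size=n))
            w = w / w.sum() * size
        bounds = np.round(np.cumsum(w)).astype(int)
    else:
        bounds = np.round(np.cumsum(widths)).astype(int)
    bounds[-1] = size
    px = np.zeros((size, size), dtype=np.int32)
    start = 0
    for label, stop in zip(order, bounds):
        px[:, start:stop] = label
        start = stop
    return px


def _random_voronoi(size: int, rng, params: dict) -> np.ndarray:
    n_seeds = params.get("n_seeds", 6)
    labels = params.get("labels", [LOBULE, CONNECTIVE, EPITHELIUM, LUMEN_FAT])
    pts = rng.uniform(0, size, size=(n_seeds, 2))
    seed_labels = rng.choice(labels, size=n_seeds)
    rr, cc = np.mgrid[0:size, 0:size]
    d2 = (rr[..., None] - pts[:, 0]) ** 2 + (cc[..., None] - pts[:, 1]) ** 2
    return seed_labels[np.argmin(d2, axis=-1)].astype(np.int32)


_BUILDERS = {
    "duct": _duct,
    "lobule_cluster": _lobule_cluster,
    "stripes": _stripes,
    "random_voronoi": _random_voronoi,
}


def generate_tile(spec: MotifSpec, size: int) -> tuple[LabelMask, dict]:
    """Render one tile and its ground-truth metadata.

    Deterministic for identical (spec, size): the spec seed fully drives the
    random geometry.
    """
    if size not in SIZE_TIERS:
        raise ValueError(f"size must be one of {sorted(SIZE_TIERS)}")
    rng = np.random.default_rng(spec.seed)
    px = _BUILDERS[spec.motif](size, rng, spec.params)
    mask = LabelMask(px, n_labels=4)
    counts = np.bincount(px.ravel(), minlength=5)[1:]
    meta = {
        "motif": spec.motif,
        "variant": spec.variant,
        "size_tier": SIZE_TIERS[size],
        "dominant_label": int(np.argmax(counts)) + 1,
        "seed": spec.seed,
    }
    return mask, meta


def make_wedge_pair(seed: int, size: int = 64) -> tuple[
    tuple[LabelMask, dict], tuple[LabelMask, dict]
]:
    """A pair of stripe tiles with identical label histograms but different
    region adjacency.

    Both tiles use the same four equal-width stripes; only the label order is
    permuted ([1,2,3,4] vs [2,1,4,3]), so tissue proportions match exactly
    while the edge sets of their RAGs differ — the configuration where
    histogram signatures are blind and graph structure is not.
    """
    a = MotifSpec("stripes", seed=seed, variant=0, params={"order": [1, 2, 3, 4]})
    b = MotifSpec("stripes", seed=seed, variant=1, params={"order": [2, 1, 4, 3]})
    return generate_tile(a, size), generate_tile(b, size)


def generate_dataset(
    config: dict,
    n_tiles: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[tuple[LabelMask, dict]]:
    """Draw tiles from a configured motif mixture.

    ``config`` keys: ``size`` (tile side), ``mixture`` — list of
    ``{"motif":..., "weight":..., "variant":..., "params": {...}}`` entries.
    When ``out_dir`` is given, masks are written as PNGs plus a CSV manifest
    mapping tile id to ground truth.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    size = config.get("size", 128)
    mixture = config.get(
        "mixture",
        [
            {"motif": "duct", "weight": 1.0, "params": {"n_lobules": 1}},
            {"motif": "lobule_cluster", "weight": 1.0},
            {
                "motif": "stripes",
                "weight": 1.0,
                "params": {"order": [2, 3, 4], "width_jitter": 0.2},
            },
            {"motif": "random_voronoi", "weight": 1.0, "params": {"n_seeds": 6}},
        ],
    )
    weights = np.array([m.get("weight", 1.0) for m in mixture], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    tiles = []
    for i in range(n_tiles):
        entry = mixture[int(rng.choice(len(mixture), p=weights))]
        spec = MotifSpec(
            motif=entry["motif"],
            seed=int(rng.integers(0, 2**31 - 1)),
            variant=entry.get("variant", 0),
            params=dict(entry.get("params", {})),
        )
        mask, meta = generate_tile(spec, size)
        meta["tile_id"] = i
        tiles.append((mask, meta))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for mask, meta in tiles:
            fname = f"tile_{meta['tile_id']:05d}.png"
            write_mask(mask, out_dir / fname)
            rows.append({**meta, "file": fname})
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
        (out_dir / "manifest.json").write_text(json.dumps(rows))
    return tiles


def standard_tile_mixture(size: int = 64) -> dict:
    """Default mixed-motif dataset configuration.

    Uses the continuous-geometry motifs (duct, lobule cluster, Voronoi
    mosaic) whose random centers and contour jitter make every drawn tile
    almost surely unique, as tiles cut from real tissue would be.
    """
    return {
        "size": size,
        "mixture": [
            {"motif": "duct", "weight": 1.0, "params": {"n_lobules": 1}},
            {"motif": "lobule_cluster", "weight": 1.0},
            {"motif": "random_voronoi", "weight": 1.0, "params": {"n_seeds": 5}},
        ],
    }


def wedge_experiment_tiles(
    seed: int, n_per_class: int = 50, size: int = 64
) -> list[tuple[LabelMask, dict]]:
    """Two-class dataset where composition is uninformative but structure is.

    Both classes are four-stripe layouts over the same labels with jittered
    widths; they differ only in stripe order ([1,2,3,4] vs [2,1,4,3]), so
    tissue-proportion histograms overlap almost completely across classes
    while region adjacency cleanly separates them.
    """
    rng = np.random.default_rng(seed)
    tiles = []
    for variant, order in ((0, [1, 2, 3, 4]), (1, [2, 1, 4, 3])):
        for _ in range(n_per_class):
            spec = MotifSpec(
                "stripes",
                seed=int(rng.integers(0, 2**31 - 1)),
                variant=variant,
                params={"order": order, "width_jitter": 0.25},
            )
            tiles.append(generate_tile(spec, size))
    return tiles


def random_attributed_graph(
    rng: np.random.Generator,
    n_nodes: int,
    n_labels: int = 4,
    edge_prob: float = 0.5,
):
    """A random ARG with attributes already in [0, 1] — used for matcher
    stress tests where graphs need not come from an image."""
    from .graphrep import AttributedGraph, EdgeAttributes, NodeAttributes

    g = AttributedGraph(provenance="random")
    for nid in range(1, n_nodes + 1):
        g.add_node(
            nid,
            NodeAttributes(
                area=float(rng.uniform(0, 1)),
                perimeter=float(rng.uniform(0, 1)),
                label=int(rng.integers(1, n_labels + 1)),
                centroid=(float(rng.uniform(0, 100)), float(rng.uniform(0, 100))),
            ),
        )
    for u in range(1, n_nodes + 1):
        for v in range(u + 1, n_nodes + 1):
            if rng.uniform() < edge_prob:
                g.add_edge(
                    u,
                    v,
                    EdgeAttributes(
                        dist=float(rng.uniform(0, 1)), blen=float(rng.uniform(0, 1))
                    ),
                )
    return g
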