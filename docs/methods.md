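# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `histograph`, in the order the pipeline runs.

## Image preparation

Input is a multilabel segmentation mask: a 2-D integer grid with 0 for
background and 1..L (L = 4) for tissue classes — lobules (1), fibrous
connective tissue (2), epithelial lining (3), lumen-&-fat (4). The pixel
size is treated as metadata only; all geometry is measured in pixels.

The mask is decomposed into one binary image per label; each is cleaned by
morphological **closing twice then opening twice** with a disk structuring
element. The default radius is 2 px, sized for roughly 1 µm/px imagery
where segmentation specks and gaps are a few pixels across; it is
configurable because the right size scales with magnification. Per-label
morphology can leave a pixel claimed by several labels or by none, so the
cleaned images are reconciled deterministically: unique claim → that label;
multiple claims → lowest label index; no claim → the pixel's original
label. The rule is order-independent and keeps the output a valid
partition.

Connected components use **8-connectivity** (diagonal tissue runs stay
whole); region adjacency below uses 4-connectivity. Regions smaller than
`min_area` (default 50 px, configurable; synthetic 64-px tiles use 8) are
dropped before graph construction — tiny fragments are more often
segmentation artifacts than anatomy. Region ids follow raster-scan order of
each region's first pixel, making the whole pipeline deterministic.

Per-region measurements:

* **area** — pixel count;
* **perimeter** — length of the closed outer boundary contour obtained by
  Moore boundary tracing over border pixel centers, summing unit steps for
  4-neighbour moves and √2 for diagonal moves. Thin structures are walked
  down and back (a 1×W bar has perimeter 2(W−1)); single-pixel regions get
  the floor value 1.0 so perimeter is always positive. Interior holes are
  not traced — the attribute describes outer shape;
* **centroid** — real-valued mean (row, col) of the region's pixels.

## Graph representation

One node per region carries (area, perimeter, label, centroid); one
undirected edge per pair of regions with a positive **common boundary
length** — the count of 4-adjacent pixel pairs straddling the two regions —
carries (centroid Euclidean distance, boundary length). Area, perimeter,
centroid distance and boundary length are globally normalized to [0, 1]
using per-feature min/max over every node and edge of the database; labels
are categorical and never normalized. Two numerical conventions matter:

* **degenerate feature** (min = max, e.g. an edge-free database): all
  values map to 0.0, avoiding division by zero and keeping the heuristic a
  lower bound;
* **query-time clipping**: a query is normalized with the *database* stats
  and clipped to [0, 1], so out-of-range query attributes cannot break the
  [0, 1] contract that the admissibility argument relies on.

Raw values are stored alongside normalized ones so graphs can be
re-normalized against another database. Graphs serialize losslessly to a
JSON dialect; GraphML export/import is provided for interoperability.

## Matching cost and A* search

Matching is directional: the test graph (N nodes) is mapped into the model
graph (N′ ≥ N). The per-pair distance is

    δ = λ δ1 + (1 − λ) δ2,    d = γ δ,

with δ1 the weighted exponential node distance and δ2 the **mean**
per-edge exponential distance over the test node's edges into the
already-mapped prefix (0 if there are none). The mean — rather than the
sum — keeps δ2 on the same scale as δ1 regardless of degree, which is what
makes λ = 0.5 ("equal relevance") meaningful; only edges into the prefix
can be scored if the accumulated cost is to be well-defined incrementally.
Node-attribute weights default to area:perimeter = 2:1, realized as
multiplicative weights u scaled to sum to K = 2 (u = (4/3, 2/3)) so unit
weights recover the plain Σ e^{|·|} − K form. Area dominates because large
regions are reliably anatomy while small ones may be noise; the same
reasoning puts w = max of the two areas in the accumulated cost
g = Σ w(d+1) + n·c — mismatching big regions costs more.

Parameters `c` (default 0.1) and `γ` (default 1.0) rescale the structural
+1 term and the attribute distance respectively. Optimality does not
depend on their values (any positive choice keeps h admissible, since
w ≥ a(1) and d ≥ 0 give a(1) + c ≤ w(d+1) + c per step), so they are
exposed in `MatchConfig` and the test suite exercises a grid of them; the
defaults simply keep the three cost terms on comparable scales.

The search maintains an Open List (priority queue on f = g + h, FIFO
tie-breaking by insertion counter) of partial mappings; test nodes enter
in fixed descending-area order (ties by id). Children of a state pair the
next test node with every unused, label-compatible model node whose edges
into the prefix all exist in the model (strict monomorphism; a missing
counterpart prunes the pair). The first complete mapping popped is optimal
and h = 0 there, so the reported cost equals g. Degenerate outcomes are
explicit statuses: `no_solution` (no label/edge-consistent injection
exists, cost ∞) and `budget_exceeded` (expansion cap, default 200 000,
hit first). An optional partial mode prices skipping a test node at
(a(1) + 1) + c — mirroring the heuristic's accounting — for callers that
need a finite ranking cost when strict matching fails; it is off by
default and unused in retrieval.

`brute_force_match` enumerates all label-consistent injections (guarded at
10⁶ combinations), filters edge-preserving ones and scores them with the
same arithmetic in the same node order, giving exact float agreement with
the search; it is the correctness oracle in the tests, never the
production path.

## Retrieval

Whole-slide masks are split into square tiles with stride
round(size·(1−overlap)); the grid is implicitly cropped to fit. The
default overlap 0.5 trades border truncation against result redundancy.
Database construction builds each tile's graph and 4-bin histogram,
computes normalization stats over *all* tile graphs, and stores
everything normalized; empty tiles are kept but never matched.

A query tile is prepared with the index's own settings, normalized with
clipping, and matched against every candidate tile. Two pre-filters keep
this tractable: a tile must offer, per label, at least as many nodes as
the query demands (necessary for any label-consistent injection — this is
where the label constraint collapses the search space), and tiles above a
node cap (default 25) are matched only under the expansion budget.
Results are ordered by (cost, tile id) — a deterministic total order.

The subgraph-style query selects every region touching a rectangle on a
whole-slide mask, restores each to full extent, and matches that graph
into whole-image graphs; the returned mapping designates the matched
subgraph. Its known limitation is inherited from the region extension:
result size follows region extent, not query extent.

The histogram baseline uses the same exponential distance over 4-bin
tissue proportions (computed over non-background pixels). It is invariant
to any spatial rearrangement of the same composition — the precise
blindness the graph method is designed to overcome.

## Evaluation

P_s = ⌊(Σᵢ₌₁..ₛ scoreᵢ / s)·100⌋ over the first s results, scores in
{0, 0.25, 0.5, 0.75, 1}. If fewer than s results exist the mean is taken
over what is available, with a warning — padding zeros would bias the
precision downward for sparse-but-correct result lists. Method comparison
averages P_s per scope across queries and reports the relative improvement
round((P_graph − P_hist)/P_hist · 100), undefined (NaN, not ∞) when the
baseline is 0.

With synthetic tiles, relevance comes from a deterministic rubric over
generator ground truth, replacing subjective human scoring: same motif
family and layout variant → 1.0 at the same size tier, 0.75 one tier away;
same family, different variant → 0.5; only the dominant tissue class in
common → 0.25; otherwise 0. A "motif class" is the (family, variant) pair:
two stripe layouts with permuted label order are *different* classes that
share a family. The rubric is a module-level function so stricter (e.g.
binary) relevance can be swapped in.

## Synthetic data

The generator emulates the geometry that matters downstream — region
shapes, sizes, adjacency and class labels — not stain texture. Motifs:
**duct** (connective background, epithelial ring, central lumen, optional
lobule blobs), **lobule_cluster**, **stripes**, **random_voronoi**.
Contour jitter is applied in polar space (a few random-phase harmonics),
which keeps regions star-shaped and simply connected so the RAG stays
clean. Tile sizes are restricted to {64, 128, 256, 512} and map to size
tiers 0–3 in the metadata.

Two preset experiment datasets define the study conditions used by the
test suite and the acceptance script:

* `standard_tile_mixture` — equal thirds duct / lobule cluster / Voronoi
  at 64 px. These motifs have continuous random geometry, so drawn tiles
  are almost surely pairwise distinct, as tiles cut from real tissue would
  be. (Stripe tiles are excluded here on purpose: integer-rounded stripe
  widths form a small discrete space in which independent draws can
  collide into byte-identical tiles, creating exact cost ties that say
  nothing about the matcher.) Preparation for these tiles uses
  struct_radius 1 and min_area 8 — the masks are speck-free by
  construction and their regions are tens to hundreds of pixels.
* `wedge_experiment_tiles` — two 50-tile classes of four-stripe layouts
  over the same labels with jittered widths, differing only in stripe
  order ([1,2,3,4] vs [2,1,4,3]). Across classes the composition
  distributions coincide while the adjacency structure differs, isolating
  exactly the signal histograms cannot see. `make_wedge_pair` produces the
  exact-width version of the same construction, where the two histograms
  are *identical* while the RAG label-edge sets differ.

What passing tests on this data do **not** show: robustness to real
segmentation noise (ragged boundaries, fragmented regions, mislabeled
pixels), to regions with holes or non-star shapes, and to the much larger
graphs of dense tissue. The matcher's optimality guarantee is
data-independent, but its runtime is not — it is exponential in the worst
case and practical only because tissue labels and the per-label count
filter prune the search.

## Problem sizes

Defaults throughout were chosen so a complete run of the test suite and
the acceptance script finishes in a few minutes on one CPU: 200 random
graph pairs (test 2–5 nodes, model 4–8) × 9 (c, γ) combinations for the
optimality/admissibility checks, 100 indexed 64-px tiles for
self-retrieval, 20 wedge pairs, 100 tiles / 10 queries for the two-class
experiment, 50 random masks for conservation. All sizes are arguments and
scale up directly.

## Known limitations

* Perimeter traces the outer contour only; regions with holes are
  under-described (Euler number and friends were deliberately left out of
  the attribute set).
* Normalization statistics are fixed per database; adding tiles requires
  re-normalization (raw values are retained to make that cheap).
* When several tile-size databases coexist, centroid distances are
  normalized within each tile-size database independently; costs are not
  comparable across tile sizes.
* The matcher requires N ≤ N′ and strict edge preservation by default; a
  query whose structure genuinely does not embed anywhere returns an empty
  result rather than a graceful nearest-miss (partial mode exists but is
  not wired into retrieval).
* Exact cost ties between distinct tiles are resolved by tile id — stable,
  but arbitrary.
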