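"""Optimal inexact attributed-graph matching by A* tree search.

The matcher seeks a graph monomorphism from a test ARG G (N nodes) into a
model ARG G' (N' >= N nodes): an injective map F with alpha(v) = alpha'(F(v))
for every node (tissue labels must agree) under which every test edge has a
model counterpart.  Among all such maps it returns the one minimizing an
attribute-dissimilarity cost

    g(n) = sum_i w_i (d_i + 1) + n c,     w_i = max(a_p(1), a_q'(1)),
    d_i  = gamma * (lambda * delta1_i + (1 - lambda) * delta2_i),

where delta1 is an exponential distance between normalized node-attribute
vectors (area weighted twice perimeter by default) and delta2 the mean
exponential distance between corresponding edge-attribute vectors into the
already-mapped prefix.  The heuristic

    h(n) = sum_{unmapped} a_i(1) + (N - n) c

is admissible: per node it adds a(1) + c, never more than the realized
w (d + 1) + c since w >= a(1) and d >= 0, so the first goal popped from the
priority queue is optimal.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

from .graphrep import AttributedGraph

__all__ = [
    "MatchConfig",
    "MatchResult",
    "Impermissible",
    "node_distance",
    "edge_distance",
    "pair_distance",
    "pair_weight",
    "g_increment",
    "h_cost",
    "astar_match",
    "brute_force_match",
    "self_match_floor",
]

INF = math.inf


class Impermissible(Exception):
    """A candidate node pair violates the monomorphism constraints."""


@dataclass(frozen=True)
class MatchConfig:
    """Tunable constants of the matching cost.

    c
        Per-node constant offset; keeps the heuristic strictly informative
        and prices every mapped node.  Any positive value preserves
        optimality; default 0.1.
    gamma
        Rescale of the attribute distance delta so the structural +1 term
        does not mask it.  Any positive value preserves optimality.
    lambda_
        Balance between node-attribute and edge-attribute distances; 0.5
        gives them equal relevance.
    attr_weights
        Relative per-node-attribute weights (area, perimeter); internally
        rescaled to sum to K so unit weights reproduce the plain exponential
        distance.  Default 2:1 — area matters more than shape.
    allow_partial
        Permit skipping a test node at cost (a(1) + 1) + c instead of
        failing; off by default (strict monomorphism).
    max_expansions
        Search budget (priority-queue pops) before giving up.
    """

    c: float = 0.1
    gamma: float = 1.0
    lambda_: float = 0.5
    attr_weights: tuple[float, ...] = (2.0, 1.0)
    allow_partial: bool = False
    max_expansions: int = 200_000

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda_ must be in [0, 1]")
        if any(w <= 0 for w in self.attr_weights):
            raise ValueError("attr_weights must be strictly positive")


@dataclass
class MatchResult:
    """Outcome of a matching run.

    ``mapping`` maps test node ids to model node ids (a skipped test node,
    in partial mode, maps to None).  ``cost`` is the final f = g value at the
    goal (h = 0 there); infinite when no permissible mapping exists or the
    budget ran out.
    """

    mapping: dict[int, int | None]
    cost: float
    expansions: int
    status: str  # matched | no_solution | budget_exceeded
    trace: dict | None = None


def node_distance(
    a_p: tuple[float, ...],
    a_q: tuple[float, ...],
    weights: tuple[float, ...] | None = None,
) -> float:
    """Weighted exponential distance delta1 between node attribute vectors.

    delta1 = sum_k u_k (e^{|a_p(k) - a_q(k)|} - 1) with u rescaled to sum to
    K; unit weights give the plain sum e^{|.|} - K form.
    """
    if len(a_p) != len(a_q):
        raise ValueError("attribute vectors differ in length")
    k = len(a_p)
    if weights is None:
        u = (1.0,) * k
    else:
        if len(weights) != k:
            raise ValueError("weights length must match attribute vectors")
        s = sum(weights)
        u = tuple(k * w / s for w in weights)
    return sum(ui * (math.exp(abs(x - y)) - 1.0) for ui, x, y in zip(u, a_p, a_q))


def edge_distance(b_p: tuple[float, ...], b_q: tuple[float, ...]) -> float:
    """Exponential distance between edge attribute vectors:
    sum_m e^{|b_p(m) - b_q(m)|} - M."""
    if len(b_p) != len(b_q):
        raise ValueError("attribute vectors differ in length")
    return sum(math.exp(abs(x - y)) - 1.0 for x, y in zip(b_p, b_q))


def pair_weight(area_p: float, area_q: float) -> float:
    """w_i = max of the two (normalized) areas — mismatches between large
    regions are penalized more than between small ones."""
    return max(area_p, area_q)


def g_increment(w: float, d: float, c: float) -> float:
    """Per-step accumulated-cost contribution w (d + 1) + c."""
    return w * (d + 1.0) + c


def h_cost(unmapped_areas, c: float) -> float:
    """Admissible remaining-cost estimate: sum of unmapped (normalized)
    areas plus c per unmapped node; 0 at the goal."""
    unmapped_areas = list(unmapped_areas)
    return sum(unmapped_areas) + len(unmapped_areas) * c


def pair_distance(
    test: AttributedGraph,
    model: AttributedGraph,
    p: int,
    q: int,
    mapping: dict[int, int],
    config: MatchConfig,
) -> float:
    """Distance d = gamma * (lambda delta1 + (1-lambda) delta2) for mapping
    test node p onto model node q given the already-mapped prefix.

    delta2 averages the edge distance over every test edge from p into the
    prefix; each such edge must have a model counterpart, otherwise the pair
    is :class:`Impermissible` (monomorphism edge preservation).
    """
    ap = test.nodes[p]
    aq = model.nodes[q]
    if ap.label != aq.label:
        raise Impermissible(f"label mismatch {ap.label} != {aq.label}")
    delta1 = node_distance(ap.a, aq.a, config.attr_weights)
    edge_dists = []
    for u, qu in mapping.items():
        e_t = test.edge(p, u)
        if e_t is None:
            continue
        if qu is None:  # skipped node in partial mode: edge cannot be checked
            continue
        e_m = model.edge(q, qu)
        if e_m is None:
            raise Impermissible(f"test edge ({p},{u}) has no model counterpart")
        edge_dists.append(edge_distance(e_t.b, e_m.b))
    delta2 = sum(edge_dists) / len(edge_dists) if edge_dists else 0.0
    delta = config.lambda_ * delta1 + (1.0 - config.lambda_) * delta2
    return config.gamma * delta


def _test_order(g: AttributedGraph) -> list[int]:
    """Order test nodes by descending raw area (ties by id): the largest,
    most informative regions enter the search first."""
    return sorted(g.nodes, key=lambda n: (-g.nodes[n].area, n))


def self_match_floor(g: AttributedGraph, c: float) -> float:
    """Cost of matching a graph onto itself (identity map): the attainable
    lower bound sum_i a_i(1) + N c of any complete mapping."""
    return sum(g.nodes[n].a[0] for n in g.nodes) + g.n_nodes * c


def astar_match(
    test: AttributedGraph,
    model: AttributedGraph,
    config: MatchConfig | None = None,
    return_trace: bool = False,
) -> MatchResult:
    """Minimum-cost monomorphism of ``test`` into ``model`` via A*.

    The Open List is a priority queue on f = g + h with FIFO tie-breaking;
    states are partial injective mappings of the area-ordered test-node
    prefix.  The first complete mapping popped is optimal because h is
    admissible and consistent.  Requires N <= N'.
    """
    config = config or MatchConfig()
    n = test.n_nodes
    if n == 0:
        raise ValueError("test graph has no nodes")
    empty_trace = {"popped_f": [], "steps": []} if return_trace else None
    if n > model.n_nodes and not config.allow_partial:
        return MatchResult({}, INF, 0, "no_solution", empty_trace)

    order = _test_order(test)
    areas = [test.nodes[p].a[0] for p in order]
    # h for a state at depth k = suffix area sum + (n - k) * c
    suffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + areas[i]

    def h_at(depth: int) -> float:
        return suffix[depth] + (n - depth) * config.c

    trace = empty_trace  # steps entries are (h_increment, g_increment)

    counter = itertools.count()
    root_h = h_at(0)
    open_list: list = [(root_h, next(counter), 0.0, ())]  # (f, tie, g, mapping)
    expansions = 0
    while open_list:
        f, _, g, mapped = heapq.heappop(open_list)
        expansions += 1
        if trace is not None:
            trace["popped_f"].append(f)
        depth = len(mapped)
        if depth == n:
            mapping = {p: q for p, q in zip(order, mapped)}
            return MatchResult(mapping, g, expansions, "matched", trace)
        if expansions > config.max_expansions:
            return MatchResult({}, INF, expansions, "budget_exceeded", trace)
        p = order[depth]
        used = set(m for m in mapped if m is not None)
        prefix_map = {order[i]: mapped[i] for i in range(depth)}
        h_child = h_at(depth + 1)
        for q in sorted(model.nodes):
            if q in used:
                continue
            try:
                d = pair_distance(test, model, p, q, prefix_map, config)
            except Impermissible:
                continue
            w = pair_weight(test.nodes[p].a[0], model.nodes[q].a[0])
            g_inc = g_increment(w, d, config.c)
            if trace is not None:
                trace["steps"].append((areas[depth] + config.c, g_inc))
            g2 = g + g_inc
            heapq.heappush(open_list, (g2 + h_child, next(counter), g2, mapped + (q,)))
        if config.allow_partial:
            g_inc = (areas[depth] + 1.0) + config.c
            g2 = g + g_inc
            heapq.heappush(
                open_list, (g2 + h_child, next(counter), g2, mapped + (None,))
            )
    return MatchResult({}, INF, expansions, "no_solution", trace)


def brute_force_match(
    test: AttributedGraph,
    model: AttributedGraph,
    config: MatchConfig | None = None,
    guard: int = 10**6,
) -> MatchResult:
    """Exhaustive-enumeration oracle for :func:`astar_match`.

    Enumerates every label-consistent injective mapping of the test nodes
    (same area ordering as the A* search), rejects those violating edge
    preservation, scores the rest with the identical arithmetic and returns
    the minimum (lexicographically smallest mapping among exact cost ties).
    Refuses instances whose label-candidate product exceeds ``guard``.
    """
    config = config or MatchConfig()
    if test.n_nodes == 0:
        raise ValueError("test graph has no nodes")
    order = _test_order(test)
    candidates = [
        sorted(
            q for q in model.nodes if model.nodes[q].label == test.nodes[p].label
        )
        for p in order
    ]
    n_combo = 1
    for cand in candidates:
        n_combo *= max(1, len(cand))
        if n_combo > guard:
            raise ValueError(f"instance too large to enumerate (> {guard})")

    best_cost = INF
    best_assign: tuple[int, ...] | None = None
    n_checked = 0
    for assign in itertools.product(*candidates):
        if len(set(assign)) != len(assign):
            continue
        n_checked += 1
        cost = _score_assignment(test, model, order, assign, config)
        if cost is None:
            continue
        if cost < best_cost or (
            cost == best_cost and (best_assign is None or assign < best_assign)
        ):
            best_cost = cost
            best_assign = assign
    if best_assign is None:
        return MatchResult({}, INF, n_checked, "no_solution")
    return MatchResult(
        {p: q for p, q in zip(order, best_assign)}, best_cost, n_checked, "matched"
    )


def _score_assignment(test, model, order, assign, config) -> float | None:
    """Score one complete mapping with the incremental arithmetic of the
    search (None if some test edge lacks a model counterpart)."""
    g = 0.0
    mapping: dict[int, int] = {}
    for p, q in zip(order, assign):
        try:
            d = pair_distance(test, model, p, q, mapping, config)
        except Impermissible:
            return None
        w = pair_weight(test.nodes[p].a[0], model.nodes[q].a[0])
        g += g_increment(w, d, config.c)
        mapping[p] = q
    return g
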