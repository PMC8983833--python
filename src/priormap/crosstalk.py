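"""Pathway-crosstalk subnetwork search and node-attack analysis.

From a network restricted to enriched-pathway genes, with each node scored by
how far its priority rating exceeds a "highly prioritized" threshold, the
crosstalk is the connected subgraph of maximum total node score: exact
enumeration for small networks, a seeded merge-and-prune heuristic above
that.  Its significance is assessed by permuting node scores.  Attack
analysis then measures how badly removing single nodes or small combinations
fragments the crosstalk (fraction of remaining nodes disconnected from the
largest component).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoredNetwork",
    "CrosstalkSubgraph",
    "AttackResult",
    "scored_network",
    "search_crosstalk",
    "crosstalk_significance",
    "disconnection_effect",
    "attack_combinations",
]

#: node-traversal tie-break penalty for the path search
EPS_PENALTY = 1e-6

#: exact enumeration is used up to this many nodes
EXACT_LIMIT = 15


@dataclass
class ScoredNetwork:
    """A network with a (possibly negative) score per node."""

    graph: nx.Graph
    scores: dict[str, float]
    threshold: float = 0.0

    def __post_init__(self) -> None:
        missing = set(self.graph.nodes) - set(self.scores)
        if missing:
            raise ValueError(f"nodes without a score: {sorted(missing)[:5]}")


@dataclass
class CrosstalkSubgraph:
    nodes: tuple[str, ...]
    graph: nx.Graph
    total_score: float
    pvalue: float | None = None
    empirical_pvalue: float | None = None
    null_mean: float | None = None
    null_std: float | None = None


@dataclass(frozen=True)
class AttackResult:
    removed: tuple[str, ...]
    fixed_context: tuple[str, ...]
    effect: float


def scored_network(
    network: nx.Graph,
    priority: pd.DataFrame,
    restrict_to: set[str] | None = None,
    quantile: float = 0.9,
) -> ScoredNetwork:
    """Score network nodes as rating minus the ``quantile`` rating threshold.

    ``restrict_to`` (e.g. the union of enriched-pathway genes) limits the
    network to those nodes first; nodes without a rating are dropped.
    """
    ratings = dict(zip(priority["gene"], priority["rating"]))
    nodes = [n for n in network.nodes if n in ratings]
    if restrict_to is not None:
        nodes = [n for n in nodes if n in restrict_to]
    sub = network.subgraph(nodes).copy()
    values = np.array([ratings[n] for n in sub.nodes])
    if values.size == 0:
        raise ValueError("no rated node remains in the scored network")
    threshold = float(np.quantile(values, quantile))
    scores = {n: ratings[n] - threshold for n in sub.nodes}
    return ScoredNetwork(sub, scores, threshold)


def _exact_search(scored: ScoredNetwork) -> tuple[tuple[str, ...], float]:
    nodes = sorted(scored.graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in scored.graph.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    score = [scored.scores[v] for v in nodes]
    best_mask, best_score = 0, -np.inf
    for mask in range(1, 1 << n):
        # connectivity by bitmask flood fill from the lowest set bit
        seen = mask & -mask
        frontier = seen
        while frontier:
            nxt = 0
            m = frontier
            while m:
                b = m & -m
                nxt |= adj[b.bit_length() - 1]
                m ^= b
            nxt &= mask & ~seen
            seen |= nxt
            frontier = nxt
        if seen != mask:
            continue
        total = sum(score[i] for i in range(n) if mask >> i & 1)
        if total > best_score + 1e-12:
            best_mask, best_score = mask, total
    members = tuple(nodes[i] for i in range(n) if best_mask >> i & 1)
    return members, float(best_score)


def _node_cost(scored: ScoredNetwork, v: str) -> float:
    return max(0.0, -scored.scores[v]) + EPS_PENALTY


def _cheapest_path(
    scored: ScoredNetwork, sources: set[str], targets: set[str]
) -> tuple[float, list[str]] | None:
    """Node-weighted Dijkstra from any source to any target.

    The cost of a path is the sum of traversal costs of the nodes entered
    (sources cost nothing); returns (cost, intermediate+target nodes).
    """
    dist: dict[str, float] = {}
    prev: dict[str, str | None] = {}
    heap: list[tuple[float, str]] = []
    for s in sorted(sources):
        dist[s] = 0.0
        prev[s] = None
        heapq.heappush(heap, (0.0, s))
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        if u in targets:
            path = []
            node: str | None = u
            while node is not None and node not in sources:
                path.append(node)
                node = prev[node]
            return d, path[::-1]
        for v in sorted(scored.graph.neighbors(u)):
            nd = d + _node_cost(scored, v)
            if nd < dist.get(v, np.inf) - 1e-15:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    return None


def _heuristic_search(scored: ScoredNetwork) -> tuple[tuple[str, ...], float]:
    positives = [v for v in scored.graph.nodes if scored.scores[v] > 0]
    pos_components = sorted(
        (sorted(c) for c in nx.connected_components(scored.graph.subgraph(positives))),
        key=lambda c: (-sum(scored.scores[v] for v in c), c),
    )
    current = set(pos_components[0])
    remaining = [set(c) for c in pos_components[1:]]
    improved = True
    while improved and remaining:
        improved = False
        best = None  # (gain, cost, comp_index, path)
        for i, comp in enumerate(remaining):
            found = _cheapest_path(scored, current, comp)
            if found is None:
                continue
            cost, path = found
            gain = sum(scored.scores[v] for v in comp | set(path) if v not in current)
            if gain > 0 and (best is None or gain > best[0] + 1e-12):
                best = (gain, cost, i, path)
        if best is not None:
            _, _, i, path = best
            current |= remaining.pop(i) | set(path)
            improved = True
    # prune negative-score leaves of the induced subgraph
    pruned = True
    while pruned:
        pruned = False
        sub = scored.graph.subgraph(current)
        for v in sorted(current):
            if scored.scores[v] < 0 and sub.degree(v) <= 1:
                current.discard(v)
                pruned = True
                break
    total = sum(scored.scores[v] for v in current)
    return tuple(sorted(current)), float(total)


def search_crosstalk(scored: ScoredNetwork) -> CrosstalkSubgraph:
    """Connected subgraph maximizing total node score.

    Exact subset enumeration for networks of up to 15 nodes; above that, a
    deterministic heuristic: positive-score components are merged through
    lowest-penalty paths (traversing a node costs max(0, -score) plus a tiny
    tie-break), accepting a merge only if the total score rises, then
    negative-score leaves are pruned.
    """
    if not any(s > 0 for s in scored.scores.values()):
        raise ValueError("no node with positive score; crosstalk undefined")
    if scored.graph.number_of_nodes() <= EXACT_LIMIT:
        members, total = _exact_search(scored)
    else:
        members, total = _heuristic_search(scored)
    return CrosstalkSubgraph(members, scored.graph.subgraph(members).copy(), total)


def crosstalk_significance(
    scored: ScoredNetwork, n_perm: int = 1000, seed: int = 0
) -> CrosstalkSubgraph:
    """Permutation significance of the crosstalk's total score.

    Node scores are shuffled across nodes ``n_perm`` times and the search is
    re-run; the null total scores are fitted with a normal distribution whose
    upper tail gives the parametric p-value (the route to extreme values the
    empirical count cannot resolve); the empirical p is reported alongside.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = search_crosstalk(scored)
    rng = np.random.default_rng(seed)
    nodes = sorted(scored.graph.nodes)
    values = np.array([scored.scores[v] for v in nodes])
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = dict(zip(nodes, values[rng.permutation(len(nodes))]))
        if not any(s > 0 for s in perm.values()):
            null[b] = 0.0
            continue
        null[b] = search_crosstalk(ScoredNetwork(scored.graph, perm)).total_score
    mean, std = float(null.mean()), float(null.std(ddof=1))
    empirical = float((1 + np.sum(null >= observed.total_score)) / (1 + n_perm))
    parametric = float(stats.norm.sf(observed.total_score, loc=mean, scale=std)) if std > 0 else None
    observed.pvalue = parametric
    observed.empirical_pvalue = empirical
    observed.null_mean = mean
    observed.null_std = std
    return observed


def disconnection_effect(
    graph: nx.Graph, removed: set[str], denominator: str = "remaining"
) -> float:
    """Fraction of nodes disconnected from the largest component after removal.

    effect = 1 - |largest component of G minus removed| / D with D the number
    of remaining nodes (default) or, with ``denominator="original"``, the full
    node count.
    """
    removed = set(removed)
    if not removed <= set(graph.nodes):
        raise ValueError("removed nodes must belong to the graph")
    rest = [v for v in graph.nodes if v not in removed]
    if not rest:
        raise ValueError("cannot remove every node")
    sub = graph.subgraph(rest)
    largest = max((len(c) for c in nx.connected_components(sub)), default=0)
    D = len(rest) if denominator == "remaining" else graph.number_of_nodes()
    return 1.0 - largest / D


def attack_combinations(
    graph: nx.Graph,
    k: int,
    fixed_context: set[str] | frozenset[str] = frozenset(),
    denominator: str = "remaining",
) -> list[AttackResult]:
    """Exhaustively rank k-node removals completing a fixed context.

    ``fixed_context`` nodes (fewer than ``k`` of them) are always removed
    together with every combination of the remaining ``k - |fixed_context|``
    candidate nodes.  Results are sorted by effect descending, ties broken by
    lexicographic gene order.
    """
    fixed = tuple(sorted(fixed_context))
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(fixed) >= k:
        raise ValueError(f"fixed_context has {len(fixed)} nodes; must be fewer than k={k}")
    if not set(fixed) <= set(graph.nodes):
        raise ValueError("fixed_context nodes must belong to the graph")
    m = k - len(fixed)
    candidates = sorted(set(graph.nodes) - set(fixed))
    results = [
        AttackResult(
            removed=combo,
            fixed_context=fixed,
            effect=disconnection_effect(graph, set(combo) | set(fixed), denominator),
        )
        for combo in itertools.combinations(candidates, m)
    ]
    results.sort(key=lambda r: (-r.effect, r.removed))
    return results
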