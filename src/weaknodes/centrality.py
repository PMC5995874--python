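"""Node rankings: Collective Influence and five comparison centralities.

Collective Influence (CI) scores a node by its degree *and* by the degrees
on the frontier of its radius-``ell`` sphere of influence,

    CI_ell(i) = (k_i - 1) * sum_{j in dBall(i, ell)} (k_j - 1),

where ``dBall(i, ell)`` holds the nodes at shortest-path distance exactly
``ell`` from ``i``.  At ``ell = 0`` the frontier is the node itself and the
ordering reduces to plain degree; for ``ell >= 1`` low-degree nodes can
outrank hubs when their sphere of influence is rich in high-degree nodes —
the signature of "weak nodes" that bridge densely connected modules.

The adaptive ranking is the greedy decimation used in optimal percolation:
repeatedly remove the current top-CI node and rescore the survivors, so the
removal order approximates the minimal set dismantling the giant component.

Degree, k-core, eigenvector, closeness and betweenness are delegated to
networkx; CI (undirected and directed) is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable

import networkx as nx

from .network import as_graph

__all__ = [
    "Ranking",
    "ci_scores",
    "ci_directed_scores",
    "ci_ranking",
    "ci_directed_ranking",
    "degree_ranking",
    "kcore_ranking",
    "eigenvector_ranking",
    "closeness_ranking",
    "betweenness_ranking",
    "adaptive_ranking",
    "CENTRALITIES",
]


@dataclass
class Ranking:
    """Ordered node list for one centrality; rank 1 is most influential.

    For adaptive (decimation) rankings the stored score is the one the node
    had at its removal step, so scores need not be monotone along the order.
    """

    centrality_name: str
    order: list
    scores: dict
    ell: int | None = None
    adaptive: bool = False

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranking order contains duplicates")
        if set(self.order) != set(self.scores):
            raise ValueError("order and scores cover different node sets")
        if not self.adaptive:
            vals = [self.scores[v] for v in self.order]
            if any(a < b - 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValueError("static ranking scores must be nonincreasing")

    def rank_of(self, node: Hashable) -> int:
        return self.order.index(node) + 1

    def top(self, k: int) -> list:
        return self.order[:k]

    def __len__(self) -> int:
        return len(self.order)


def _sorted_ranking(name: str, scores: dict, *, ell: int | None = None) -> Ranking:
    order = sorted(scores, key=lambda v: (-scores[v], v))
    return Ranking(name, order, dict(scores), ell=ell)


# ----------------------------------------------------------------------
# Collective Influence
# ----------------------------------------------------------------------

def _frontier(g: nx.Graph, source: Hashable, ell: int,
              out: bool = False) -> set:
    """Nodes at shortest-path distance exactly ``ell`` from ``source``."""
    neighbors = g.successors if out and g.is_directed() else g.neighbors
    current = {source}
    seen = {source}
    for _ in range(ell):
        nxt = {w for v in current for w in neighbors(v)} - seen
        if not nxt:
            return set()
        seen |= nxt
        current = nxt
    return current


def ci_scores(net, ell: int) -> dict:
    """Collective Influence score per node at sphere radius ``ell``.

    ``ell = 0`` returns the degree (the zero-order limit); for
    ``ell >= 1`` leaves and isolated nodes (k_i <= 1) score 0.
    """
    if ell < 0:
        raise ValueError("ell must be nonnegative")
    g = as_graph(net)
    if g.is_directed():
        raise ValueError("ci_scores expects an undirected network; "
                         "use ci_directed_scores")
    if ell == 0:
        return {v: g.degree(v) for v in g.nodes}
    scores = {}
    for v in g.nodes:
        k = g.degree(v)
        if k <= 1:
            scores[v] = 0
            continue
        scores[v] = (k - 1) * sum(g.degree(j) - 1 for j in _frontier(g, v, ell))
    return scores


def ci_directed_scores(net, ell: int) -> dict:
    """Directed CI: out-degree times in-degrees on the outgoing ``ell``-frontier."""
    if ell < 0:
        raise ValueError("ell must be nonnegative")
    g = as_graph(net)
    if not g.is_directed():
        raise ValueError("ci_directed_scores expects a directed network")
    if ell == 0:
        return {v: g.out_degree(v) for v in g.nodes}
    scores = {}
    for v in g.nodes:
        k = g.out_degree(v)
        if k <= 1:
            scores[v] = 0
            continue
        frontier = _frontier(g, v, ell, out=True)
        scores[v] = (k - 1) * sum(g.in_degree(j) - 1 for j in frontier)
    return scores


def adaptive_ranking(net, scorer: Callable[[nx.Graph], dict],
                     name: str, ell: int | None = None) -> Ranking:
    """Greedy decimation: remove the current top-scoring node, rescore, repeat.

    When every remaining score is zero but edges remain (e.g. the CI
    sphere-of-influence frontier is empty in small surviving fragments),
    decimation continues by current degree — the zero-radius limit of CI.
    Fully isolated nodes are appended by id.
    """
    g = as_graph(net).copy()
    order: list = []
    scores: dict = {}
    while g.number_of_nodes():
        s = scorer(g)
        top_score = max(s.values())
        if top_score <= 0:
            if g.number_of_edges() == 0:
                for v in sorted(g.nodes):
                    order.append(v)
                    scores[v] = 0
                break
            s = dict(g.degree())
            top_score = max(s.values())
        # deterministic tie-break: max score, then smallest id
        best = min(v for v in s if s[v] == top_score)
        order.append(best)
        scores[best] = s[best]
        g.remove_node(best)
    return Ranking(name, order, scores, ell=ell, adaptive=True)


def ci_ranking(net, ell: int = 2, adaptive: bool = True) -> Ranking:
    """CI ranking; adaptive mode is the optimal-percolation decimation order."""
    if adaptive:
        return adaptive_ranking(net, lambda g: ci_scores(g, ell), "ci", ell=ell)
    return _sorted_ranking("ci", ci_scores(net, ell), ell=ell)


def ci_directed_ranking(net, ell: int = 2, adaptive: bool = True) -> Ranking:
    if adaptive:
        return adaptive_ranking(net, lambda g: ci_directed_scores(g, ell),
                                "ci_directed", ell=ell)
    return _sorted_ranking("ci_directed", ci_directed_scores(net, ell), ell=ell)


# ----------------------------------------------------------------------
# comparison centralities
# ----------------------------------------------------------------------

def degree_ranking(net) -> Ranking:
    g = as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return _sorted_ranking("degree", dict(g.degree()))


def kcore_ranking(net) -> Ranking:
    """Score = core index: the largest k whose iterative degree-k pruning keeps the node."""
    g = as_graph(net)
    return _sorted_ranking("kcore", nx.core_number(g))


def eigenvector_ranking(net) -> Ranking:
    """Principal adjacency eigenvector; computed on the largest component
    (other nodes score 0) since the leading eigenvector localizes there."""
    g = as_graph(net)
    scores = {v: 0.0 for v in g.nodes}
    if g.number_of_edges():
        comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
        sub = g.subgraph(comp)
        try:
            ev = nx.eigenvector_centrality(sub, max_iter=1000, tol=1e-10)
        except nx.PowerIterationFailedConvergence:
            # dense fallback for graphs where power iteration stalls
            if len(comp) == 2:
                ev = {v: 2 ** -0.5 for v in comp}
            else:
                ev = nx.eigenvector_centrality_numpy(sub)
        scores.update(ev)
    return _sorted_ranking("eigenvector", scores)


def closeness_ranking(net) -> Ranking:
    """(n_c - 1) / sum of distances within each node's own component."""
    g = as_graph(net)
    scores: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        # wf_improved=False keeps the plain within-component convention
        scores.update(nx.closeness_centrality(sub, wf_improved=False))
    return _sorted_ranking("closeness", scores)


def betweenness_ranking(net) -> Ranking:
    """Exact Brandes betweenness, unnormalized, each unordered pair counted once."""
    g = as_graph(net)
    return _sorted_ranking("betweenness", nx.betweenness_centrality(g, normalized=False))


def _ci_factory(ell: int, adaptive: bool):
    return lambda net: ci_ranking(net, ell=ell, adaptive=adaptive)


CENTRALITIES: dict[str, Callable] = {
    "ci": ci_ranking,
    "degree": degree_ranking,
    "kcore": kcore_ranking,
    "eigenvector": eigenvector_ranking,
    "closeness": closeness_ranking,
    "betweenness": betweenness_ranking,
}
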