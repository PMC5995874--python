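"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: path enumeration, dense eigensolvers, exhaustive
subset search.  Only usable on small graphs.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def bfs_distances(g: nx.Graph, source):
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    return dist


def betweenness_oracle(g: nx.Graph) -> dict:
    """Sum over unordered pairs of the fraction of shortest paths through i."""
    scores = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / len(paths)
    return scores


def closeness_oracle(g: nx.Graph) -> dict:
    scores = {}
    for v in g.nodes:
        dist = bfs_distances(g, v)
        total = sum(dist.values())
        scores[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return scores


def eigenvector_oracle(g: nx.Graph) -> dict:
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    nodes = sorted(comp)
    a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes)
    w, v = np.linalg.eigh(a)
    lead = np.abs(v[:, np.argmax(w)])
    lead = lead / np.linalg.norm(lead)
    out = {u: 0.0 for u in g.nodes}
    out.update(dict(zip(nodes, lead)))
    return out


def kcore_oracle(g: nx.Graph) -> dict:
    core = {}
    for v in g.nodes:
        k = 0
        while True:
            h = g.copy()
            changed = True
            while changed:
                low = [u for u in h.nodes if h.degree(u) < k + 1]
                changed = bool(low)
                h.remove_nodes_from(low)
            if v in h.nodes:
                k += 1
            else:
                break
        core[v] = k
    return core


def ci_oracle(g: nx.Graph, ell: int) -> dict:
    """Direct evaluation of (k_i-1) * sum over the exact-distance-ell shell."""
    scores = {}
    for v in g.nodes:
        k = g.degree(v)
        if ell == 0:
            scores[v] = k
            continue
        if k <= 1:
            scores[v] = 0
            continue
        dist = bfs_distances(g, v)
        shell = [u for u, d in dist.items() if d == ell]
        scores[v] = (k - 1) * sum(g.degree(u) - 1 for u in shell)
    return scores


def largest_component_size(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def minimum_dismantling_size(g: nx.Graph, target_abs: float) -> int:
    """Smallest number of removals leaving every component <= target_abs nodes."""
    nodes = sorted(g.nodes)
    for k in range(len(nodes) + 1):
        for combo in itertools.combinations(nodes, k):
            h = g.copy()
            h.remove_nodes_from(combo)
            if largest_component_size(h) <= target_abs:
                return k
    return len(nodes)
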