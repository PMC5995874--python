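"""Core network container shared by all stages.

A :class:`BrainNetwork` is a thin wrapper around a :class:`networkx.Graph`
(or :class:`~networkx.DiGraph`) carrying per-node module labels and optional
spatial coordinates, plus a per-edge intra/inter link classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import networkx as nx

__all__ = ["BrainNetwork", "as_graph"]


@dataclass
class BrainNetwork:
    """Sparse interaction network over a set of labelled nodes.

    Parameters
    ----------
    graph
        Undirected or directed simple graph. Self-loops are rejected.
    modules
        Optional mapping node -> module label. Nodes without a label get
        ``None``.
    coords
        Optional mapping node -> spatial coordinate tuple.
    """

    graph: nx.Graph | nx.DiGraph
    modules: dict[Hashable, object] = field(default_factory=dict)
    coords: dict[Hashable, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:5]}")
        extra = set(self.modules) - set(self.graph.nodes)
        if extra:
            raise ValueError(f"module labels for unknown nodes: {sorted(extra)[:5]}")

    # -- basic accessors -------------------------------------------------
    @property
    def node_ids(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def is_directed(self) -> bool:
        return self.graph.is_directed()

    def module_of(self, node: Hashable):
        return self.modules.get(node)

    def degree(self, node: Hashable) -> int:
        return self.graph.degree(node)

    def link_class(self, u: Hashable, v: Hashable) -> str:
        """``"intra"`` if both endpoints share a module label, else ``"inter"``."""
        return "intra" if self.modules.get(u) == self.modules.get(v) else "inter"

    def edges_by_class(self) -> dict[str, list[tuple]]:
        out: dict[str, list[tuple]] = {"intra": [], "inter": []}
        for u, v in self.graph.edges:
            out[self.link_class(u, v)].append((u, v))
        return out

    def module_sizes(self) -> dict[object, int]:
        sizes: dict[object, int] = {}
        for node in self.graph.nodes:
            lab = self.modules.get(node)
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def subgraph_without(self, removed: Iterable[Hashable]) -> nx.Graph:
        keep = set(self.graph.nodes) - set(removed)
        return self.graph.subgraph(keep)

    def copy(self) -> "BrainNetwork":
        return BrainNetwork(self.graph.copy(), dict(self.modules), dict(self.coords))


def as_graph(net: "BrainNetwork | nx.Graph | nx.DiGraph") -> nx.Graph | nx.DiGraph:
    """Accept either a raw networkx graph or a :class:`BrainNetwork`."""
    if isinstance(net, BrainNetwork):
        return net.graph
    if isinstance(net, (nx.Graph, nx.DiGraph)):
        return net
    raise TypeError(f"expected BrainNetwork or networkx graph, got {type(net)!r}")


def modules_of(net: "BrainNetwork | nx.Graph | nx.DiGraph", partition: Mapping | None = None) -> dict:
    """Resolve a node -> module mapping from an explicit partition or the network."""
    if partition is not None:
        return dict(partition)
    if isinstance(net, BrainNetwork):
        return dict(net.modules)
    return {}
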