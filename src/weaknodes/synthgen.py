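"""Synthetic cohorts with planted weak-node bridges.

The generator emulates the structure of an evoked functional brain network:
a hub-rich "stimulated" module, a low-degree "bridge" module and a third
intermediate module, with the few inter-module links routed exclusively
through planted low-degree bridge nodes.  Because every path between the
outer modules crosses a planted bridge, those bridges are ground-truth
essential integrators even though their degree is small.  A matched
precision matrix turns the graph into a Gaussian graphical model so that
sampled time series have the planted partial-correlation structure, giving
every downstream stage (inference, ranking, percolation) a known answer.

Each module's intra-links are a connectivity backbone (a random
attachment tree; degree-capped in the bridge module) plus uniform extra
edges up to the requested intra-link density.  At the default density the
outer modules are densely knit near-cliques: every node of a module sits
within distance two of every other, so internal radius-2 spheres of
influence are degree-poor, while a planted bridge's sphere contains the
dense interiors of *both* modules it joins — the planted bridges are
low-degree yet maximally collective-influential, the "strength of weak
ties" regime.  In the ``resting`` regime the inter-links are placed
uniformly between modules instead of through bridges, so no module holds
a privileged integrative position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .network import BrainNetwork

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "UnsatisfiableSpecError",
    "generate_modular_graph",
    "build_precision",
    "sample_gaussian_series",
    "sample_var_series",
    "generate_cohort",
]

STIMULATED = "stimulated"
BRIDGE = "bridge"
THIRD = "third"

_MAX_RETRIES = 50


class UnsatisfiableSpecError(RuntimeError):
    """Raised when no graph satisfying the spec was found within the retry budget."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults are the package's reference evoked condition: a 95-node
    network of three modules (40-node stimulated, 15-node bridge, 40-node
    third), densely knit intra-links (near-clique modules, the
    "densely knit clumps" of the weak-ties picture), five planted bridge
    nodes of degree at most three carrying all stimulated-third traffic,
    pairwise coupling 0.3 and series of length 50 time points per node.
    """

    n_subjects: int = 6
    module_sizes: tuple[int, ...] = (40, 15, 40)
    intra_density: float = 1.0
    n_bridge_nodes: int = 5
    bridge_degree_cap: int = 3
    coupling: float = 0.3
    T: int | None = None  # default 50 * n_nodes
    noise_sd: float = 0.1
    seed: int = 0
    regime: str = "evoked"
    # cohort-shared template: which bridge-module nodes are the planted
    # bridges (the "anatomical location" shared by all subjects); defaults
    # to the subject seed when standing alone
    template_seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))

    @property
    def n_nodes(self) -> int:
        n = sum(self.module_sizes)
        if len(self.module_sizes) == 2:
            n += self.n_bridge_nodes  # standalone bridge nodes
        return n

    @property
    def n_timepoints(self) -> int:
        return 50 * self.n_nodes if self.T is None else self.T

    def validate(self) -> None:
        if len(self.module_sizes) not in (2, 3):
            raise ValueError("module_sizes must have 2 or 3 entries")
        if any(m < 3 for m in self.module_sizes):
            raise ValueError("every module must have at least 3 nodes")
        if self.regime not in ("evoked", "resting"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "evoked" and self.n_bridge_nodes < 1:
            raise ValueError("evoked regime requires at least one bridge node")
        if not 0.0 < self.intra_density <= 1.0:
            raise ValueError("intra_density must be in (0, 1]")
        if self.bridge_degree_cap < 2:
            raise ValueError("bridge_degree_cap must be >= 2 (one link per side)")
        if self.coupling <= 0:
            raise ValueError("coupling must be positive")
        if len(self.module_sizes) == 3 and self.n_bridge_nodes > self.module_sizes[1]:
            raise ValueError("more bridge nodes than bridge-module nodes")


@dataclass
class GroundTruth:
    """Planted graph, matched precision matrix and bridge-node identities."""

    network: BrainNetwork
    precision: np.ndarray
    planted_bridges: set
    directed_edges: list[tuple] = field(default_factory=list)

    @property
    def graph(self) -> nx.Graph:
        return self.network.graph

    @classmethod
    def from_edges(cls, n_nodes: int, directed_edges: Sequence[tuple]) -> "GroundTruth":
        """Minimal ground truth for a hand-specified directed wiring."""
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from((u, v) for u, v in directed_edges)
        net = BrainNetwork(g)
        return cls(net, np.eye(n_nodes), set(), list(directed_edges))


# ----------------------------------------------------------------------
# graph construction
# ----------------------------------------------------------------------

def _attachment_tree(nodes: Sequence[int], rng: np.random.Generator,
                     preferential: bool, degree_cap: int | None = None) -> list[tuple]:
    """Random recursive tree over ``nodes``.

    With ``preferential`` each newcomer attaches proportionally to current
    degree (hubs emerge); otherwise uniformly.  ``degree_cap`` bounds the
    degree of attachment targets (low-degree backbone).
    """
    nodes = list(nodes)
    if len(nodes) <= 1:
        return []
    edges: list[tuple] = []
    deg = {nodes[0]: 0}
    for v in nodes[1:]:
        candidates = [u for u in deg if degree_cap is None or deg[u] < degree_cap]
        if not candidates:  # cap saturated; fall back to least-loaded node
            candidates = [min(deg, key=lambda u: (deg[u], u))]
        if preferential:
            w = np.array([deg[u] + 1.0 for u in candidates])
            target = candidates[rng.choice(len(candidates), p=w / w.sum())]
        else:
            target = candidates[rng.integers(len(candidates))]
        edges.append((target, v))
        deg[target] += 1
        deg[v] = 1
    return edges


def _fill_density(g: nx.Graph, nodes: Sequence[int], density: float,
                  rng: np.random.Generator) -> None:
    """Add uniform extra intra-links until the module reaches ``density``."""
    nodes = list(nodes)
    n = len(nodes)
    target = int(round(density * n * (n - 1) / 2))
    existing = g.subgraph(nodes).number_of_edges()
    missing = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]
               if not g.has_edge(u, v)]
    n_extra = min(max(target - existing, 0), len(missing))
    if n_extra:
        for idx in rng.choice(len(missing), size=n_extra, replace=False):
            g.add_edge(*missing[idx])


def _build_once(spec: CohortSpec, rng: np.random.Generator) -> tuple[nx.Graph, dict, set]:
    sizes = spec.module_sizes
    three = len(sizes) == 3
    bounds = np.cumsum((0,) + sizes)
    if three:
        blocks = [list(range(bounds[i], bounds[i + 1])) for i in range(3)]
        labels = [STIMULATED, BRIDGE, THIRD]
    else:
        blocks = [list(range(bounds[0], bounds[1])), list(range(bounds[1], bounds[2]))]
        labels = [STIMULATED, THIRD]

    g = nx.Graph()
    modules: dict[int, str] = {}
    for block, lab in zip(blocks, labels):
        g.add_nodes_from(block)
        for v in block:
            modules[v] = lab

    resting = spec.regime == "resting"
    for block, lab in zip(blocks, labels):
        if resting:
            tree = _attachment_tree(block, rng, preferential=False)
        elif lab == BRIDGE:
            tree = _attachment_tree(block, rng, preferential=False,
                                    degree_cap=max(spec.bridge_degree_cap, 2))
        else:
            # preferential attachment backbone: hubs emerge at any density
            tree = _attachment_tree(block, rng, preferential=True)
        g.add_edges_from(tree)
        _fill_density(g, block, spec.intra_density, rng)

    stim, third = blocks[0], blocks[-1]

    if resting:
        # Inter-links without privileged bridges.  Counts per module pair
        # are solved so that every node is equally likely to host an
        # inter-link (naive pair-uniform sampling overrepresents small
        # modules, whose nodes have more cross-module partners).
        m_inter = 2 * spec.n_bridge_nodes
        sizes_b = [len(b) for b in blocks]
        if len(blocks) == 2:
            counts = {(0, 1): m_inter}
        else:
            lam = 2 * m_inter / sum(sizes_b)
            a = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=float)
            sol = np.linalg.solve(a, lam * np.asarray(sizes_b, dtype=float))
            probs = np.clip(sol, 0, None)
            probs = probs / probs.sum()
            draw = rng.multinomial(m_inter, probs)
            counts = {(0, 1): draw[0], (0, 2): draw[1], (1, 2): draw[2]}
        for (i, j), cnt in counts.items():
            placed = 0
            for _ in range(50 * max(cnt, 1)):
                if placed >= cnt:
                    break
                u = int(rng.choice(blocks[i]))
                v = int(rng.choice(blocks[j]))
                if not g.has_edge(u, v):
                    g.add_edge(u, v)
                    placed += 1
        return g, modules, set()

    if three:
        bridge_block = blocks[1]
        t_seed = spec.seed if spec.template_seed is None else spec.template_seed
        rng_t = np.random.default_rng(t_seed)
        bridges = set(rng_t.choice(bridge_block, size=spec.n_bridge_nodes,
                                   replace=False).tolist())
        # strip planted bridges down so inter-links fit under the degree cap
        for b in bridges:
            nbrs = sorted(g.neighbors(b))
            keep_internal = max(spec.bridge_degree_cap - 2, 0)
            for v in nbrs[keep_internal:]:
                g.remove_edge(b, v)
        # keep the bridge module internally connected among non-bridge nodes
        rest = [v for v in bridge_block if v not in bridges]
        if rest:
            comp_fix = _attachment_tree(rest, rng, preferential=False,
                                        degree_cap=max(spec.bridge_degree_cap, 2))
            g.add_edges_from(e for e in comp_fix if not g.has_edge(*e))
    else:
        bridges = set(range(bounds[-1], bounds[-1] + spec.n_bridge_nodes))
        g.add_nodes_from(bridges)
        for b in bridges:
            modules[b] = BRIDGE

    # Route all stimulated-third traffic through the planted bridges.
    # Attachment points are neighbours of degree-weighted hubs, so each
    # bridge's radius-2 sphere of influence contains a module hub: the
    # planted bridges are low-degree yet surrounded by high-degree nodes.
    def gateway(block: list[int]) -> int:
        degs = np.array([g.degree(v) for v in block], dtype=float)
        if degs.sum() == 0:
            return int(rng.choice(block))
        hub = block[int(rng.choice(len(block), p=degs / degs.sum()))]
        nbrs = [w for w in g.neighbors(hub) if modules[w] == modules[hub]]
        leaf_nbrs = [w for w in nbrs if g.degree(w) == 1]
        pool = leaf_nbrs or nbrs
        return int(rng.choice(pool)) if pool else int(hub)

    for b in sorted(bridges):
        g.add_edge(b, gateway(stim))
        g.add_edge(b, gateway(third))
    return g, modules, bridges


def generate_modular_graph(spec: CohortSpec) -> GroundTruth:
    """Draw one planted modular graph satisfying the spec's structural contract.

    Post-conditions (re-drawn up to a retry budget, then
    :class:`UnsatisfiableSpecError`): the graph is connected, the
    stimulated module contains a node of degree above ``bridge_degree_cap``
    (hub-rich), planted bridges respect the cap, and in the evoked regime
    removing the planted bridges disconnects the stimulated module from
    the third one.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    last_reason = "no attempt"
    for _ in range(_MAX_RETRIES):
        g, modules, bridges = _build_once(spec, rng)
        if not nx.is_connected(g):
            last_reason = "graph disconnected"
            continue
        stim_nodes = [v for v, m in modules.items() if m == STIMULATED]
        if max(g.degree(v) for v in stim_nodes) <= spec.bridge_degree_cap:
            last_reason = "stimulated module not hub-rich"
            continue
        if bridges and any(g.degree(b) > spec.bridge_degree_cap for b in bridges):
            last_reason = "bridge degree cap violated"
            continue
        net = BrainNetwork(g, modules)
        prec = build_precision_from_graph(g, spec.coupling)
        directed = _orient_edges(g, rng)
        return GroundTruth(net, prec, bridges, directed)
    raise UnsatisfiableSpecError(
        f"unsatisfiable spec after {_MAX_RETRIES} retries (last failure: {last_reason})")


def _orient_edges(g: nx.Graph, rng: np.random.Generator) -> list[tuple]:
    """One random direction per undirected edge (used by the VAR regime)."""
    out = []
    for u, v in sorted(g.edges):
        out.append((u, v) if rng.random() < 0.5 else (v, u))
    return out


# ----------------------------------------------------------------------
# Gaussian graphical model and sampling
# ----------------------------------------------------------------------

def build_precision_from_graph(g: nx.Graph, coupling: float) -> np.ndarray:
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    prec = np.zeros((n, n))
    for u, v in g.edges:
        prec[index[u], index[v]] = prec[index[v], index[u]] = -coupling
    # diagonal dominance: 1 + attractive row mass guarantees PD
    np.fill_diagonal(prec, 1.0 + np.abs(prec).sum(axis=1))
    return prec


def build_precision(gt: GroundTruth, coupling: float) -> np.ndarray:
    """Precision matrix whose off-diagonal support is exactly the planted edge set.

    Off-diagonal entries are ``-coupling`` on edges; the diagonal is
    inflated by the absolute row sum so the matrix is strictly diagonally
    dominant, hence positive definite.
    """
    if coupling <= 0:
        raise ValueError("coupling must be positive")
    return build_precision_from_graph(gt.graph, coupling)


def sample_gaussian_series(precision: np.ndarray, T: int, noise_sd: float,
                           seed: int) -> np.ndarray:
    """I.i.d. samples from N(0, precision^-1) plus observation noise.

    Returns a node x time matrix.
    """
    precision = np.asarray(precision, dtype=float)
    n = precision.shape[0]
    if T < 1:
        raise ValueError("T must be positive")
    eigmin = np.linalg.eigvalsh(precision).min()
    if eigmin <= 0:
        raise ValueError(f"precision not positive definite (min eigenvalue {eigmin:.3g})")
    if T < 10 * n:
        warnings.warn(f"T={T} is short for {n} nodes; recommend T >= {10 * n}",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    # x = L^-T z with L the Cholesky factor of the precision gives cov = P^-1
    L = np.linalg.cholesky(precision)
    z = rng.standard_normal((n, T))
    x = np.linalg.solve(L.T, z)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal((n, T))
    return x


def sample_var_series(gt: GroundTruth, lag_coefficient: float, T: int,
                      seed: int) -> np.ndarray:
    """Stationary VAR(1) series where each directed edge i->j feeds x_i(t-1) into x_j(t)."""
    if not gt.directed_edges:
        if lag_coefficient != 0:
            raise ValueError("ground truth has no directed edges")
    n = gt.graph.number_of_nodes()
    nodes = sorted(gt.graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for i, j in gt.directed_edges:
        A[index[j], index[i]] = lag_coefficient
    radius = max(np.abs(np.linalg.eigvals(A))) if n else 0.0
    if radius >= 1.0:
        raise ValueError(f"unstable VAR(1): spectral radius {radius:.4f} >= 1")
    rng = np.random.default_rng(seed)
    burn = 200
    x = np.zeros((n, T + burn))
    eps = rng.standard_normal((n, T + burn))
    for t in range(1, T + burn):
        x[:, t] = A @ x[:, t - 1] + eps[:, t]
    return x[:, burn:]


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

def subject_seed(master_seed: int, subject: int, stage: int = 0) -> int:
    """Deterministic per-subject, per-stage sub-seed below 2**31."""
    return int((master_seed * 1_000_003 + subject * 7919 + stage * 104_729) % (2**31 - 1))


def generate_cohort(spec: CohortSpec):
    """Independent subjects sharing the module template; returns
    ``[(panel, ground_truth), ...]`` with ``panel`` a node x time array
    wrapped later by :class:`weaknodes.netinfer.TimeSeriesPanel`."""
    from .netinfer import TimeSeriesPanel  # local import avoids a cycle

    spec.validate()
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for s in range(spec.n_subjects):
        sub = replace(spec, seed=subject_seed(spec.seed, s, 0),
                      template_seed=spec.seed)
        gt = generate_modular_graph(sub)
        series = sample_gaussian_series(gt.precision, spec.n_timepoints,
                                        spec.noise_sd, subject_seed(spec.seed, s, 1))
        panel = TimeSeriesPanel(values=series, node_ids=sorted(gt.graph.nodes),
                                subject_id=f"subject_{s}",
                                modules=dict(gt.network.modules))
        out.append((panel, gt))
    return out
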