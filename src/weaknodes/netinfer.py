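"""From multivariate time series to a sparse modular interaction network.

The construction chain mirrors standard functional-connectivity practice:

1. Pearson correlation between node time series.
2. Threshold + binarize the correlation matrix and maximize modularity on
   the binary graph to detect modules (anatomical-area surrogates).
3. Penalized inverse-covariance estimation (graphical lasso): the network's
   edges are the nonzero off-diagonal entries of the estimated precision
   matrix, i.e. direct pairwise interactions rather than raw correlations.
4. Penalty selection by a percolation criterion: the largest penalty whose
   network still has a single connected component spanning all nodes — the
   sparsest network that keeps the giant component.
5. Optionally orient each undirected link with pairwise Granger tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import greedy_modularity_communities, modularity
from sklearn.covariance import graphical_lasso

from .network import BrainNetwork

__all__ = [
    "TimeSeriesPanel",
    "CorrelationMatrix",
    "Partition",
    "GlassoConfig",
    "GlassoConvergenceError",
    "compute_correlation",
    "detect_modules",
    "infer_interactions",
    "select_penalty",
    "orient_links",
]


class GlassoConvergenceError(RuntimeError):
    def __init__(self, rho: float, max_iter: int, cause: Exception | None = None):
        self.rho = rho
        self.max_iter = max_iter
        super().__init__(f"graphical lasso failed to converge at rho={rho:.6g} "
                         f"within {max_iter} iterations" +
                         (f": {cause}" if cause else ""))


@dataclass
class TimeSeriesPanel:
    """Node x time matrix for one subject, with optional node metadata."""

    values: np.ndarray
    node_ids: list
    subject_id: str = "subject"
    modules: dict = field(default_factory=dict)
    coords: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D node x time matrix")
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length does not match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in time series")
        sd = self.values.std(axis=1)
        constant = [self.node_ids[i] for i in np.flatnonzero(sd == 0)]
        if constant:
            raise ValueError(f"constant (zero-variance) rows for nodes: {constant}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    r: np.ndarray
    node_ids: list

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n) or len(self.node_ids) != n:
            raise ValueError("correlation matrix / node_ids shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")


@dataclass
class Partition:
    """Node -> module mapping plus the modularity of that split."""

    labels: dict
    modularity: float

    def n_modules(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class GlassoConfig:
    """Penalty and numerics for sparse inverse-covariance estimation.

    ``penalty_grid`` is the ordered set of candidate penalties scanned by
    :func:`select_penalty` (log-spaced fractions of the largest off-diagonal
    correlation when left as ``None``); ``n_bisection`` refinement steps
    sharpen the connectivity boundary between the bracketing grid points.
    """

    penalty: float = 0.05
    penalty_grid: np.ndarray | None = None
    grid_size: int = 50
    n_bisection: int = 10
    tol: float = 1e-4
    max_iter: int = 200
    support_floor: float = 1e-8  # relative to max diagonal of the precision

    def grid_for(self, corr: np.ndarray) -> np.ndarray:
        if self.penalty_grid is not None:
            grid = np.asarray(self.penalty_grid, dtype=float)
        else:
            off = np.abs(corr - np.diag(np.diag(corr)))
            hi = float(off.max())
            if hi <= 0:
                hi = 1.0
            grid = np.geomspace(hi * 1e-3, hi * 1.05, self.grid_size)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("penalty grid must be strictly increasing")
        return grid


def compute_correlation(ts: TimeSeriesPanel) -> CorrelationMatrix:
    """Pearson correlation between node time series (symmetric, unit diagonal)."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points")
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, list(ts.node_ids))


def detect_modules(corr: CorrelationMatrix, threshold: float = 0.3) -> Partition:
    """Binarize |r| > threshold and maximize modularity on the binary graph.

    Uses greedy (CNM) modularity maximization, which is deterministic; the
    resulting communities are relabelled 0, 1, ... by their smallest node
    id for reproducibility.  If the binary graph is edgeless every node
    becomes its own module (with a warning).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    n = len(corr.node_ids)
    g = nx.Graph()
    g.add_nodes_from(corr.node_ids)
    absr = np.abs(corr.r)
    for i in range(n):
        for j in range(i + 1, n):
            if absr[i, j] > threshold:
                g.add_edge(corr.node_ids[i], corr.node_ids[j])
    if g.number_of_edges() == 0:
        warnings.warn("threshold leaves an edgeless graph; "
                      "every node is its own module", stacklevel=2)
        return Partition({v: i for i, v in enumerate(sorted(g.nodes))}, 0.0)
    comms = [set(c) for c in greedy_modularity_communities(g)]
    comms.sort(key=lambda c: min(c))
    labels = {v: i for i, c in enumerate(comms) for v in c}
    return Partition(labels, modularity(g, comms))


def _empirical_correlation(ts: TimeSeriesPanel) -> np.ndarray:
    return compute_correlation(ts).r


def _glasso_support(corr: np.ndarray, cfg: GlassoConfig, rho: float) -> np.ndarray:
    """Boolean edge-support matrix of the precision estimated at penalty rho."""
    if rho < 0:
        raise ValueError("penalty must be nonnegative")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec = graphical_lasso(corr, alpha=rho, tol=cfg.tol,
                                      max_iter=cfg.max_iter)
    except FloatingPointError as exc:  # sklearn's non-convergence signal
        raise GlassoConvergenceError(rho, cfg.max_iter, exc) from None
    floor = cfg.support_floor * np.abs(np.diag(prec)).max()
    support = np.abs(prec) > floor
    np.fill_diagonal(support, False)
    return support | support.T


def _network_from_support(support: np.ndarray, node_ids: Sequence,
                          partition: Mapping | None,
                          coords: Mapping | None = None) -> BrainNetwork:
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    idx = np.argwhere(np.triu(support, k=1))
    for i, j in idx:
        g.add_edge(node_ids[i], node_ids[j])
    modules = dict(partition) if partition else {}
    return BrainNetwork(g, modules, dict(coords) if coords else {})


def infer_interactions(ts: TimeSeriesPanel, cfg: GlassoConfig | None = None,
                       partition: Partition | Mapping | None = None) -> BrainNetwork:
    """Sparse interaction network at the config's penalty.

    An edge (i, j) is present iff the estimated precision entry exceeds the
    numerical support floor.  Edges are classified intra/inter from the
    partition labels (detected modules, or the panel's own metadata).
    """
    cfg = cfg or GlassoConfig()
    corr = _empirical_correlation(ts)
    support = _glasso_support(corr, cfg, cfg.penalty)
    labels = partition.labels if isinstance(partition, Partition) else partition
    if labels is None and ts.modules:
        labels = ts.modules
    return _network_from_support(support, ts.node_ids, labels, ts.coords)


def select_penalty(ts: TimeSeriesPanel, cfg: GlassoConfig | None = None,
                   partition: Partition | Mapping | None = None
                   ) -> tuple[float, BrainNetwork]:
    """Largest penalty whose inferred network still spans all nodes.

    Scans the penalty grid from sparse (large rho) to dense, takes the
    largest grid value with a single all-node connected component, then
    bisects between that value and the next (disconnected) grid point to
    sharpen the boundary.  Fails when no grid value yields a connected
    network.
    """
    cfg = cfg or GlassoConfig()
    corr = _empirical_correlation(ts)
    grid = cfg.grid_for(corr)

    def connected_support(rho: float):
        support = _glasso_support(corr, cfg, rho)
        g = nx.from_numpy_array(support.astype(int))
        return nx.is_connected(g), support

    rho_star, support_star = None, None
    upper = None  # smallest penalty known to disconnect, above rho_star
    for rho in grid[::-1]:
        ok, support = connected_support(rho)
        if ok:
            rho_star, support_star = float(rho), support
            break
        upper = float(rho)
    if rho_star is None:
        raise RuntimeError("no spanning component in grid: every penalty in the "
                           "grid yields a disconnected network")
    if upper is None:
        warnings.warn("largest grid penalty still yields a connected network; "
                      "grid may not reach full sparsification", stacklevel=2)
    else:
        lo, hi = rho_star, upper
        for _ in range(cfg.n_bisection):
            mid = 0.5 * (lo + hi)
            ok, support = connected_support(mid)
            if ok:
                lo, support_star = mid, support
            else:
                hi = mid
        rho_star = lo
    labels = partition.labels if isinstance(partition, Partition) else partition
    if labels is None and ts.modules:
        labels = ts.modules
    net = _network_from_support(support_star, ts.node_ids, labels, ts.coords)
    return rho_star, net


def orient_links(net: BrainNetwork, ts: TimeSeriesPanel, max_lag: int = 1,
                 alpha: float = 0.05) -> BrainNetwork:
    """Orient each undirected link with bivariate Granger tests.

    For every edge (i, j) both directions are tested at lag ``max_lag``
    (F-test on the residual sum of squares).  Arcs with p < alpha are kept;
    if neither direction is significant the link is retained symmetrically
    (direction undetermined), so the directed wiring can differ from the
    undirected one.
    """
    from statsmodels.tsa.stattools import grangercausalitytests

    if net.is_directed:
        raise ValueError("orient_links expects an undirected network")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if ts.n_timepoints < 3 * max_lag + 3:
        raise ValueError(f"series too short (T={ts.n_timepoints}) for lag {max_lag}")
    index = {v: i for i, v in enumerate(ts.node_ids)}
    missing = [v for v in net.graph.nodes if v not in index]
    if missing:
        raise ValueError(f"panel lacks series for nodes: {missing[:10]}")

    def p_value(src, dst) -> float:
        data = np.column_stack([ts.values[index[dst]], ts.values[index[src]]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = grangercausalitytests(data, maxlag=[max_lag], verbose=False)
        return float(res[max_lag][0]["ssr_ftest"][1])

    dg = nx.DiGraph()
    dg.add_nodes_from(net.graph.nodes)
    failures = []
    for u, v in sorted(net.graph.edges):
        try:
            p_uv, p_vu = p_value(u, v), p_value(v, u)
        except Exception as exc:  # pragma: no cover - per-edge numerical failure
            failures.append((u, v, str(exc)))
            continue
        if p_uv < alpha:
            dg.add_edge(u, v, p=p_uv)
        if p_vu < alpha:
            dg.add_edge(v, u, p=p_vu)
        if p_uv >= alpha and p_vu >= alpha:
            dg.add_edge(u, v, p=p_uv)
            dg.add_edge(v, u, p=p_vu)
    if failures:
        raise RuntimeError(f"Granger tests failed on {len(failures)} edges: "
                           f"{failures[:3]}")
    return BrainNetwork(dg, dict(net.modules), dict(net.coords))
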