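"""Plain-text readers and writers for the pipeline's artifacts.

Dialects: time series as TSV (rows = nodes, columns = time points, first
column the node id), node metadata as CSV (node_id, module, x, y, z),
networks as two-column edge lists (three columns with a direction flag for
directed graphs) or GraphML, rankings/curves/maps/compositions as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import Ranking
from .influence import InfluenceMap
from .netinfer import Partition, TimeSeriesPanel
from .network import BrainNetwork
from .percolation import PercolationCurve

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_metadata", "read_metadata",
    "write_edgelist", "read_edgelist", "write_graphml",
    "write_ranking", "write_curve", "write_partition", "write_map",
    "write_json",
]


def write_timeseries(path, panel: TimeSeriesPanel) -> None:
    df = pd.DataFrame(panel.values, index=panel.node_ids)
    df.index.name = "node_id"
    df.to_csv(path, sep="\t")


def read_timeseries(path, subject_id: str | None = None,
                    metadata: pd.DataFrame | None = None) -> TimeSeriesPanel:
    df = pd.read_csv(path, sep="\t", index_col="node_id")
    modules, coords = {}, {}
    if metadata is not None:
        meta = metadata.set_index("node_id") if "node_id" in metadata.columns else metadata
        for node in df.index:
            if node in meta.index:
                row = meta.loc[node]
                if "module" in meta.columns and not pd.isna(row["module"]):
                    modules[node] = row["module"]
                if {"x", "y", "z"} <= set(meta.columns):
                    coords[node] = (row["x"], row["y"], row["z"])
    return TimeSeriesPanel(df.to_numpy(), list(df.index),
                           subject_id or Path(path).stem, modules, coords)


def write_metadata(path, net: BrainNetwork) -> None:
    rows = []
    for v in net.node_ids:
        xyz = net.coords.get(v, (np.nan, np.nan, np.nan))
        rows.append({"node_id": v, "module": net.modules.get(v),
                     "x": xyz[0], "y": xyz[1], "z": xyz[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_edgelist(path, net: BrainNetwork) -> None:
    with open(path, "w") as fh:
        if net.is_directed:
            fh.write("source\ttarget\tdirected\n")
            for u, v in sorted(net.graph.edges):
                fh.write(f"{u}\t{v}\t1\n")
        else:
            fh.write("source\ttarget\n")
            for u, v in sorted(net.graph.edges):
                fh.write(f"{u}\t{v}\n")


def read_edgelist(path, modules: Mapping | None = None) -> BrainNetwork:
    df = pd.read_csv(path, sep="\t")
    directed = "directed" in df.columns and df["directed"].any()
    g = nx.DiGraph() if directed else nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["source"], row["target"])
    return BrainNetwork(g, dict(modules) if modules else {})


def write_graphml(path, net: BrainNetwork) -> None:
    g = net.graph.copy()
    for v in g.nodes:
        if v in net.modules and net.modules[v] is not None:
            g.nodes[v]["module"] = str(net.modules[v])
    nx.write_graphml(g, path)


def write_partition(path, partition: Partition) -> None:
    rows = [{"node_id": v, "module": m} for v, m in sorted(partition.labels.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ranking(path, ranking: Ranking) -> None:
    rows = [{"rank": i + 1, "node_id": v, "score": ranking.scores[v],
             "centrality": ranking.centrality_name, "ell": ranking.ell,
             "adaptive": ranking.adaptive}
            for i, v in enumerate(ranking.order)]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve(path, curve: PercolationCurve) -> None:
    removed = [None] + list(curve.removal_order)
    mods = [None] + list(curve.removal_modules)
    pd.DataFrame({"q": curve.q, "g_rel": curve.g_rel,
                  "removed_node": removed, "module": mods}).to_csv(path, index=False)


def write_map(path, imap: InfluenceMap) -> None:
    rows = [{"location": k, "score": imap.scores[k],
             "n_subjects": imap.n_subjects[k], "centrality": imap.centrality_name}
            for k in sorted(imap.scores, key=str)]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path, payload) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
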