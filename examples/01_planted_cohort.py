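"""Generate a planted evoked cohort and look at its ground truth.

Builds the default three-module network (40-node stimulated and third
modules, a 15-node low-degree bridge module, five planted bridge nodes of
degree <= 3 carrying all traffic between the outer modules) and prints the
structural facts every later stage relies on.
"""

import networkx as nx

from weaknodes import CohortSpec, generate_modular_graph

spec = CohortSpec(seed=1)
gt = generate_modular_graph(spec)
g, modules = gt.graph, gt.network.modules

print(f"nodes: {g.number_of_nodes()}, edges: {g.number_of_edges()}, "
      f"connected: {nx.is_connected(g)}")
print(f"module sizes: {gt.network.module_sizes()}")
print(f"planted bridges: {sorted(gt.planted_bridges)} "
      f"(degrees {[g.degree(b) for b in sorted(gt.planted_bridges)]})")

h = g.copy()
h.remove_nodes_from(gt.planted_bridges)
sizes = sorted((len(c) for c in nx.connected_components(h)), reverse=True)
print(f"component sizes after deleting the bridges: {sizes[:4]}")
# The giant component collapses from one spanning component to fragments:
# the low-degree bridges, not the hubs, hold the network together.
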