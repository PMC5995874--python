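# Methods

This note documents the models implemented in `weaknodes`, the default
parameters and why they were chosen, the numerics, and what the synthetic
cohorts do and do not establish about real data.

## Network inference

**Correlation and modules.** Functional connectivity is the Pearson
correlation matrix of the node time series.  For module detection the
matrix is binarized at `|r| > threshold` (magnitude, so anticorrelations
count as coupling) and greedy (CNM) modularity maximization is run on the
binary graph; communities are relabelled by smallest member id so the
partition is deterministic.  The default threshold is 0.3; for weakly
coupled data (marginal correlations of order 0.1, as in the sparse
synthetic condition below) a threshold around 0.08–0.1 is appropriate,
and the parameter is exposed everywhere.  When the binary graph is
edgeless every node becomes its own module, with a warning.

**Sparse interaction networks.** Direct interactions are estimated with
the graphical lasso on the empirical correlation matrix: an edge (i, j)
exists iff the estimated precision entry exceeds a numerical support
floor of `1e-8 × max diagonal`.  Working on the correlation (rather than
covariance) scale makes a single penalty grid meaningful across datasets.
Convergence failures carry the penalty and iteration budget in the error.

**Penalty selection by percolation.** The penalty ρ* is the largest value
whose inferred network has a single connected component containing all
nodes — the sparsest network that still integrates every node.  The
implementation scans a log-spaced grid (default 50 points from 1e-3 to
1.05 times the largest off-diagonal correlation; tests and the
acceptance script use 30 points, which changes ρ* only within the
bisection tolerance) from sparse to dense, then refines the boundary with
10 bisection steps between the last connected and first disconnected
penalties.  If no grid point yields a spanning component the stage fails
explicitly ("no spanning component in grid").

A consequence worth stating plainly: this criterion optimizes
*integration*, not reconstruction.  On redundant (loopy) planted graphs
the sparsest connected network drops redundant true edges (we measure
recall ≈ 0.65 at intra-module density 0.2 with perfect precision), while
on sparse planted graphs it essentially coincides with the truth
(edge-F1 ≥ 0.95 at density 0.08, T = 50 n, coupling 0.3).  Edge-recovery
claims are therefore made in the sparse regime.

**Granger orientation.** Each undirected link is tested in both
directions with bivariate Granger F-tests at lag `max_lag` (default 1).
Arcs with p < α are kept; if neither direction is significant the link is
retained symmetrically, so no connectivity is silently lost.  Tests are
per-edge without multiple-testing correction; with the default α = 0.05
roughly 10% of null links will receive some spurious direction
(1 − 0.95²), so directional claims should use α = 0.01, where the
measured false-direction rate is ≤ 5% over 200 white-noise replicates.

## Centralities

Collective Influence at sphere radius ℓ:
`CI_ℓ(i) = (k_i − 1) Σ_{j ∈ ∂Ball(i,ℓ)} (k_j − 1)`, with ∂Ball the set of
nodes at shortest-path distance exactly ℓ.  ℓ = 0 returns the degree (the
hub limit); nodes with k ≤ 1 score 0 for ℓ ≥ 1.  The default ℓ = 2 suits
networks of ~100 nodes whose module diameters are small; ℓ is exposed and
should stay below the network diameter.  The adaptive ranking is greedy
decimation (remove the current top-CI node, rescore the survivors), the
standard optimal-percolation heuristic.  When every remaining CI score is
zero but edges remain — small fragments have empty radius-ℓ shells — the
decimation continues by current degree, which is exactly the ℓ = 0 limit
of CI; fully isolated nodes are appended by id.  All ties break by node
id, ascending, so every ranking is reproducible.

The directed variant uses out-degree at the root and in-degrees on the
outgoing-arc frontier, `(k_i^out − 1) Σ (k_j^in − 1)`; on a symmetrized
digraph it reproduces the undirected ordering exactly.

Degree, k-core, eigenvector, closeness and betweenness delegate to
networkx (eigenvector via power iteration with a dense fallback when it
stalls, computed on the largest component; closeness per component with
the plain `(n_c − 1)/Σd` convention; betweenness exact and unnormalized).
All five are cross-checked against hand-written brute-force oracles in
the test suite.

## Percolation

Attack curves remove nodes one by one on the native grid q = 0, 1/N, …, 1
and record G(q)/G(0), with the removed node's module label kept for
composition-colored plots.  Directed networks use weak connectivity for G
(integration is about reachability through links, not direction); a
strong-component reading can be obtained by passing the condensed graph.
The dismantling fraction q_c is the smallest grid q with
G(q)/G(0) ≤ target (default 0.05).

In the centrality comparison the CI strategy is adaptive decimation while
the degree strategy is, by default, the *static* hub list — the ranking
frozen before the attack, nodes removed from high to low degree.  This is
the natural reading of a hub-inactivation experiment (the hub map is
fixed before intervening); a fully adaptive degree variant is available
behind `adaptive_degree=True`.  On planted two-module cohorts (density
0.1, 5 bridges) adaptive CI reaches the 5% target with a strictly smaller
removed fraction than the static hub list in 20 of 20 seeds.

Greedy CI dismantling is near-optimal at small scale: on 50 random
connected graphs of ≤ 12 nodes its dismantling set for G/G0 < 0.5 is
within 2 nodes of the exhaustive-search minimum.

## Synthetic cohorts

The generator emulates the structure of an evoked, modular functional
network in which low-degree bridge nodes — not hubs — are the essential
integrators:

- three modules, default sizes (40, 15, 40): a "stimulated" module, a
  low-degree "bridge" module, and a "third" module;
- intra-links: a random attachment-tree backbone per module (guaranteeing
  connectivity at any density; degree-capped in the bridge module) filled
  with uniform extra edges up to `intra_density`;
- planted bridges: `n_bridge_nodes` (default 5) members of the bridge
  module, stripped to at most `bridge_degree_cap` (default 3) links: one
  into the bridge-module tree and one each to the stimulated and third
  modules, attached next to a degree-weighted hub so the bridge's
  radius-2 sphere contains high-degree nodes.  *Every* path between the
  outer modules crosses a planted bridge — they are ground-truth cut
  nodes;
- the bridge identities are drawn from a cohort-level template seed, so
  subjects share the "anatomical location" of the weak nodes while intra
  edges vary independently;
- the default `intra_density` is 1.0: the outer modules are densely knit
  clumps.  This is the regime in which the weak-tie phenomenon is
  geometrically sharp — inside a clique every node is within distance
  two of every other, so internal radius-2 spheres are degree-poor, while
  a bridge's sphere contains both 40-node interiors.  At sparse densities
  (≈ 0.1 and below) hubs and bridges trade places gradually and the
  dismantling comparison becomes the informative contrast; both regimes
  are exercised in the tests.

The matched Gaussian model sets the precision matrix to −coupling on
planted edges with the diagonal inflated by the absolute row sum
(strict diagonal dominance ⇒ positive definite; an attractive Gaussian
graphical model).  Note the implied partial correlations shrink as
1/(1 + coupling·k), so dense modules are intrinsically harder to recover
from data — another reason recovery claims live in the sparse regime.
Series are i.i.d. draws from N(0, P⁻¹) via Cholesky plus observation
noise (default sd 0.1); the recommended length is T = 50 n (warning below
10 n).  The VAR(1) regime assigns each planted edge a random direction
and propagates `lag_coefficient · x_i(t−1)` into x_j(t), refusing
coefficients whose companion spectral radius reaches 1, with a 200-step
burn-in.

The resting regime keeps the intra structure but removes the bridges'
privileged role: inter-links are placed with per-module-pair counts
solved so every node is equally likely to host one (naive pair-uniform
placement would overrepresent the small module, whose nodes have more
cross-module partners), making the module size share the correct null
for top-CI composition.

**What passing tests show — and don't.**  The synthetic cohorts establish
that the implementation faithfully computes the intended quantities and
that the qualitative phenomena (weak-node dominance of CI, dismantling
efficiency, resting delocalization) follow from the planted structure.
They do not model hemodynamics, spatial smoothing, scanner noise,
non-stationarity, or atlas registration, so they say nothing about
whether a particular real dataset is in the weak-node regime; that is an
empirical question for the inference stage on that data.

## Pipeline

`run_full` chains generation (or TSV/CSV loading), correlation, module
detection, penalty selection, the six rankings, attack curves, the q_c
comparison table, cohort influence maps (mean normalized rank
`(N − rank + 1)/N` per node id, or per rounded coordinate for real data)
and module-composition tables, writing every artifact as plain text with
all seeds and parameters in `report.json`; reruns are byte-identical.
`rank_on="planted"` ranks the ground-truth graphs instead of the inferred
ones — useful at small scale, where inference noise dominates the tiny
networks, and for separating ranking behaviour from inference behaviour.
Cohort-level claims in the tests use graph-level cohorts of 20 seeds and
networks of 85–95 nodes; pipeline-level end-to-end runs are exercised at
17–21 nodes, sizes chosen so the full suite stays fast while every code
path is covered.

## Known limitations

- Greedy CI has no reinsertion refinement; its dismantling sets are
  near-optimal, not optimal.
- The percolation penalty criterion under-recovers redundant edges by
  design (see above).
- Bivariate Granger orientation ignores conditioning on the rest of the
  network and multiple testing; it orients links, it does not discover
  them.
- Eigenvector centrality on disconnected networks is reported for the
  largest component only (scores elsewhere are 0), mirroring the
  localization of the leading eigenvector.
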