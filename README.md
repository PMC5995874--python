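# weaknodes

Find the nodes that hold a functional brain network together — which are
often *not* the hubs.

`weaknodes` is a Python library for identifying essential "integrator"
nodes in functional networks inferred from multivariate time series (for
example evoked fMRI activity across brain areas).  It implements the full
chain: sparse network inference from time series, node ranking by
Collective Influence and five classical centralities, simulated targeted
inactivation of ranked nodes with giant-component tracking, and
aggregation of per-subject rankings into cohort influence maps.  A
synthetic-cohort generator with planted ground truth makes every stage
testable end to end.

## The science in one paragraph

Global integration of a modular network is measured by its giant connected
component *G* — the largest set of nodes joined by paths.  The essential
integrators are the minimal node set whose inactivation destroys *G*
(optimal percolation, NP-hard, approximated greedily).  Collective
Influence scores a node by its degree *and* the degrees on the frontier of
its distance-ℓ sphere of influence,

    CI_ℓ(i) = (k_i − 1) · Σ_{j ∈ ∂Ball(i, ℓ)} (k_j − 1),

where ∂Ball(i, ℓ) is the set of nodes at shortest-path distance exactly ℓ
from *i*; at ℓ = 0 it reduces to degree.  In modular networks — densely
knit clumps joined by a few weak ties — low-degree nodes bridging the
modules can carry the highest CI, because their spheres of influence
contain the dense interiors of *both* modules, while a hub's sphere ends
in its own module.  Inactivating a few such "weak nodes" disintegrates the
network; inactivating hubs barely dents it.  Hub-style centralities
(degree, k-core, eigenvector) find the hubs; integrative centralities (CI,
betweenness) find the weak nodes.

The interaction networks themselves are estimated with the graphical
lasso (sparse inverse covariance: edges are direct pairwise interactions,
not raw correlations), with the penalty chosen by a percolation
criterion: the largest penalty whose network still keeps all nodes in one
connected component — the sparsest integrated network.  Links can
optionally be oriented by pairwise Granger causality.

## Worked example

Generate the default evoked cohort condition — two dense 40-node modules
("stimulated" and "third") and a 15-node low-degree bridge module, with
five planted bridge nodes of degree ≤ 3 carrying all traffic between the
outer modules — then rank and attack it (`examples/03_rank_and_attack.py`):

```text
top 5 by adaptive CI:     [(40, 'bridge'), (45, 'bridge'), (46, 'bridge'), (49, 'bridge'), (53, 'bridge')]
top 5 by degree:          [(1, 'stimulated'), (16, 'stimulated'), (19, 'stimulated'), (21, 'stimulated'), (31, 'stimulated')]
top-7% CI composition:    {'bridge': 0.714, 'stimulated': 0.143, 'third': 0.143}
G/G0 after top 3% CI removals: 0.968
G/G0 after top 7% CI removals: 0.411
```

Adaptive CI puts the five planted degree-3 bridges at ranks 1–5 even
though degree ranks them near the bottom; removing the top 7% of CI nodes
(which includes all bridges) collapses the giant component to 41% — the
two modules separate — while the degree hub list needs most of the
network removed to do equivalent damage.  `examples/` contains one short
script per capability (cohort generation, network inference, ranking and
attack, influence maps, Granger orientation); each prints what it
computes and what the numbers mean.

The same pipeline is scriptable from the shell:

```bash
weaknodes simulate --seed 1 --out run/sim --n-subjects 6
weaknodes full --seed 1 --out run/full
weaknodes resting-contrast --seed 1 --out run/contrast
```

## Layout

- `src/weaknodes/synthgen.py` — planted modular cohorts, precision
  matrices, Gaussian and VAR(1) sampling
- `src/weaknodes/netinfer.py` — correlation, community detection,
  graphical lasso, percolation penalty selection, Granger orientation
- `src/weaknodes/centrality.py` — CI (undirected/directed, static and
  adaptive decimation) and the five comparison centralities
- `src/weaknodes/percolation.py` — attack curves, dismantling fractions,
  centrality comparison
- `src/weaknodes/influence.py` — normalized ranks, cohort influence maps,
  module-composition tables
- `src/weaknodes/pipeline.py`, `cli.py` — end-to-end orchestration and the
  `weaknodes` command
- `docs/methods.md` — models, parameter choices, numerics, limitations
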