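"""Cross-subject influence maps and the evoked-versus-resting contrast.

Ranks every subject of a cohort, averages normalized ranks into a
per-node influence map, and contrasts the bridge-module share of top-CI
locations between the evoked regime (inter-links routed through planted
bridges) and the resting regime (inter-links placed uniformly).
"""

import dataclasses

from weaknodes import (CohortSpec, average_map, ci_ranking, generate_cohort,
                       module_composition)

spec = CohortSpec(n_subjects=6, T=400, seed=1)

for regime in ("evoked", "resting"):
    cohort = generate_cohort(dataclasses.replace(spec, regime=regime))
    rankings = [ci_ranking(gt.network, ell=2, adaptive=True)
                for _, gt in cohort]
    imap = average_map(rankings)
    modules = cohort[0][1].network.modules
    comp = module_composition(imap, modules, top_fraction=0.07)
    print(f"{regime:>8}: top-7% CI map composition = "
          f"{ {k: round(v, 3) for k, v in comp.items()} }")
print("bridge-module size share =", round(15 / 95, 3))
# Evoked: the averaged map concentrates on the bridge module.  Resting:
# high-CI locations scatter close to the size share of each module.
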