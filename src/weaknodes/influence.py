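"""Cross-subject influence maps and module-composition summaries.

Each subject's ranking is converted to a normalized rank score
``(N - rank + 1) / N`` (top node 1, bottom node 1/N) and averaged across
subjects at registered locations — node ids in the shared synthetic space,
or coordinates rounded to a common grid for real data.  Composition tables
report how the top-ranked locations distribute over modules, the summary
behind statements like "most top-CI nodes sit in the bridge module".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .centrality import Ranking

__all__ = [
    "InfluenceMap",
    "normalized_rank",
    "average_map",
    "module_composition",
]


@dataclass
class InfluenceMap:
    """Per-location average normalized rank (1 = most influential)."""

    scores: dict
    n_subjects: dict
    centrality_name: str

    def __post_init__(self) -> None:
        for k, s in self.scores.items():
            if not 0.0 <= s <= 1.0 + 1e-12:
                raise ValueError(f"score out of [0,1] at {k!r}: {s}")
        if any(self.n_subjects.get(k, 0) < 1 for k in self.scores):
            raise ValueError("every location needs at least one contributing subject")

    def top(self, k: int) -> list:
        return sorted(self.scores, key=lambda v: (-self.scores[v], str(v)))[:k]


def normalized_rank(ranking: Ranking) -> dict:
    """score(i) = (N - rank(i) + 1) / N, linear in rank."""
    n = len(ranking)
    if n == 0:
        raise ValueError("empty ranking")
    return {v: (n - r) / n for r, v in enumerate(ranking.order)}


def _round_coord(coord: Sequence[float], grid: float = 1.0) -> tuple:
    return tuple(round(c / grid) * grid for c in coord)


def average_map(rankings: Sequence[Ranking], registration: str = "node-id",
                coords: Mapping | None = None, grid: float = 1.0) -> InfluenceMap:
    """Mean normalized rank per location over the subjects possessing it.

    ``registration="node-id"`` keys locations by node id (shared synthetic
    space); ``"coordinate"`` keys by the node coordinate rounded to a
    common ``grid`` (nearest-voxel registration for real space).
    """
    if not rankings:
        raise ValueError("need at least one subject ranking")
    if registration not in ("node-id", "coordinate"):
        raise ValueError(f"unknown registration {registration!r}")
    if registration == "coordinate" and coords is None:
        raise ValueError("coordinate registration requires a coords mapping")
    totals: dict = {}
    counts: dict = {}
    for ranking in rankings:
        for node, score in normalized_rank(ranking).items():
            key = node if registration == "node-id" else _round_coord(coords[node], grid)
            totals[key] = totals.get(key, 0.0) + score
            counts[key] = counts.get(key, 0) + 1
    if not totals:
        raise ValueError("no registered locations")
    name = rankings[0].centrality_name
    return InfluenceMap({k: totals[k] / counts[k] for k in totals}, counts, name)


def module_composition(ranked, partition: Mapping, top_fraction: float = 0.07) -> dict:
    """Share of each module among the top-ranked locations.

    ``ranked`` may be a :class:`Ranking` or an :class:`InfluenceMap`; the
    top ``ceil(top_fraction * N)`` locations are tallied by module label
    and the proportions sum to one.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    if isinstance(ranked, Ranking):
        order = ranked.order
    elif isinstance(ranked, InfluenceMap):
        order = ranked.top(len(ranked.scores))
    else:
        raise TypeError("ranked must be a Ranking or InfluenceMap")
    k = math.ceil(top_fraction * len(order))
    top = order[:k]
    counts: dict = {}
    for v in top:
        lab = partition.get(v) if hasattr(partition, "get") else partition[v]
        counts[lab] = counts.get(lab, 0) + 1
    return {lab: c / k for lab, c in counts.items()}
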