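"""Degree ranking of differential sub-network vertices.

The candidate biomarkers are the hubs: vertices of the differential
sub-network whose correlations with many other ratios changed. Vertices are
ranked by degree in descending order (ties broken lexicographically by name
for determinism) and the top k are selected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ParameterError

TIE_ORDER = "lexicographic"


@dataclass
class HubRanking:
    """Ordered (vertex, degree) pairs, non-increasing in degree."""

    entries: list[tuple[str, int]]
    tie_order: str = TIE_ORDER

    @property
    def vertices(self) -> list[str]:
        return [v for v, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def rank_by_degree(net) -> HubRanking:
    """Rank the vertices of a (sub-)network by degree, descending.

    Accepts a differential sub-network, a projection or a plain signed
    network — anything with ``edges`` keyed by vertex pairs and a vertex
    set. An empty edge set yields an empty ranking with a warning.
    """
    universe = getattr(net, "vertex_set", None)
    if universe is None:
        universe = net.vertices
    if not net.edges:
        warnings.warn("ranking an empty sub-network", stacklevel=2)
        return HubRanking(entries=[])
    deg: dict[str, int] = {v: 0 for v in universe}
    for u, v in net.edges:
        deg[u] += 1
        deg[v] += 1
    entries = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    return HubRanking(entries=entries)


def top_k(ranking: HubRanking, k: int) -> list[str]:
    """First min(k, len) vertices of the ranking."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    return ranking.vertices[:k]
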