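"""Differential sub-network extraction.

An edge of the target label's network is *differential* when it behaves
differently — disappears, or changes sign — in at least a required number
of the comparison networks. In the static setting the comparisons are all
other groups' networks; in the time-series setting only the networks of
earlier time points are compared, so the resulting sub-network is a
prospective signal for the onset of the target time point's stage.

"Most" of the comparison networks is operationalized as
``required_count = ceil(fraction * n_comparisons)`` with a default fraction
of 2/3: with four groups an edge must differ in 2 of the 3 other networks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ParameterError
from .network import Edge, EdgeKey, SignedNetwork

DEFAULT_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class DifferentialSubNetwork:
    """Differential edges of a target network plus bookkeeping.

    ``edges`` is a subset of the target network's signed edges (same sign
    and correlation); ``vertex_set`` contains only the endpoints of those
    edges; ``per_edge_difference_count`` records in how many comparison
    networks each retained edge behaved differently.
    """

    target_label: str | None
    tau: float | None
    edges: dict[EdgeKey, Edge]
    vertex_set: frozenset[str]
    comparison_labels: tuple[str, ...]
    fraction: float
    required_count: int
    per_edge_difference_count: dict[EdgeKey, int]

    @property
    def vertices(self) -> frozenset[str]:
        return self.vertex_set

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: str) -> int:
        if v not in self.vertex_set:
            raise ParameterError(f"unknown vertex {v!r}")
        return sum(1 for k in self.edges if v in k)


@dataclass(frozen=True)
class ProjectedSubNetwork:
    """A differential sub-network seen through another label's network.

    The vertex set is copied unchanged from the base sub-network; the edge
    set is the intersection of the base's edges with the other network's
    edges, and each edge carries the *other* network's sign and correlation.
    """

    base_label: str | None
    other_label: str | None
    tau: float | None
    edges: dict[EdgeKey, Edge]
    vertex_set: frozenset[str]

    @property
    def vertices(self) -> frozenset[str]:
        return self.vertex_set

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: str) -> int:
        if v not in self.vertex_set:
            raise ParameterError(f"unknown vertex {v!r}")
        return sum(1 for k in self.edges if v in k)


def required_count(fraction: float, n_comparisons: int) -> int:
    """ceil(fraction * n_comparisons), robust to the floating-point
    representation of fractions like 2/3 (so 2/3 of 3 is exactly 2)."""
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    if n_comparisons < 1:
        raise ParameterError("need at least one comparison network")
    return math.ceil(fraction * n_comparisons - 1e-9)


def edge_behavior_differs(key: EdgeKey, sign: int, other: SignedNetwork) -> bool:
    """True iff the edge is absent from ``other`` or present with the
    opposite sign ("disappears or has a different color")."""
    other_sign = other.sign_of(*key)
    return other_sign != sign


def _extract(
    target: SignedNetwork,
    comparisons: Sequence[SignedNetwork],
    fraction: float,
) -> tuple[dict[EdgeKey, Edge], dict[EdgeKey, int], int]:
    need = required_count(fraction, len(comparisons))
    kept: dict[EdgeKey, Edge] = {}
    counts: dict[EdgeKey, int] = {}
    for key in sorted(target.edges):
        e = target.edges[key]
        n_diff = sum(1 for net in comparisons if edge_behavior_differs(key, e.sign, net))
        if n_diff >= need:
            kept[key] = e
            counts[key] = n_diff
    return kept, counts, need


def differential_subnetwork_static(
    networks: Mapping[str, SignedNetwork] | Sequence[SignedNetwork],
    target_label: str,
    fraction: float = DEFAULT_FRACTION,
) -> DifferentialSubNetwork:
    """Differential sub-network of one group against all other groups.

    ``networks`` maps labels to signed networks (or is a sequence of
    labeled networks) sharing one vertex universe and tau. An edge of the
    target network is retained iff it behaves differently in at least
    ``ceil(fraction * n_other)`` of the other networks.
    """
    if not isinstance(networks, Mapping):
        networks = {n.label: n for n in networks}
    if target_label not in networks:
        raise ParameterError(f"target label {target_label!r} not among networks")
    if len(networks) < 2:
        raise ParameterError("need at least two networks")
    target = networks[target_label]
    comparisons = [networks[l] for l in networks if l != target_label]
    kept, counts, need = _extract(target, comparisons, fraction)
    verts = frozenset(v for k in kept for v in k)
    return DifferentialSubNetwork(
        target_label=target_label,
        tau=target.tau,
        edges=kept,
        vertex_set=verts,
        comparison_labels=tuple(n.label for n in comparisons),
        fraction=fraction,
        required_count=need,
        per_edge_difference_count=counts,
    )


def differential_subnetwork_timeseries(
    networks: Sequence[SignedNetwork],
    target_index: int,
    fraction: float = DEFAULT_FRACTION,
) -> DifferentialSubNetwork:
    """Differential (signal) sub-network of one time point against all
    *earlier* time points.

    ``networks`` is ordered by time; ``target_index`` is the 0-based
    position of the target time point and must have at least one earlier
    network. Retention requires different behavior in at least
    ``ceil(fraction * target_index)`` of the earlier networks.
    """
    if not 0 <= target_index < len(networks):
        raise ParameterError(f"target_index {target_index} out of range")
    if target_index == 0:
        raise ParameterError("the first time point has no earlier networks to compare")
    target = networks[target_index]
    comparisons = list(networks[:target_index])
    kept, counts, need = _extract(target, comparisons, fraction)
    verts = frozenset(v for k in kept for v in k)
    return DifferentialSubNetwork(
        target_label=target.label,
        tau=target.tau,
        edges=kept,
        vertex_set=verts,
        comparison_labels=tuple(n.label for n in comparisons),
        fraction=fraction,
        required_count=need,
        per_edge_difference_count=counts,
    )


def project_subnetwork(
    dsn: DifferentialSubNetwork, other: SignedNetwork
) -> ProjectedSubNetwork:
    """Intersect a differential sub-network with another label's network.

    Edges present in both keep the *other* network's sign and correlation;
    the vertex set is the differential sub-network's, unchanged.
    """
    edges = {k: other.edges[k] for k in dsn.edges if k in other.edges}
    return ProjectedSubNetwork(
        base_label=dsn.target_label,
        other_label=other.label,
        tau=other.tau,
        edges=edges,
        vertex_set=dsn.vertex_set,
    )


def star_subnetwork(net, center: str) -> SignedNetwork:
    """The star around ``center``: its incident edges with their signs.

    Works on signed networks, differential sub-networks and projections
    alike; the result has ``degree(center)`` edges and contains the center
    plus its neighbors.
    """
    universe = net.vertices if isinstance(net, SignedNetwork) else net.vertex_set
    if center not in universe:
        raise ParameterError(f"unknown vertex {center!r}")
    edges = {k: e for k, e in net.edges.items() if center in k}
    verts = {center}
    for k in edges:
        verts.update(k)
    label = (
        getattr(net, "label", None)
        or getattr(net, "target_label", None)
        or getattr(net, "base_label", None)
    )
    return SignedNetwork(
        label=label, tau=net.tau, vertices=frozenset(verts), edges=edges
    )
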