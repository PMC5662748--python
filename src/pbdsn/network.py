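"""Signed Pearson-correlation networks per group or time point.

One network is built for each label: vertices are the ratio columns (or the
features themselves in molecular-network mode) and an edge joins two
vertices whenever the Pearson correlation of their values over that label's
samples reaches the threshold tau in magnitude. Edges carry a sign: +1
("red") for PCC >= tau, -1 ("green") for PCC <= -tau. The default tau is
0.7.

The correlation is the standard sample statistic

    PCC(x, y) = 1/(n-1) * sum_k ((x_k - mu_x)/s_x) * ((y_k - mu_y)/s_y)

with the (n-1)-denominator standard deviations, requiring n >= 3 samples.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import networkx as nx
import numpy as np

from .errors import InputError, ParameterError, ZeroVarianceError

DEFAULT_TAU = 0.7


class Edge(NamedTuple):
    sign: int  # +1 (red) or -1 (green)
    pcc: float


EdgeKey = tuple[str, str]


def _key(u: str, v: str) -> EdgeKey:
    if u == v:
        raise ParameterError(f"self-loop on {u!r}")
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class SignedNetwork:
    """Per-label signed correlation graph over a shared vertex universe.

    ``vertices`` contains every column of the source matrix, so degree-0
    vertices exist; ``edges`` maps lexicographically ordered vertex pairs to
    their sign and realized correlation.
    """

    label: str | None
    tau: float | None
    vertices: frozenset[str]
    edges: dict[EdgeKey, Edge]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return _key(u, v) in self.edges

    def edge(self, u: str, v: str) -> Edge:
        return self.edges[_key(u, v)]

    def sign_of(self, u: str, v: str) -> int:
        """Edge sign, or 0 when the pair is not connected."""
        e = self.edges.get(_key(u, v))
        return 0 if e is None else e.sign

    def degree(self, v: str) -> int:
        if v not in self.vertices:
            raise ParameterError(f"unknown vertex {v!r}")
        return sum(1 for k in self.edges if v in k)

    def incident_edges(self, v: str) -> Iterator[tuple[EdgeKey, Edge]]:
        for k, e in self.edges.items():
            if v in k:
                yield k, e

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.vertices))
        for (u, v), e in sorted(self.edges.items()):
            g.add_edge(u, v, sign=e.sign, pcc=e.pcc)
        return g


def pearson(x, y) -> float:
    """Sample Pearson correlation with the (n-1)-denominator convention.

    Requires equal lengths n >= 3 and nonzero variance in both inputs;
    the result is clamped to [-1, 1] against floating-point overshoot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-d sequences of equal length")
    n = x.size
    if n < 3:
        raise ParameterError(f"need at least 3 observations, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("zero variance: correlation undefined")
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    r = float(np.dot(zx, zy) / (n - 1))
    return max(-1.0, min(1.0, r))


def build_network(matrix, label: str, tau: float = DEFAULT_TAU) -> SignedNetwork:
    """Build the signed correlation network of one label.

    ``matrix`` is any object exposing ``values`` (samples x columns
    DataFrame) and ``sample_labels`` — a :class:`~pbdsn.ratios.RatioMatrix`
    for ratio networks or an imputed :class:`~pbdsn.data_io.OmicsDataset`
    for molecular (feature-level) networks. All columns become vertices; a
    pair is connected iff |PCC| >= tau over the label's samples. Columns
    with zero variance within the label yield no edges.
    """
    if not 0 < tau <= 1:
        raise ParameterError(f"tau must be in (0, 1], got {tau}")
    mask = (matrix.sample_labels == label).to_numpy()
    if mask.sum() == 0:
        raise InputError(f"label {label!r} has no samples")
    if mask.sum() < 3:
        raise InputError(f"label {label!r} has fewer than 3 samples")
    cols = list(matrix.values.columns)
    X = matrix.values.to_numpy(dtype=float)[mask]

    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    edges: dict[EdgeKey, Edge] = {}
    if ok.sum() >= 2:
        C = np.corrcoef(X[:, ok], rowvar=False)
        np.clip(C, -1.0, 1.0, out=C)
        idx = np.flatnonzero(ok)
        a, b = np.nonzero(np.triu(np.abs(C) >= tau, k=1))
        for i, j in zip(a.tolist(), b.tolist()):
            r = float(C[i, j])
            u, v = cols[idx[i]], cols[idx[j]]
            edges[_key(u, v)] = Edge(sign=1 if r >= tau else -1, pcc=r)
    return SignedNetwork(label=label, tau=tau, vertices=frozenset(cols), edges=edges)
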