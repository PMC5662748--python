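"""Shared fixtures and independent oracles used across the test suite."""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pbdsn.data_io import OmicsDataset
from pbdsn.network import Edge, SignedNetwork


@pytest.fixture
def toy_dataset() -> OmicsDataset:
    """6 samples x 3 features, two groups of 3."""
    values = pd.DataFrame(
        {
            "fa": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
            "fb": [2.0, 4.0, 6.0, 5.0, 10.0, 15.0],
            "fc": [4.0, 5.0, 6.0, 4.0, 5.0, 6.0],
        },
        index=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=values.index)
    return OmicsDataset(values=values, sample_labels=labels)


def make_network(
    label: str,
    edges: dict[tuple[str, str], int] | dict[tuple[str, str], tuple[int, float]],
    vertices: set[str] | None = None,
    tau: float = 0.7,
) -> SignedNetwork:
    """Hand-build a signed network; edge values are signs or (sign, pcc)."""
    norm: dict[tuple[str, str], Edge] = {}
    verts = set(vertices or ())
    for (u, v), val in edges.items():
        key = (u, v) if u <= v else (v, u)
        sign, pcc = val if isinstance(val, tuple) else (val, val * 0.9)
        norm[key] = Edge(sign=sign, pcc=pcc)
        verts.update(key)
    return SignedNetwork(label=label, tau=tau, vertices=frozenset(verts), edges=norm)


def pearson_oracle(x, y) -> float:
    """Naive two-pass evaluation of the correlation definition: standardize
    both sequences with (n-1)-denominator deviations, average the products."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = math.sqrt(sum((v - mx) ** 2 for v in x) / (n - 1))
    sy = math.sqrt(sum((v - my) ** 2 for v in y) / (n - 1))
    return sum(
        ((xv - mx) / sx) * ((yv - my) / sy) for xv, yv in zip(x, y)
    ) / (n - 1)


def differential_oracle(
    target: SignedNetwork, others: list[SignedNetwork], fraction: Fraction
) -> set[tuple[str, str]]:
    """Exhaustive per-edge evaluation of the differential rule with exact
    rational arithmetic for the 'most' threshold."""
    need = math.ceil(fraction * len(others))
    kept = set()
    for key, e in target.edges.items():
        n_diff = 0
        for net in others:
            oe = net.edges.get(key)
            if oe is None or oe.sign != e.sign:
                n_diff += 1
        if n_diff >= need:
            kept.add(key)
    return kept


def mann_whitney_oracle(pos, neg) -> float:
    """AUC by exhaustive pair enumeration with half credit for ties."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
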