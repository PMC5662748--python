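"""Pairwise feature-ratio construction.

Networks are built over *feature ratios*: for each sample the quotient
``f_i / f_j`` of two feature abundances, taken for every unordered feature
pair with ``i < j`` in feature order. A ratio is a natural unit in
metabolomics (one metabolite converted into another through one or more
reactions) and has also been used for expression data; m features yield
m(m-1)/2 ratio columns.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import OmicsDataset
from .errors import ParameterError

#: Separator used in ratio names, e.g. "N,N-dimethylglycine/threonic acid".
RATIO_SEP = "/"


@dataclass
class RatioMatrix:
    """Samples x ratios matrix derived from an imputed dataset.

    Columns are named ``"<f_i>/<f_j>"`` with i < j in the order of
    ``source_features``; values are strictly positive.
    """

    values: pd.DataFrame
    source_features: list[str]
    sample_labels: pd.Series
    mode: str = "static"
    label_order: list[str] | None = None

    @property
    def ratio_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def labels(self) -> list[str]:
        if self.label_order is not None:
            present = set(self.sample_labels)
            return [l for l in self.label_order if l in present]
        return sorted(set(self.sample_labels))

    def samples_for(self, label: str) -> pd.DataFrame:
        return self.values.loc[self.sample_labels == label]


def ratio_count(m: int) -> int:
    """Number of pairwise ratios constructible from ``m`` features:
    m(m-1)/2 (e.g. 81 features -> 3240 ratios, 17 -> 136)."""
    if m < 1:
        raise ParameterError(f"m must be >= 1, got {m}")
    return m * (m - 1) // 2


def ratio_name(f_i: str, f_j: str) -> str:
    return f"{f_i}{RATIO_SEP}{f_j}"


def compute_ratios(ds: OmicsDataset, kept_features: Sequence[str] | None = None) -> RatioMatrix:
    """Build the ratio matrix over ``kept_features`` (default: all).

    For every unordered pair (i, j) with i < j in kept-feature order and
    every sample k the value is ``f_i(k) / f_j(k)``; columns are ordered
    lexicographically by the index pair. The dataset must be imputed.
    """
    feats = list(kept_features) if kept_features is not None else ds.feature_names
    unknown = set(feats) - set(ds.feature_names)
    if unknown:
        raise ParameterError(f"unknown features: {sorted(unknown)}")
    if len(feats) < 2:
        raise ParameterError("need at least 2 features to form ratios")
    X = ds.values[feats].to_numpy(dtype=float)
    if not (X > 0).all():
        raise ParameterError("compute_ratios requires an imputed (all-positive) dataset")

    m = len(feats)
    iu, ju = np.triu_indices(m, k=1)
    vals = X[:, iu] / X[:, ju]
    names = [ratio_name(feats[i], feats[j]) for i, j in zip(iu, ju)]
    df = pd.DataFrame(vals, index=ds.values.index, columns=names)
    return RatioMatrix(
        values=df,
        source_features=feats,
        sample_labels=ds.sample_labels,
        mode=ds.mode,
        label_order=ds.label_order,
    )
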