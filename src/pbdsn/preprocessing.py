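"""Fold-change based feature filtering.

Before ratios are formed, uninformative features are removed: a feature is
kept only if the magnitude of the log fold-change of its group means reaches
a threshold for at least one pair of compared labels. Typical settings are
a threshold of 3 (log2) for multi-group expression data and 1 for
metabolomics time courses, evaluated either over all label pairs or over a
designated subset of "typical" labels.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import log
from typing import Sequence

import numpy as np

from .data_io import OmicsDataset
from .errors import ParameterError


@dataclass
class FeatureFilterResult:
    """Outcome of :func:`fold_change_filter`.

    ``kept_features`` preserves the dataset's feature order;
    ``per_feature_max_abs_log_fc`` maps every feature (kept or not) to the
    maximum |log FC| it achieved over the compared label pairs.
    """

    kept_features: list[str]
    per_feature_max_abs_log_fc: dict[str, float]
    threshold: float
    log_base: float
    compared_labels: list[str]


def fold_change_filter(
    ds: OmicsDataset,
    threshold: float,
    log_base: float = 2.0,
    compare_labels: Sequence[str] | None = None,
) -> FeatureFilterResult:
    """Keep features whose max |log fold-change| between label means
    reaches ``threshold``.

    The fold change between labels *a* and *b* is the ratio of arithmetic
    group means, and every unordered pair of ``compare_labels`` (all labels
    when omitted) is evaluated. The dataset must be imputed (all values
    strictly positive) so the log is defined.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    if log_base <= 1:
        raise ParameterError(f"log_base must be > 1, got {log_base}")
    labels = list(compare_labels) if compare_labels is not None else ds.labels
    missing = set(labels) - set(ds.labels)
    if missing:
        raise ParameterError(f"compare labels absent from dataset: {sorted(missing)}")
    if len(labels) < 2:
        raise ParameterError("need at least two labels to compare")

    means = np.array([ds.samples_for(lab).mean(axis=0).to_numpy() for lab in labels])
    if not (means > 0).all():
        raise ParameterError("fold-change filter requires an imputed (all-positive) dataset")
    log_means = np.log(means) / log(log_base)
    max_fc = np.zeros(ds.n_features)
    for i, j in combinations(range(len(labels)), 2):
        np.maximum(max_fc, np.abs(log_means[i] - log_means[j]), out=max_fc)

    per_feature = dict(zip(ds.feature_names, max_fc.tolist()))
    kept = [f for f, v in per_feature.items() if v >= threshold]
    return FeatureFilterResult(
        kept_features=kept,
        per_feature_max_abs_log_fc=per_feature,
        threshold=threshold,
        log_base=log_base,
        compared_labels=labels,
    )
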