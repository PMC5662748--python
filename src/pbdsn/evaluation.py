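"""Biomarker evaluation: logistic-regression ROC/AUC and group summaries.

Selected ratios are scored as discriminators of a binary contrast (one
group versus the rest, or a union of time points versus the others) with an
unpenalized logistic regression; the ROC curve is swept over the fitted
probabilities and the AUC equals the Mann-Whitney statistic (ties counted
half). For trajectory-style reporting, per-label means and standard errors
of a ratio are computed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .errors import InputError, ParameterError
from .ratios import RatioMatrix

MAX_ITER = 1000


@dataclass
class EvaluationResult:
    """AUC with its ROC curve and the contrast that produced it."""

    auc: float
    roc_points: list[tuple[float, float]]  # (FPR, TPR), monotone, (0,0)..(1,1)
    features_used: list[str]
    positive_labels: tuple[str, ...]
    n_pos: int
    n_neg: int
    converged: bool = True


@dataclass
class GroupSummary:
    """Per-label mean and standard error of one ratio.

    ``se`` is the sample standard deviation (n-1 denominator) divided by
    sqrt(n); single-sample labels get se = 0 and are flagged degenerate.
    """

    feature: str
    labels: list[str]
    means: dict[str, float]
    ses: dict[str, float]
    ns: dict[str, int]
    degenerate_labels: list[str]


def logistic_auc(
    rm: RatioMatrix,
    features: Sequence[str],
    positive_labels: Sequence[str],
) -> EvaluationResult:
    """Fit logistic regression on ``features`` and report ROC/AUC.

    Samples with a label in ``positive_labels`` form the positive class,
    all others the negative class. The model is an intercept plus one
    linear coefficient per feature, fitted by (unpenalized) maximum
    likelihood with a bounded iteration count; under perfect separation the
    ranking of the fitted scores is still well-defined, so the AUC is
    reported and the result is flagged as non-converged.
    """
    features = list(features)
    unknown = set(features) - set(rm.values.columns)
    if unknown:
        raise ParameterError(f"unknown features: {sorted(unknown)}")
    if not features:
        raise ParameterError("need at least one feature")
    pos = set(positive_labels)
    y = rm.sample_labels.isin(pos).to_numpy()
    if y.all() or not y.any():
        raise InputError("both classes must be non-empty")
    X = rm.values[features].to_numpy(dtype=float)

    # C = inf disables the ridge term: plain maximum-likelihood logistic fit
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=MAX_ITER)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X, y)
    scores = model.predict_proba(X)[:, 1]

    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    value = float(_trapezoid_auc(fpr, tpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    return EvaluationResult(
        auc=value,
        roc_points=points,
        features_used=features,
        positive_labels=tuple(positive_labels),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        converged=converged,
    )


def mann_whitney_auc(scores: Sequence[float], positive: Sequence[bool]) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie).

    This is the Mann-Whitney U statistic divided by n_pos * n_neg and is
    what the ROC trapezoid evaluates to under the midpoint tie convention.
    Exposed for cross-checks and per-feature scoring.
    """
    s = np.asarray(scores, dtype=float)
    p = np.asarray(positive, dtype=bool)
    if p.all() or not p.any():
        raise InputError("both classes must be non-empty")
    pos, neg = s[p], s[~p]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def group_summary(rm: RatioMatrix, feature: str) -> GroupSummary:
    """Mean and standard error of one ratio per label, in label order."""
    if feature not in set(rm.values.columns):
        raise ParameterError(f"unknown feature {feature!r}")
    col = rm.values[feature]
    means: dict[str, float] = {}
    ses: dict[str, float] = {}
    ns: dict[str, int] = {}
    degenerate: list[str] = []
    for lab in rm.labels:
        x = col[rm.sample_labels == lab].to_numpy(dtype=float)
        n = x.size
        means[lab] = float(x.mean())
        ns[lab] = n
        if n < 2:
            ses[lab] = 0.0
            degenerate.append(lab)
        else:
            ses[lab] = float(x.std(ddof=1) / np.sqrt(n))
    return GroupSummary(
        feature=feature,
        labels=rm.labels,
        means=means,
        ses=ses,
        ns=ns,
        degenerate_labels=degenerate,
    )
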