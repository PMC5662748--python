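"""Synthetic datasets with a planted differential correlation hub.

The generator emulates the correlation topology the differential
sub-network method detects: a designated hub ratio (feature pair) is
strongly correlated with a set of partner ratios in exactly one target
group (or time point) and essentially uncorrelated with them everywhere
else, while the partner ratios are correlated *among themselves* in every
label so that only the hub-partner edges are differential.

Construction. Features are lognormal: ``f = exp(mu + g)`` with ``g`` a
linear mix of independent standard-normal latents per sample,

    g_0 = h0 * e_0 + c * w              (hub numerator)
    g_1 = v * u    - c * w              (hub denominator)
    g_j = v * p + sigma * e_j - c * w   (partnered tail features)
    g_j = sigma_big * e_j               (unpartnered tail features)

where ``w`` is active only in the target label (c = 0 elsewhere). The hub
ratio f_0/f_1 then shares the latent ``w`` with every partner ratio
f_0/f_j, giving a strong positive correlation only in the target label; the
anchor latent ``p`` correlates the partners with each other in *all*
labels, so partner-partner edges keep the same (red) sign everywhere and
never enter the differential sub-network. Coefficients ``c`` and ``h0`` are
solved numerically from the requested raw-scale correlations through the
lognormal moment formula

    corr(e^X, e^Y) = (exp(cov(X,Y)) - 1) /
                     sqrt((exp(var X) - 1) (exp(var Y) - 1)).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_io import OmicsDataset
from .errors import ParameterError
from .ratios import ratio_name

#: anchor-to-noise variance ratio: sigma^2 = 0.2 v^2 puts the population
#: partner-partner correlation near 0.85 in every label.
_ANCHOR_NOISE_VAR_RATIO = 0.2


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``within_target_pcc`` and ``background_pcc`` are the intended raw-scale
    hub-partner Pearson correlations inside and outside the target label;
    ``noise_sd`` is the log-scale measurement noise of the partnered tail
    features. The seed fully determines the output.
    """

    mode: Literal["static", "time-series"] = "static"
    n_labels: int = 4
    samples_per_label: int = 20
    n_features: int = 10
    n_partners: int = 8
    target_label: str | None = None  # default: first group / last time point
    within_target_pcc: float = 0.95
    background_pcc: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ParameterError("need at least 2 labels")
        if self.samples_per_label < 3:
            raise ParameterError("need at least 3 samples per label")
        if self.n_features < 2:
            raise ParameterError("need at least 2 features")
        if not 0 <= self.n_partners <= self.n_features - 2:
            raise ParameterError(
                f"n_partners must be in [0, n_features - 2] = "
                f"[0, {self.n_features - 2}], got {self.n_partners}"
            )
        if not 0 < self.within_target_pcc < 1:
            raise ParameterError("within_target_pcc must be in (0, 1)")
        if not 0 <= self.background_pcc <= 0.6:
            raise ParameterError(
                "background_pcc must be in [0, 0.6] (it has to stay below tau)"
            )
        if self.background_pcc >= self.within_target_pcc:
            raise ParameterError("background_pcc must be below within_target_pcc")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")

    @property
    def labels(self) -> list[str]:
        prefix = "S" if self.mode == "time-series" else "G"
        return [f"{prefix}{i + 1}" for i in range(self.n_labels)]

    @property
    def resolved_target(self) -> str:
        if self.target_label is not None:
            if self.target_label not in self.labels:
                raise ParameterError(
                    f"target_label {self.target_label!r} not among {self.labels}"
                )
            return self.target_label
        return self.labels[-1] if self.mode == "time-series" else self.labels[0]


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the hub ratio, its partners and the differential
    edges (all carrying a positive sign in the target label)."""

    hub: str
    partners: tuple[str, ...]
    planted_edges: tuple[tuple[str, str], ...]
    target_label: str
    feature_names: tuple[str, ...]


def _lognormal_corr(cov_xy: float, var_x: float, var_y: float) -> float:
    return (np.exp(cov_xy) - 1) / np.sqrt(
        (np.expm1(var_x)) * (np.expm1(var_y))
    )


def _solve_coefficients(spec: SyntheticSpec) -> tuple[float, float, float, float]:
    """Return (v, sigma, h0, c) for the latent mixing matrix."""
    sigma = spec.noise_sd
    v = sigma / np.sqrt(_ANCHOR_NOISE_VAR_RATIO)
    y_floor = (0.25 * sigma) ** 2

    # background hub-partner correlation is driven by the shared e_0 latent
    # (variance h0^2 =: y): corr_bg = y / sqrt((y + v^2)(y + v^2 + sigma^2))
    # on the log scale, pushed through the lognormal moment formula.
    def bg(y: float) -> float:
        return _lognormal_corr(y, y + v**2, y + v**2 + sigma**2)

    if spec.background_pcc <= bg(y_floor):
        y = y_floor
    else:
        y = brentq(lambda t: bg(t) - spec.background_pcc, y_floor, (10 * v) ** 2)
    h0 = float(np.sqrt(y))

    # target hub-partner correlation gains 4c^2 from the shared w latent:
    # cov = y + 4c^2, var_hub = y + v^2 + 4c^2, var_p = y + v^2 + sigma^2 + 4c^2.
    def tg(c: float) -> float:
        q = 4 * c**2
        return _lognormal_corr(y + q, y + v**2 + q, y + v**2 + sigma**2 + q)

    lo, hi = 0.0, 0.01
    while tg(hi) < spec.within_target_pcc:
        lo, hi = hi, hi * 2
        if hi > 1e3:
            raise ParameterError(
                "within_target_pcc is not achievable with these settings"
            )
    c = float(brentq(lambda t: tg(t) - spec.within_target_pcc, lo, hi))
    return float(v), float(sigma), h0, c


def generate(spec: SyntheticSpec) -> tuple[OmicsDataset, GroundTruth]:
    """Generate a dataset with the planted hub structure of ``spec``.

    Returns the dataset and a :class:`GroundTruth` record naming the hub
    ratio, the partner ratios and the planted differential edges.
    Deterministic under ``spec.seed``.
    """
    m = spec.n_features
    width = len(str(m))
    feats = [f"f{i + 1:0{width}d}" for i in range(m)]
    labels = spec.labels
    target = spec.resolved_target

    v, sigma, h0, c = _solve_coefficients(spec)
    sigma_big = max(6 * sigma, 3 * c)

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2_165_941]))
    mu = rng.uniform(2.0, 5.0, size=m)  # log-scale baselines, per feature

    def mixing(active: bool) -> np.ndarray:
        cc = c if active else 0.0
        # latent order: p, u, w, e_0 .. e_{m-1}
        L = np.zeros((m, 3 + m))
        L[0, 3] = h0
        L[0, 2] = cc
        L[1, 1] = v
        L[1, 2] = -cc
        for j in range(2, m):
            if j - 2 < spec.n_partners:
                L[j, 0] = v
                L[j, 3 + j] = sigma
                L[j, 2] = -cc
            else:
                L[j, 3 + j] = sigma_big
        return L

    blocks = []
    sample_labels = []
    sample_ids = []
    for lab in labels:
        lat = rng.standard_normal((spec.samples_per_label, 3 + m))
        L = mixing(active=(lab == target and spec.n_partners > 0))
        blocks.append(np.exp(lat @ L.T + mu))
        sample_labels.extend([lab] * spec.samples_per_label)
        sample_ids.extend(
            f"{lab}_{k + 1:02d}" for k in range(spec.samples_per_label)
        )

    values = pd.DataFrame(
        np.vstack(blocks), index=sample_ids, columns=feats
    )
    ds = OmicsDataset(
        values=values,
        sample_labels=pd.Series(sample_labels, index=sample_ids),
        mode=spec.mode,
        label_order=labels if spec.mode == "time-series" else None,
    )

    hub = ratio_name(feats[0], feats[1])
    partners = tuple(
        ratio_name(feats[0], feats[j]) for j in range(2, 2 + spec.n_partners)
    )
    edges = tuple(tuple(sorted((hub, p))) for p in partners)
    truth = GroundTruth(
        hub=hub,
        partners=partners,
        planted_edges=edges,
        target_label=target,
        feature_names=tuple(feats),
    )
    return ds, truth


def add_missingness(
    ds: OmicsDataset, rate: float, seed: int = 0
) -> OmicsDataset:
    """Mask each value independently with probability ``rate`` (as NaN).

    At least one value of every feature is left unmasked within each label,
    so group-minimum imputation always has a donor value. Deterministic
    under ``seed``.
    """
    if not 0 <= rate < 1:
        raise ParameterError(f"rate must be in [0, 1), got {rate}")
    if rate == 0:
        return ds
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 911_730]))
    vals = ds.values.copy()
    arr = vals.to_numpy(dtype=float)
    mask = rng.random(arr.shape) < rate
    lab_arr = ds.sample_labels.to_numpy()
    for lab in ds.labels:
        rows = np.flatnonzero(lab_arr == lab)
        for j in range(arr.shape[1]):
            col_mask = mask[rows, j]
            if col_mask.all():
                keep = rng.integers(0, len(rows))
                mask[rows[keep], j] = False
    arr[mask] = np.nan
    vals.loc[:, :] = arr
    return replace(ds, values=vals)
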