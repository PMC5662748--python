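"""End-to-end analysis pipeline.

``run_pipeline`` chains the stages: imputation, fold-change filtering,
ratio construction (or raw features in molecular-network mode), per-label
signed networks, differential sub-network of the target, projections into
the other labels, hub star sub-networks, degree ranking and ROC/AUC
evaluation — and writes every artifact to an output directory. All outputs
are deterministic for a fixed configuration and input: rows are sorted,
ties are broken lexicographically, and floats are serialized with ``repr``.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .data_io import (
    OmicsDataset,
    impute_missing,
    read_dataset,
    write_edge_list,
    write_graphml,
)
from .differential import (
    DEFAULT_FRACTION,
    DifferentialSubNetwork,
    ProjectedSubNetwork,
    differential_subnetwork_static,
    differential_subnetwork_timeseries,
    project_subnetwork,
    star_subnetwork,
)
from .errors import InputError, ParameterError
from .evaluation import EvaluationResult, logistic_auc, mann_whitney_auc
from .network import DEFAULT_TAU, SignedNetwork, build_network
from .preprocessing import fold_change_filter
from .ranking import HubRanking, rank_by_degree, top_k
from .ratios import compute_ratios

log = logging.getLogger("pbdsn")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Defaults follow the method's standard settings: tau = 0.7,
    fraction = 2/3 ("most" of the comparison networks), top k = 5, and a
    fold-change threshold of 3 (log2) for static group comparisons or 1 for
    time-series data.
    """

    mode: str = "static"
    label_column: str = "label"
    label_order: list[str] | None = None
    fc_threshold: float = 3.0
    log_base: float = 2.0
    compare_labels: list[str] | None = None
    tau: float = DEFAULT_TAU
    fraction: float = DEFAULT_FRACTION
    target_label: str | None = None  # static: None = every label in turn
    target_index: int | None = None  # time-series: None = last time point
    k: int = 5
    molecular: bool = False  # True: networks on features (MN-PCC variant)
    positive_labels: list[str] | None = None  # evaluation contrast
    out_dir: str | Path = "pbdsn_out"

    def validate(self) -> None:
        if self.mode not in ("static", "time-series"):
            raise ParameterError(f"invalid mode {self.mode!r}")
        if not 0 < self.tau <= 1:
            raise ParameterError(f"tau must be in (0, 1], got {self.tau}")
        if not 0 < self.fraction <= 1:
            raise ParameterError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.fc_threshold < 0:
            raise ParameterError("fc_threshold must be >= 0")
        if self.log_base <= 1:
            raise ParameterError("log_base must be > 1")
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.mode == "time-series" and self.label_order is None:
            raise ParameterError("time-series mode requires label_order")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        # the bundle does not embed its own location, so that two runs of
        # the same analysis into different directories compare equal
        d.pop("out_dir")
        d["version"] = __version__
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class TargetResult:
    """Everything computed for one target label."""

    target_label: str
    dsn: DifferentialSubNetwork
    projections: dict[str, ProjectedSubNetwork]
    ranking: HubRanking
    selected: list[str]
    hub_star: SignedNetwork | None
    evaluation: EvaluationResult | None
    per_feature_auc: dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineResult:
    config: RunConfig
    kept_features: list[str]
    networks: dict[str, SignedNetwork]
    targets: dict[str, TargetResult]


def _evaluate(rm, selected, positive, labels) -> tuple[EvaluationResult | None, dict]:
    positive = [p for p in positive if p in labels]
    if not positive or set(positive) == set(labels) or not selected:
        return None, {}
    joint = logistic_auc(rm, selected, positive)
    pos_mask = rm.sample_labels.isin(set(positive)).to_numpy()
    per_feature = {
        f: mann_whitney_auc(rm.values[f].to_numpy(), pos_mask) for f in selected
    }
    return joint, per_feature


def run_pipeline(
    config: RunConfig,
    dataset_path: str | Path | None = None,
    dataset: OmicsDataset | None = None,
) -> PipelineResult:
    """Execute the full analysis and write the result bundle to
    ``config.out_dir``. Exactly one of ``dataset_path``/``dataset`` must be
    given; the configuration is validated before any data is read.
    """
    config.validate()
    if (dataset_path is None) == (dataset is None):
        raise ParameterError("provide exactly one of dataset_path or dataset")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, dataset_path, dataset, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config, dataset_path, dataset, out: Path) -> PipelineResult:
    log.info("pbdsn %s", __version__)
    (out / "run_config.json").write_text(config.to_json() + "\n")

    if dataset is None:
        dataset = read_dataset(
            dataset_path,
            label_column=config.label_column,
            mode=config.mode,
            label_order=config.label_order,
        )
    log.info(
        "dataset: %d samples x %d features, labels %s",
        len(dataset.values), dataset.n_features, dataset.labels,
    )
    dataset = impute_missing(dataset)

    if config.fc_threshold > 0:
        filt = fold_change_filter(
            dataset, config.fc_threshold, config.log_base, config.compare_labels
        )
        kept = filt.kept_features
    else:
        kept = dataset.feature_names
    log.info("fold-change filter: %d of %d features kept", len(kept), dataset.n_features)
    if len(kept) < 2:
        raise InputError(
            "fewer than 2 features survive the fold-change filter; "
            "lower fc_threshold"
        )

    if config.molecular:
        matrix = OmicsDataset(
            values=dataset.values[kept],
            sample_labels=dataset.sample_labels,
            mode=dataset.mode,
            label_order=dataset.label_order,
        )
        log.info("molecular mode: networks on %d features", len(kept))
    else:
        matrix = compute_ratios(dataset, kept)
        log.info("ratios: %d columns from %d features", len(matrix.values.columns), len(kept))

    labels = matrix.labels
    networks = {lab: build_network(matrix, lab, config.tau) for lab in labels}
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for lab in labels:
        log.info("network %s: %d edges", lab, networks[lab].n_edges)
        write_edge_list(networks[lab], net_dir / f"{_safe(lab)}.edges.tsv")

    if config.mode == "time-series":
        idx = config.target_index if config.target_index is not None else len(labels) - 1
        if not 0 <= idx < len(labels):
            raise ParameterError(f"target_index {idx} out of range for {len(labels)} time points")
        target_labels = [labels[idx]]
    elif config.target_label is not None:
        if config.target_label not in labels:
            raise ParameterError(f"target label {config.target_label!r} not in dataset")
        target_labels = [config.target_label]
    else:
        target_labels = labels

    targets: dict[str, TargetResult] = {}
    for t_lab in target_labels:
        targets[t_lab] = _analyze_target(config, matrix, networks, labels, t_lab, out)

    return PipelineResult(
        config=config, kept_features=kept, networks=networks, targets=targets
    )


def _analyze_target(config, matrix, networks, labels, t_lab, out: Path) -> TargetResult:
    tdir = out / f"target_{_safe(t_lab)}"
    tdir.mkdir(exist_ok=True)
    if config.mode == "time-series":
        ordered = [networks[lab] for lab in labels]
        dsn = differential_subnetwork_timeseries(
            ordered, labels.index(t_lab), config.fraction
        )
    else:
        dsn = differential_subnetwork_static(networks, t_lab, config.fraction)
    log.info("differential sub-network %s: %d edges, %d vertices",
             t_lab, dsn.n_edges, len(dsn.vertex_set))
    _write_differential(dsn, tdir / "differential.edges.tsv")

    projections: dict[str, ProjectedSubNetwork] = {}
    proj_dir = tdir / "projections"
    proj_dir.mkdir(exist_ok=True)
    for lab in dsn.comparison_labels:
        proj = project_subnetwork(dsn, networks[lab])
        projections[lab] = proj
        _write_projection(proj, proj_dir / f"{_safe(lab)}.edges.tsv")

    ranking = rank_by_degree(dsn) if dsn.edges else HubRanking(entries=[])
    selected = top_k(ranking, config.k) if ranking.entries else []
    _write_ranking(ranking, tdir / "ranking.tsv")

    hub_star = None
    if selected:
        hub = selected[0]
        log.info("hub %s: degree %d", hub, dsn.degree(hub))
        star_dir = tdir / "stars"
        star_dir.mkdir(exist_ok=True)
        hub_star = star_subnetwork(dsn, hub)
        write_graphml(hub_star, star_dir / "hub_differential.graphml")
        write_edge_list(hub_star, star_dir / "hub_differential.edges.tsv")
        for lab, proj in sorted(projections.items()):
            if hub in proj.vertex_set:
                star = star_subnetwork(proj, hub)
                write_graphml(star, star_dir / f"hub_in_{_safe(lab)}.graphml")

    if config.positive_labels is not None:
        positive = config.positive_labels
    elif config.mode == "time-series":
        positive = labels[labels.index(t_lab):]  # target stage onward
    else:
        positive = [t_lab]  # one vs rest
    evaluation, per_feature = _evaluate(matrix, selected, positive, labels)
    _write_auc(evaluation, per_feature, tdir / "auc_report.tsv")
    if evaluation is not None:
        log.info("AUC (%s vs rest, %d features): %s",
                 "+".join(positive), len(selected), repr(evaluation.auc))

    return TargetResult(
        target_label=t_lab,
        dsn=dsn,
        projections=projections,
        ranking=ranking,
        selected=selected,
        hub_star=hub_star,
        evaluation=evaluation,
        per_feature_auc=per_feature,
    )


def _safe(label: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_." else "_" for ch in str(label))


def _write_differential(dsn: DifferentialSubNetwork, path: Path) -> None:
    lines = ["vertex_u\tvertex_v\tsign\tpcc\tdifference_count"]
    for key in sorted(dsn.edges):
        e = dsn.edges[key]
        lines.append(
            f"{key[0]}\t{key[1]}\t{e.sign:+d}\t{e.pcc!r}\t{dsn.per_edge_difference_count[key]}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_projection(proj: ProjectedSubNetwork, path: Path) -> None:
    lines = ["vertex_u\tvertex_v\tsign\tpcc"]
    for key in sorted(proj.edges):
        e = proj.edges[key]
        lines.append(f"{key[0]}\t{key[1]}\t{e.sign:+d}\t{e.pcc!r}")
    path.write_text("\n".join(lines) + "\n")


def _write_ranking(ranking: HubRanking, path: Path) -> None:
    lines = ["rank\tvertex\tdegree"]
    for i, (vtx, deg) in enumerate(ranking.entries, start=1):
        lines.append(f"{i}\t{vtx}\t{deg}")
    path.write_text("\n".join(lines) + "\n")


def _write_auc(
    evaluation: EvaluationResult | None, per_feature: dict[str, float], path: Path
) -> None:
    lines = ["comparison\tfeatures\tauc\tn_pos\tn_neg\tconverged"]
    if evaluation is not None:
        contrast = "+".join(evaluation.positive_labels) + " vs rest"
        lines.append(
            f"{contrast}\t{';'.join(evaluation.features_used)}\t{evaluation.auc!r}"
            f"\t{evaluation.n_pos}\t{evaluation.n_neg}\t{evaluation.converged}"
        )
        for feat in evaluation.features_used:
            lines.append(
                f"{contrast} [single]\t{feat}\t{per_feature[feat]!r}"
                f"\t{evaluation.n_pos}\t{evaluation.n_neg}\tTrue"
            )
    path.write_text("\n".join(lines) + "\n")
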