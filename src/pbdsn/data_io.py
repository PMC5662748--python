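"""Reading, validating and writing datasets and network artifacts.

The central container is :class:`OmicsDataset`: a samples x features matrix
of strictly positive abundances (expression levels, metabolite
concentrations, ...) with a per-sample group or time-point label. Datasets
are read from delimited text (TSV/CSV, header row of feature names, one
designated label column) and missing or non-positive entries are filled by
:func:`impute_missing` before any ratio or correlation is computed.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError

#: Pearson correlation over fewer than 3 samples is degenerate (it is
#: always +/-1 for n=2), so every label must have at least this many samples.
MIN_SAMPLES_PER_LABEL = 3

MODES = ("static", "time-series")


@dataclass
class OmicsDataset:
    """A labeled samples x features abundance matrix.

    Parameters
    ----------
    values :
        DataFrame with samples as rows and features as columns. ``NaN``
        marks a missing measurement. Values are expected to be positive
        after imputation.
    sample_labels :
        Per-sample group (static mode) or time point (time-series mode),
        aligned with ``values.index``.
    mode :
        ``"static"`` for independent groups, ``"time-series"`` for ordered
        time points.
    label_order :
        Required in time-series mode: the ordered sequence of time points.
        Optional in static mode (defaults to sorted group names).
    """

    values: pd.DataFrame
    sample_labels: pd.Series
    mode: str = "static"
    label_order: list[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InputError(f"mode must be one of {MODES}, got {self.mode!r}")
        names = list(self.values.columns)
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate feature names: {dupes}")
        if any(not str(n).strip() for n in names):
            raise InputError("feature names must be non-empty")
        self.sample_labels = pd.Series(self.sample_labels, dtype=object)
        self.sample_labels.index = self.values.index
        if self.mode == "time-series":
            if self.label_order is None:
                raise InputError("time-series mode requires label_order")
        if self.label_order is not None:
            unknown = set(self.sample_labels) - set(self.label_order)
            if unknown:
                raise InputError(
                    f"sample labels not in label_order: {sorted(unknown)}"
                )
        counts = self.sample_labels.value_counts()
        small = counts[counts < MIN_SAMPLES_PER_LABEL]
        if not small.empty:
            raise InputError(
                "every label needs at least "
                f"{MIN_SAMPLES_PER_LABEL} samples; too few for: "
                f"{sorted(small.index)}"
            )

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> list[str]:
        """Labels in analysis order (label_order if given, else sorted)."""
        if self.label_order is not None:
            present = set(self.sample_labels)
            return [l for l in self.label_order if l in present]
        return sorted(set(self.sample_labels))

    def samples_for(self, label: str) -> pd.DataFrame:
        """Rows of ``values`` belonging to one label."""
        return self.values.loc[self.sample_labels == label]


def read_dataset(
    path: str | Path,
    label_column: str,
    mode: str = "static",
    label_order: Sequence[str] | None = None,
    sep: str | None = None,
    features_as_rows: bool = False,
) -> OmicsDataset:
    """Read a delimited text matrix into an :class:`OmicsDataset`.

    The file must have a header row; ``label_column`` names the column that
    carries group/time-point membership. ``sep`` is inferred from the file
    extension when omitted (``.csv`` -> comma, otherwise tab). Set
    ``features_as_rows=True`` for files with features as rows and samples
    as columns (the label row is then named by ``label_column``).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if not features_as_rows and len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise InputError(f"duplicate feature names in header: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if features_as_rows:
        df = df.T
    df.index.name = None
    df.columns.name = None
    if label_column not in df.columns:
        raise InputError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].astype(str)
    values = df.drop(columns=[label_column]).apply(pd.to_numeric)
    return OmicsDataset(
        values=values,
        sample_labels=labels,
        mode=mode,
        label_order=list(label_order) if label_order is not None else None,
    )


def write_dataset(ds: OmicsDataset, path: str | Path, label_column: str = "label") -> None:
    """Write a dataset back to TSV/CSV (inverse of :func:`read_dataset`)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = ds.values.copy()
    out.insert(0, label_column, ds.sample_labels)
    out.to_csv(path, sep=sep, index=True, index_label="sample")


def impute_missing(ds: OmicsDataset) -> OmicsDataset:
    """Replace missing values by the group minimum of the same feature.

    A missing (or non-positive, which ratios cannot accommodate) value of
    feature *f* in label group *g* is replaced by the minimum strictly
    positive value of *f* among the samples of *g*. If *g* has no positive
    value of *f* at all, the global minimum positive value of *f* is used.
    A feature with no positive value anywhere is an input error.

    The operation is idempotent and never alters an already-positive value.
    """
    vals = ds.values.copy()
    arr = vals.to_numpy(dtype=float)
    missing = ~(arr > 0) | np.isnan(arr)
    if not missing.any():
        return ds
    labels = ds.sample_labels.to_numpy()
    with np.errstate(invalid="ignore"):
        masked = np.where(missing, np.nan, arr)
    global_min = np.min(np.where(np.isnan(masked), np.inf, masked), axis=0)
    dead = ~np.isfinite(global_min)
    if dead.any():
        bad = [ds.feature_names[i] for i in np.where(dead)[0]]
        raise InputError(f"feature(s) with no positive value anywhere: {bad}")
    for lab in ds.labels:
        rows = labels == lab
        block = masked[rows]
        if not missing[rows].any():
            continue
        grp_min = np.nanmin(
            np.where(np.isnan(block), np.inf, block), axis=0
        )
        fill = np.where(np.isfinite(grp_min), grp_min, global_min)
        sub = arr[rows]
        sub[missing[rows]] = np.broadcast_to(fill, sub.shape)[missing[rows]]
        arr[rows] = sub
    vals.loc[:, :] = arr
    return replace(ds, values=vals)


# ---------------------------------------------------------------------------
# network serialization


def write_edge_list(net, path: str | Path) -> None:
    """Serialize a signed network as a TSV edge list.

    Columns are ``vertex_u, vertex_v, sign, pcc`` with rows in lexicographic
    order of the vertex pair. The label, threshold and the full vertex set
    (including isolated vertices) are preserved in ``#``-prefixed header
    lines so that a network round-trips exactly through its own file.
    """
    path = Path(path)
    buf = io.StringIO()
    if net.label is not None:
        buf.write(f"# label={net.label}\n")
    if net.tau is not None:
        buf.write(f"# tau={net.tau!r}\n")
    buf.write("# vertices=" + ";".join(sorted(net.vertices)) + "\n")
    buf.write("vertex_u\tvertex_v\tsign\tpcc\n")
    for (u, v) in sorted(net.edges):
        e = net.edges[(u, v)]
        buf.write(f"{u}\t{v}\t{e.sign:+d}\t{e.pcc!r}\n")
    path.write_text(buf.getvalue())


def read_edge_list(path: str | Path):
    """Read a signed network written by :func:`write_edge_list`."""
    from .network import Edge, SignedNetwork  # local import to avoid a cycle

    path = Path(path)
    label = None
    tau = None
    vertices: set[str] = set()
    rows: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("# label="):
            label = line.split("=", 1)[1]
        elif line.startswith("# tau="):
            tau = float(line.split("=", 1)[1])
        elif line.startswith("# vertices="):
            payload = line.split("=", 1)[1]
            vertices = set(payload.split(";")) if payload else set()
        elif line.startswith("#") or not line.strip():
            continue
        else:
            rows.append(line)
    header, *data = rows
    if header.split("\t")[:4] != ["vertex_u", "vertex_v", "sign", "pcc"]:
        raise InputError(f"{path} is not a pbdsn edge list")
    edges = {}
    for line in data:
        u, v, sign, pcc = line.split("\t")
        key = (u, v) if u <= v else (v, u)
        edges[key] = Edge(sign=int(sign), pcc=float(pcc))
        vertices.update(key)
    return SignedNetwork(label=label, tau=tau, vertices=frozenset(vertices), edges=edges)


def write_graphml(net, path: str | Path) -> None:
    """Export a network to GraphML with ``sign`` and ``color`` edge
    attributes (red = positive, green = negative) for visualization tools."""
    g = nx.Graph(label=str(net.label), tau=float(net.tau) if net.tau is not None else -1.0)
    g.add_nodes_from(sorted(net.vertices))
    for (u, v) in sorted(net.edges):
        e = net.edges[(u, v)]
        g.add_edge(u, v, sign=e.sign, pcc=e.pcc,
                   color="red" if e.sign > 0 else "green")
    nx.write_graphml(g, str(path))
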