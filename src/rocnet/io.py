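"""CSV input, run configuration, and the end-to-end pipeline.

Input is a pair of CSV files: an observation table (header row of factor
names, first column the sample id) and a label table (``sample_id,label``
with label 1 for the diseased / high-incidence group).  The two are joined
on sample id, so row order need not match.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .network import apply_threshold, build_graph, correlation_matrix, export_graph
from .nullsim import edge_threshold, null_rij, null_sa
from .screening import screen_factors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dataset:
    """Joined observations and labels for one study."""

    values: pd.DataFrame  # samples x factors
    labels: pd.Series  # aligned to values.index, 0/1

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def factor_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_diseased(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_healthy(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def lambda_ratio(self) -> float:
        return self.n_diseased / self.n_healthy


def read_dataset(obs_path, labels_path, samples_as_columns: bool = False) -> Dataset:
    """Read and join the observation and label CSVs.

    The observation file's first column holds sample ids (or, with
    ``samples_as_columns``, its header holds sample ids and its first
    column factor names).  Rows lacking a label are dropped with a
    warning; label ids missing from the observations are an error, as are
    missing cells, duplicate factor names and non-binary labels.
    """
    with open(obs_path, newline="") as fh:
        header = next(csv.reader(fh))[1:]
    if not samples_as_columns and len(set(header)) != len(header):
        dupes = sorted({n for n in header if header.count(n) > 1})
        raise InvalidInputError(f"duplicate factor names in observations: {dupes}")
    obs = pd.read_csv(obs_path, index_col=0)
    if samples_as_columns:
        obs = obs.T
        factor_names = [str(c) for c in obs.columns]
        if len(set(factor_names)) != len(factor_names):
            dupes = sorted({n for n in factor_names if factor_names.count(n) > 1})
            raise InvalidInputError(f"duplicate factor names in observations: {dupes}")
    obs.index = obs.index.astype(str)

    lab = pd.read_csv(labels_path)
    if lab.shape[1] < 2:
        raise InvalidInputError("labels file needs a sample-id column and a label column")
    lab = lab.iloc[:, :2].set_index(lab.columns[0])
    lab.index = lab.index.astype(str)
    labels = lab.iloc[:, 0]

    unmatched = sorted(set(labels.index) - set(obs.index))
    if unmatched:
        raise InvalidInputError(f"label sample ids missing from observations: {unmatched}")
    unlabeled = sorted(set(obs.index) - set(labels.index))
    if unlabeled:
        logger.warning("dropping %d samples without labels: %s", len(unlabeled), unlabeled)
        obs = obs.drop(index=unlabeled)
    labels = labels.loc[obs.index]

    if not set(pd.unique(labels)) <= {0, 1}:
        raise InvalidInputError(
            f"labels must be binary 0/1, found values {sorted(pd.unique(labels))}"
        )
    if labels.nunique() < 2:
        raise InvalidInputError("single-class labels: both 0 and 1 are required")

    for col in obs.columns:
        numeric = pd.to_numeric(obs[col], errors="coerce")
        bad = obs.index[numeric.isna()]
        if len(bad):
            raise InvalidInputError(
                f"missing or non-numeric cells in column {col!r}, rows {list(bad[:5])}"
            )
        obs[col] = numeric.astype(float)
    return Dataset(values=obs, labels=labels.astype(int))


def write_dataset(obs: pd.DataFrame, labels: pd.Series, obs_path, labels_path) -> None:
    """Write a dataset in the same CSV dialect :func:`read_dataset` accepts."""
    obs.to_csv(obs_path, index_label="sample_id")
    labels.rename("label").to_csv(labels_path, index_label="sample_id")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one reproducible analysis run."""

    obs_path: str
    labels_path: str
    out_dir: str
    alpha: float = 0.05
    beta: float = 0.01
    n_sim: int = 1000
    grid: int = 1000
    seed: int = 0
    metric: str = "l1"
    form: str = "inv1p"
    threshold_tail: str = "upper"
    drop_isolated: bool = False
    samples_as_columns: bool = False
    category_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.beta < 1:
            raise ConfigurationError("alpha and beta must lie strictly between 0 and 1")
        if self.n_sim < 1 or self.grid < 2:
            raise ConfigurationError("n_sim must be >= 1 and grid >= 2")


def read_category_map(path) -> dict:
    """Read a ``factor,category`` CSV into a dict."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise InvalidInputError("category file needs columns factor,category")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run screening and network construction end to end; returns artifact paths.

    Writes to ``config.out_dir``: ``screening.csv``, ``r_matrix.csv``,
    ``r_matrix_thresholded.csv``, ``network.graphml``, ``edges.csv`` and
    ``run_log.json`` (the full configuration, the sample sizes and the
    edge threshold).  Identical config and seed give identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        data = read_dataset(
            config.obs_path, config.labels_path, samples_as_columns=config.samples_as_columns
        )
    except (InvalidInputError, OSError) as exc:
        raise InvalidInputError(f"read_dataset: {exc}") from exc

    table = screen_factors(
        data.values,
        data.labels,
        alpha=config.alpha,
        n_sim=config.n_sim,
        G=config.grid,
        seed=config.seed,
    )
    table.to_csv(out / "screening.csv")

    dist, r = correlation_matrix(data.values, data.labels, metric=config.metric, form=config.form)
    r.to_csv(out / "r_matrix.csv")
    null_r = null_rij(
        data.lambda_ratio,
        data.n_diseased,
        n_sim=config.n_sim,
        G=config.grid,
        seed=config.seed + 1,
        metric=config.metric,
        form=config.form,
    )
    thr = edge_threshold(null_r, config.beta, tail=config.threshold_tail)
    pruned = apply_threshold(r, null_r, config.beta, tail=config.threshold_tail)
    pruned.to_csv(out / "r_matrix_thresholded.csv")

    node_attrs = read_category_map(config.category_path) if config.category_path else None
    net = build_graph(
        pruned,
        node_attrs=node_attrs,
        drop_isolated=config.drop_isolated,
        r_matrix=r,
        distance_matrix=dist,
        beta=config.beta,
        threshold=thr,
    )
    export_graph(net, out / "network.graphml", format="graphml")
    export_graph(net, out / "edges.csv", format="edgelist_csv")

    log = {
        "config": asdict(config),
        "n_diseased": data.n_diseased,
        "n_healthy": data.n_healthy,
        "lambda_ratio": data.lambda_ratio,
        "edge_threshold": thr,
        "n_edges": net.graph.number_of_edges(),
        "n_significant": int(table.frame["significant"].sum()),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {
        "screening": str(out / "screening.csv"),
        "r_matrix": str(out / "r_matrix.csv"),
        "r_matrix_thresholded": str(out / "r_matrix_thresholded.csv"),
        "graphml": str(out / "network.graphml"),
        "edges": str(out / "edges.csv"),
        "run_log": str(out / "run_log.json"),
    }
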