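"""Factor network from the ROC-distance correlation matrix.

For every pair of factors the distance between their empirical ROC curves
is mapped to a correlation-like weight in (0, 1]; the matrix of weights,
pruned by a quantile of its simulated null, is the adjacency matrix of an
undirected weighted graph whose components expose groups of factors with a
shared relation to the disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .nullsim import NullSample, edge_threshold
from .roc import TwoGroupSample, empirical_roc, roc_correlation, roc_distance
from .screening import _numeric_column, split_groups

EXPORT_FORMATS = ("graphml", "edgelist_csv", "dot")


@dataclass(frozen=True)
class CorrelationNetwork:
    """Thresholded factor network plus the matrices it was built from."""

    factor_names: list
    graph: nx.Graph
    r_matrix: pd.DataFrame | None = None
    distance_matrix: pd.DataFrame | None = None
    beta: float | None = None
    threshold: float | None = None
    node_attrs: dict | None = None

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        """Retained undirected edges as (factor_a, factor_b, weight)."""
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def degrees(self) -> dict:
        return dict(self.graph.degree())


def correlation_matrix(
    data: pd.DataFrame, labels, metric: str = "l1", form: str = "inv1p"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise ROC-curve distances and correlation weights for all factors.

    Returns ``(distance_matrix, r_matrix)``, both symmetric with zero /
    unit diagonal respectively.
    """
    if data.shape[1] < 2:
        raise InvalidInputError("correlation matrix requires at least 2 factors")
    diseased, healthy = split_groups(data, labels)
    names = [str(c) for c in data.columns]
    curves = [
        empirical_roc(
            TwoGroupSample(
                factor_name=name,
                diseased_values=_numeric_column(diseased, col),
                healthy_values=_numeric_column(healthy, col),
            )
        )
        for name, col in zip(names, data.columns)
    ]
    k = len(curves)
    d = np.zeros((k, k))
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            dij = roc_distance(curves[i], curves[j], metric=metric)
            d[i, j] = d[j, i] = dij
            r[i, j] = r[j, i] = roc_correlation(dij, form=form)
    return (
        pd.DataFrame(d, index=names, columns=names),
        pd.DataFrame(r, index=names, columns=names),
    )


def apply_threshold(
    r_matrix: pd.DataFrame, null: NullSample, beta: float, tail: str = "upper"
) -> pd.DataFrame:
    """Zero the entries of ``r_matrix`` below the simulated-null threshold.

    The cutoff is :func:`rocnet.nullsim.edge_threshold` of the ``r_ij``
    null at level ``beta``; the diagonal is zeroed too so the result is an
    adjacency matrix without self-loops.
    """
    thr = edge_threshold(null, beta, tail=tail)
    vals = r_matrix.to_numpy(dtype=float).copy()
    vals[vals < thr] = 0.0
    np.fill_diagonal(vals, 0.0)
    return pd.DataFrame(vals, index=r_matrix.index, columns=r_matrix.columns)


def build_graph(
    matrix: pd.DataFrame,
    node_attrs: dict | None = None,
    drop_isolated: bool = False,
    r_matrix: pd.DataFrame | None = None,
    distance_matrix: pd.DataFrame | None = None,
    beta: float | None = None,
    threshold: float | None = None,
) -> CorrelationNetwork:
    """Undirected weighted graph from a thresholded adjacency matrix.

    ``node_attrs`` maps factor name to a category label (kept as a node
    attribute, e.g. pollutant class).  Isolated nodes are kept by default;
    ``drop_isolated`` removes them, mirroring network figures that show
    connected factors only.
    """
    vals = matrix.to_numpy(dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise InvalidInputError("adjacency matrix must be square")
    if not np.allclose(vals, vals.T):
        raise InvalidInputError("adjacency matrix must be symmetric")
    names = [str(c) for c in matrix.columns]
    graph = nx.Graph()
    for name in names:
        attrs = {"name": name}
        if node_attrs and name in node_attrs:
            attrs["category"] = str(node_attrs[name])
        graph.add_node(name, **attrs)
    rows, cols = np.nonzero(np.triu(vals, k=1))
    for i, j in zip(rows, cols):
        graph.add_edge(names[i], names[j], weight=float(vals[i, j]))
    if drop_isolated:
        graph.remove_nodes_from(list(nx.isolates(graph)))
    return CorrelationNetwork(
        factor_names=list(graph.nodes),
        graph=graph,
        r_matrix=r_matrix,
        distance_matrix=distance_matrix,
        beta=beta,
        threshold=threshold,
        node_attrs=node_attrs,
    )


def export_graph(
    net: CorrelationNetwork, path, format: str = "graphml", binarize: bool = False
) -> None:
    """Write the network as GraphML, an edge-list CSV, or DOT.

    GraphML keeps node attributes ``name``/``category`` and the edge
    ``weight``; the CSV has columns ``source,target,weight``.  With
    ``binarize`` every retained edge weight is written as 1.
    """
    if format not in EXPORT_FORMATS:
        raise ConfigurationError(f"unknown export format {format!r}; choose from {EXPORT_FORMATS}")
    graph = net.graph
    if binarize:
        graph = graph.copy()
        for _, _, d in graph.edges(data=True):
            d["weight"] = 1.0
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist_csv":
        frame = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)],
            columns=["source", "target", "weight"],
        )
        frame.to_csv(path, index=False)
    else:
        lines = ["graph factors {"]
        for node, attrs in graph.nodes(data=True):
            cat = f' [category="{attrs["category"]}"]' if "category" in attrs else ""
            lines.append(f'  "{node}"{cat};')
        for u, v, d in graph.edges(data=True):
            lines.append(f'  "{u}" -- "{v}" [weight={d["weight"]:.6f}];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def plot_network(net: CorrelationNetwork, path, seed: int = 0) -> None:
    """Minimal spring-layout rendering with category colors; display aid only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = sorted({d.get("category", "") for _, d in net.graph.nodes(data=True)})
    palette = plt.get_cmap("tab10")
    color = {c: palette(i % 10) for i, c in enumerate(cats)}
    pos = nx.spring_layout(net.graph, seed=seed)
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(
        net.graph,
        pos=pos,
        ax=ax,
        node_color=[color[d.get("category", "")] for _, d in net.graph.nodes(data=True)],
        node_size=300,
        font_size=8,
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
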