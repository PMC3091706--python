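"""Thresholded Pearson co-expression network construction and diagnostics.

An edge connects two genes whose expression vectors correlate with
PCC >= tau (closed rule; an optional absolute-value mode edges on
|PCC| >= tau). Networks are undirected, unweighted for analysis purposes,
with the PCC retained as an edge annotation. Also provides the log-log
degree-distribution fit used as a scale-free diagnostic, annotation-based
network precision, and the threshold sweep that profiles a network family
over a grid of cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import topology
from .errors import (
    ConfigurationError,
    DegenerateDistributionError,
    InsufficientDataError,
    UndefinedMetricError,
)
from .synthetic import GeneSetCollection

__all__ = [
    "NetworkConfig",
    "pearson_matrix",
    "build_network",
    "degree_distribution_fit",
    "network_precision",
    "threshold_sweep",
    "non_isolated_nodes",
]

log = logging.getLogger(__name__)

#: default PCC cutoff for edge inclusion
DEFAULT_PCC_THRESHOLD = 0.70


@dataclass(frozen=True)
class NetworkConfig:
    """Edge-inclusion rule for co-expression networks.

    ``pcc_threshold`` (tau) must lie in (0, 1]; ``use_absolute_pcc`` switches
    from the default positive-only rule (PCC >= tau) to |PCC| >= tau;
    ``min_samples`` is the minimum sample count accepted for correlation.
    """

    pcc_threshold: float = DEFAULT_PCC_THRESHOLD
    use_absolute_pcc: bool = False
    min_samples: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.pcc_threshold <= 1.0):
            raise ConfigurationError(
                f"pcc_threshold must be in (0, 1], got {self.pcc_threshold}"
            )
        if self.min_samples < 3:
            raise ConfigurationError("min_samples must be >= 3")


def pearson_matrix(
    expr: pd.DataFrame, min_samples: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """All pairwise Pearson correlations between gene expression vectors.

    Returns the symmetric genes x genes correlation matrix restricted to
    genes with non-zero variance, plus the list of excluded zero-variance
    gene ids. Diagonal is exactly 1.
    """
    if expr.shape[1] < min_samples:
        raise InsufficientDataError(
            f"need >= {min_samples} samples, got {expr.shape[1]}"
        )
    if expr.isna().any().any():
        raise InsufficientDataError("expression matrix contains missing values")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    zero_var = sd == 0.0
    excluded = expr.index[zero_var].tolist()
    if excluded:
        log.warning(
            "excluding %d zero-variance genes from correlation: %s%s",
            len(excluded), excluded[:5], "..." if len(excluded) > 5 else "",
        )
    kept = expr.index[~zero_var]
    corr = np.corrcoef(values[~zero_var])
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return pd.DataFrame(corr, index=kept, columns=kept), excluded


def build_network(
    expr: pd.DataFrame, config: NetworkConfig | None = None
) -> nx.Graph:
    """Threshold the correlation matrix into an undirected simple graph.

    Nodes are all genes passing the variance check (isolated nodes are kept
    in the node set); an edge (i, j) exists iff PCC(i, j) >= tau — or
    |PCC| >= tau in absolute mode — and carries the PCC as its ``weight``.
    The graph records ``threshold`` and ``excluded_genes`` attributes.
    """
    config = config or NetworkConfig()
    corr, excluded = pearson_matrix(expr, config.min_samples)
    tau = config.pcc_threshold
    mat = corr.to_numpy()
    score = np.abs(mat) if config.use_absolute_pcc else mat
    iu, ju = np.triu_indices_from(mat, k=1)
    hit = score[iu, ju] >= tau
    genes = corr.index.to_numpy()
    g = nx.Graph(threshold=tau, use_absolute_pcc=config.use_absolute_pcc,
                 excluded_genes=excluded)
    g.add_nodes_from(genes.tolist())
    g.add_weighted_edges_from(
        (genes[i], genes[j], float(mat[i, j]))
        for i, j in zip(iu[hit], ju[hit])
    )
    log.info(
        "network at tau=%.3g: %d genes (%d with edges), %d edges",
        tau, g.number_of_nodes(),
        sum(1 for _, d in g.degree() if d > 0), g.number_of_edges(),
    )
    return g


def non_isolated_nodes(net: nx.Graph) -> list:
    """Genes with at least one co-expression link ("genes in the network")."""
    return [n for n, d in net.degree() if d > 0]


def degree_distribution_fit(net: nx.Graph) -> dict[str, float]:
    """Least-squares log10(count) vs log10(degree) fit of the degree histogram.

    Zero-degree nodes and empty bins are omitted. A markedly negative slope
    with high R^2 on a log-log plot is the classic (if rough) scale-free
    signature. Requires >= 3 distinct positive degrees.
    """
    degrees = np.array([d for _, d in net.degree() if d > 0])
    if degrees.size == 0:
        raise DegenerateDistributionError("no node has positive degree")
    values, counts = np.unique(degrees, return_counts=True)
    if values.size < 3:
        raise DegenerateDistributionError(
            f"only {values.size} distinct positive degrees; need >= 3"
        )
    x = np.log10(values)
    y = np.log10(counts)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {"slope": float(slope), "intercept": float(intercept), "r_squared": r2}


def network_precision(net: nx.Graph, annot: GeneSetCollection) -> float:
    """Fraction of network genes carrying at least one annotation.

    Genes that map to any term are counted as true positives; precision is
    true positives over all (non-isolated) network genes — a node-level
    specificity proxy, independent of edge structure.
    """
    genes = non_isolated_nodes(net)
    if not genes:
        raise UndefinedMetricError("network has no connected gene")
    annotated = annot.annotated_genes()
    return sum(1 for gidx in genes if gidx in annotated) / len(genes)


def threshold_sweep(
    source: pd.DataFrame | nx.Graph,
    tau_grid: list[float],
    annot: GeneSetCollection | None = None,
    config: NetworkConfig | None = None,
) -> pd.DataFrame:
    """Profile network structure over a grid of PCC cutoffs.

    ``source`` is either an expression matrix (a network is built per tau)
    or an already-weighted network (subgraphs are taken by re-thresholding
    its edge weights, which is equivalent and cheaper). Returns one row per
    tau with node count (non-isolated), edge count, mean betweenness, number
    of connected components, mean clustering coefficient and — when an
    annotation collection is supplied — network precision.
    """
    if len(tau_grid) == 0:
        raise ConfigurationError("tau grid is empty")
    if any(not (0.0 < t <= 1.0) for t in tau_grid):
        raise ConfigurationError("tau grid values must be in (0, 1]")

    if isinstance(source, nx.Graph):
        base = source
        use_abs = bool(base.graph.get("use_absolute_pcc", False))

        def net_at(tau: float) -> nx.Graph:
            g = nx.Graph(threshold=tau)
            g.add_nodes_from(base.nodes())
            for u, v, w in base.edges(data="weight"):
                s = abs(w) if use_abs else w
                if s >= tau:
                    g.add_edge(u, v, weight=w)
            return g
    else:
        base_config = config or NetworkConfig(pcc_threshold=min(tau_grid))

        def net_at(tau: float) -> nx.Graph:
            cfg = NetworkConfig(
                pcc_threshold=tau,
                use_absolute_pcc=base_config.use_absolute_pcc,
                min_samples=base_config.min_samples,
            )
            return build_network(source, cfg)

    rows = []
    for tau in tau_grid:
        g = net_at(tau)
        active = non_isolated_nodes(g)
        sub = g.subgraph(active)
        row = {
            "tau": tau,
            "n_genes": len(active),
            "n_edges": g.number_of_edges(),
        }
        if active:
            btw = topology.betweenness(sub)
            row["mean_betweenness"] = float(np.mean(list(btw.values())))
            row["n_components"] = nx.number_connected_components(sub)
            _, avg_cc = topology.clustering_coefficients(sub)
            row["mean_clustering"] = avg_cc
        else:
            row["mean_betweenness"] = float("nan")
            row["n_components"] = 0
            row["mean_clustering"] = float("nan")
        if annot is not None:
            row["precision"] = (
                network_precision(g, annot) if active else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
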