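"""Topological characterization, core extraction and hub-removal robustness.

Six standard descriptors are computed on the undirected simple graph: node
degree, betweenness centrality (unnormalized, over unordered pairs,
endpoints excluded, fractional credit across multiple shortest paths),
local clustering coefficient, connected components, characteristic path
length (average shortest-path distance over connected pairs) and an
"average-path diameter" — the same average-distance quantity exposed under
the diameter name, with the conventional max-eccentricity diameter reported
alongside. Disconnected node pairs are excluded from path-length averages
and their count reported, never assigned an arbitrary distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedMetricError

__all__ = [
    "TopologyProfile",
    "CoreParams",
    "RobustnessTrajectory",
    "betweenness",
    "clustering_coefficients",
    "connected_components",
    "characteristic_path_length",
    "paper_diameter",
    "topology_profile",
    "extract_core",
    "hub_removal",
]

log = logging.getLogger(__name__)

_LOG_FN = {"natural": math.log, "2": math.log2, "10": math.log10}


def betweenness(net: nx.Graph) -> dict:
    """Unnormalized shortest-path betweenness per node.

    For each unordered pair (s, t), a node v strictly between them receives
    credit sigma_st(v) / sigma_st — the fraction of shortest s-t paths
    passing through v. Leaves therefore always score 0.
    """
    return nx.betweenness_centrality(net, normalized=False)


def clustering_coefficients(net: nx.Graph) -> tuple[dict, float]:
    """Local clustering coefficient per node, plus its graph average.

    triangles through v / C(deg v, 2); nodes of degree < 2 score 0.
    The average is over all nodes (0 for the empty graph).
    """
    per_node = nx.clustering(net)
    avg = float(np.mean(list(per_node.values()))) if per_node else 0.0
    return per_node, avg


def connected_components(net: nx.Graph) -> list[set]:
    """Maximal connected subgraph node sets, largest first."""
    return sorted(nx.connected_components(net), key=len, reverse=True)


def _pairwise_distance_sums(net: nx.Graph) -> tuple[float, int, int]:
    """(sum of distances, connected unordered pairs, disconnected pairs)."""
    n = net.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    dist_sum = 0.0
    connected_pairs = 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        k = len(comp)
        connected_pairs += k * (k - 1) // 2
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            dist_sum += sum(dists.values())
    dist_sum /= 2.0  # each unordered pair counted twice
    return dist_sum, connected_pairs, total_pairs - connected_pairs


def characteristic_path_length(net: nx.Graph) -> tuple[float, int]:
    """Average shortest-path distance over connected unordered node pairs.

    Returns (CPL, number of excluded disconnected pairs). Raises
    :class:`UndefinedMetricError` when no pair of nodes is connected.
    """
    if net.number_of_nodes() < 2:
        raise UndefinedMetricError("need >= 2 nodes for a path length")
    dist_sum, connected_pairs, excluded = _pairwise_distance_sums(net)
    if connected_pairs == 0:
        raise UndefinedMetricError("no connected node pair")
    return dist_sum / connected_pairs, excluded


def paper_diameter(net: nx.Graph) -> float:
    """Average shortest path between pairs of nodes, exposed as "diameter".

    Some network studies label the *average* inter-node distance the network
    diameter; this function computes exactly that quantity (identical to
    :func:`characteristic_path_length`). The conventional longest-shortest-
    path diameter is available in :func:`topology_profile` as
    ``max_eccentricity_diameter``.
    """
    return characteristic_path_length(net)[0]


@dataclass
class TopologyProfile:
    """Per-node and graph-level topology summary."""

    per_node: pd.DataFrame  # columns: degree, betweenness, clustering
    n_nodes: int
    n_edges: int
    avg_degree: float
    n_connected_components: int
    avg_clustering: float
    characteristic_path_length: float | None
    paper_diameter: float | None
    max_eccentricity_diameter: int | None
    disconnected_pairs: int

    def graph_level(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "n_connected_components": self.n_connected_components,
            "avg_clustering": self.avg_clustering,
            "characteristic_path_length": self.characteristic_path_length,
            "paper_diameter": self.paper_diameter,
            "max_eccentricity_diameter": self.max_eccentricity_diameter,
            "disconnected_pairs": self.disconnected_pairs,
        }


def topology_profile(net: nx.Graph) -> TopologyProfile:
    """Compute the full per-node + graph-level descriptor set."""
    n = net.number_of_nodes()
    m = net.number_of_edges()
    btw = betweenness(net)
    cc, avg_cc = clustering_coefficients(net)
    degrees = dict(net.degree())
    per_node = pd.DataFrame(
        {
            "degree": pd.Series(degrees),
            "betweenness": pd.Series(btw),
            "clustering": pd.Series(cc),
        }
    ).sort_index()
    try:
        cpl, excluded = characteristic_path_length(net)
    except UndefinedMetricError:
        cpl, excluded = None, n * (n - 1) // 2 if n > 1 else 0
    ecc_diam: int | None = None
    if n > 0:
        comps = connected_components(net)
        ecc_diam = max(
            nx.diameter(net.subgraph(comp)) for comp in comps
        )
    return TopologyProfile(
        per_node=per_node,
        n_nodes=n,
        n_edges=m,
        avg_degree=(2.0 * m / n) if n else 0.0,
        n_connected_components=nx.number_connected_components(net),
        avg_clustering=avg_cc,
        characteristic_path_length=cpl,
        paper_diameter=cpl,
        max_eccentricity_diameter=ecc_diam,
        disconnected_pairs=excluded,
    )


@dataclass(frozen=True)
class CoreParams:
    """Thresholds defining the high-betweenness core and its hubs.

    Core nodes satisfy log(betweenness) > ``log_betweenness_threshold``
    (natural log by default; betweenness-0 nodes never qualify); hubs
    additionally satisfy degree > ``degree_threshold``.
    """

    log_betweenness_threshold: float = 6.0
    degree_threshold: int = 15
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if self.log_betweenness_threshold < 0 or self.degree_threshold < 0:
            raise ConfigurationError("core thresholds must be >= 0")
        if self.log_base not in _LOG_FN:
            raise ConfigurationError(
                f"log_base must be one of {sorted(_LOG_FN)}, got {self.log_base!r}"
            )


def extract_core(
    net: nx.Graph, params: CoreParams | None = None
) -> tuple[nx.Graph, set]:
    """Induced subgraph of topologically central nodes, plus the hub set.

    Returns ``(core_network, hubs)`` where the core contains every node with
    log(betweenness) above the threshold together with all internal edges,
    and hubs are the core nodes that also exceed the degree threshold.
    """
    params = params or CoreParams()
    logf = _LOG_FN[params.log_base]
    btw = betweenness(net)
    core_nodes = {
        v for v, b in btw.items()
        if b > 0 and logf(b) > params.log_betweenness_threshold
    }
    degrees = dict(net.degree())
    hubs = {v for v in core_nodes if degrees[v] > params.degree_threshold}
    core = nx.Graph(net.subgraph(core_nodes))
    core.graph["core_params"] = params
    log.info(
        "core: %d / %d nodes, %d internal edges, %d hubs",
        len(core_nodes), net.number_of_nodes(), core.number_of_edges(), len(hubs),
    )
    return core, hubs


@dataclass
class RobustnessTrajectory:
    """Metric trajectory of a node-removal experiment.

    ``steps`` has one row per recorded state (row 0 = intact graph) with
    columns n_removed, avg_betweenness, characteristic_path_length (NaN when
    no connected pair remains), n_components.
    """

    removal_order: list
    steps: pd.DataFrame
    mode: str
    seed: int | None = None


def hub_removal(
    net: nx.Graph,
    k: int = 200,
    mode: str = "targeted",
    seed: int | None = None,
    recompute_metrics_every: int = 1,
    recompute_ranking: bool = False,
) -> RobustnessTrajectory:
    """Remove k nodes and track average betweenness, CPL and components.

    ``targeted`` mode removes nodes in descending order of their degree in
    the *intact* graph (ties broken by gene id), modelling an attack on the
    pre-identified hub list; ``random`` removes k uniformly sampled nodes.
    Metrics are recorded for the intact graph and after every
    ``recompute_metrics_every`` removals (and always after the last).
    ``recompute_ranking`` re-sorts the remaining targets by current degree
    after each removal (adaptive attack) instead of the frozen ranking.
    """
    n = net.number_of_nodes()
    if k >= n:
        raise ConfigurationError(f"k={k} must be < number of nodes ({n})")
    if mode not in ("targeted", "random"):
        raise ConfigurationError(f"mode must be 'targeted' or 'random', got {mode!r}")
    if recompute_metrics_every < 1:
        raise ConfigurationError("recompute_metrics_every must be >= 1")

    if mode == "targeted":
        ranked = sorted(net.degree(), key=lambda kv: (-kv[1], str(kv[0])))
        order = [v for v, _ in ranked[:k]]
    else:
        rng = np.random.default_rng(seed)
        nodes = sorted(net.nodes(), key=str)
        order = [nodes[i] for i in rng.choice(n, size=k, replace=False)]

    work = nx.Graph(net)

    def record(n_removed: int) -> dict:
        btw = betweenness(work)
        avg_btw = float(np.mean(list(btw.values()))) if btw else float("nan")
        try:
            cpl, _ = characteristic_path_length(work)
        except UndefinedMetricError:
            cpl = float("nan")
        return {
            "n_removed": n_removed,
            "avg_betweenness": avg_btw,
            "characteristic_path_length": cpl,
            "n_components": nx.number_connected_components(work)
            if work.number_of_nodes() else 0,
        }

    rows = [record(0)]
    removed: list = []
    for i in range(k):
        if mode == "targeted" and recompute_ranking:
            # adaptive attack: highest current degree, ties by id
            target = sorted(work.degree(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]
        else:
            target = order[i]
        work.remove_node(target)
        removed.append(target)
        if (i + 1) % recompute_metrics_every == 0 or i == k - 1:
            rows.append(record(i + 1))
    return RobustnessTrajectory(
        removal_order=removed,
        steps=pd.DataFrame(rows),
        mode=mode,
        seed=seed,
    )
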