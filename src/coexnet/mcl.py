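"""Markov Cluster Algorithm (MCL): graph clustering by stochastic flow.

MCL simulates random-walk flow on the graph: the (self-loop augmented)
adjacency matrix is column-normalized, then *expansion* (matrix power,
spreading flow along walks) alternates with *inflation* (entrywise power
followed by column renormalization, amplifying strong flows and starving
weak ones) until the flow stabilizes. In the limit matrix the flow collects
at attractor nodes; each attractor together with the nodes whose flow it
captures forms a cluster. Higher inflation fragments flow earlier and
yields finer clusterings.

The operator runs on the dense column-stochastic matrix with optional
pruning of tiny entries (set to zero, columns renormalized) to keep the
intermediate matrices tractable; on toy graphs with pruning disabled the
iteration is the exact textbook process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigurationError

__all__ = ["MCLParams", "ClusterSet", "mcl", "filter_clusters"]

log = logging.getLogger(__name__)

#: flow below this is treated as zero when reading clusters off the limit matrix
_ATTRACTOR_EPS = 1e-8


@dataclass(frozen=True)
class MCLParams:
    """MCL tuning parameters.

    inflation:
        Entrywise power of the inflation step (> 1); the main granularity
        knob. Default 1.3 (coarse clusters).
    expansion:
        Matrix-power of the expansion step; 2 is the canonical choice.
    self_loop_weight:
        Weight added on the diagonal before normalization; stabilizes the
        iteration for bipartite-like structures.
    prune_threshold:
        Entries below this are zeroed (then columns renormalized) after each
        inflation; 0 disables pruning.
    max_iterations / convergence_tol:
        Iteration stops when the max entrywise change between successive
        matrices falls below the tolerance, or at the iteration cap.
    min_cluster_size_for_enrichment:
        Cluster-size floor applied before functional enrichment.
    """

    inflation: float = 1.3
    expansion: int = 2
    self_loop_weight: float = 1.0
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-8
    min_cluster_size_for_enrichment: int = 10

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ConfigurationError("inflation must be > 1")
        if self.expansion < 2:
            raise ConfigurationError("expansion must be >= 2")
        if self.self_loop_weight < 0 or self.prune_threshold < 0:
            raise ConfigurationError("self_loop_weight and prune_threshold must be >= 0")
        if self.convergence_tol <= 0:
            raise ConfigurationError("convergence_tol must be > 0")


@dataclass
class ClusterSet:
    """A partition of the node set into clusters.

    ``clusters`` are disjoint gene lists covering every node, sorted by
    descending size (ties by smallest member id); ``n_dropped`` counts
    clusters removed by :func:`filter_clusters`.
    """

    clusters: list[list]
    params: MCLParams | None
    n_iterations: int
    converged: bool
    n_dropped: int = 0

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)

    def labels(self) -> dict:
        """gene id -> 0-based cluster index (clusters sorted by size)."""
        return {g: i for i, c in enumerate(self.clusters) for g in c}


def _normalize_columns(mat: np.ndarray) -> None:
    sums = mat.sum(axis=0)
    sums[sums == 0.0] = 1.0
    mat /= sums


def mcl(
    net: nx.Graph,
    params: MCLParams | None = None,
    weighted: bool = False,
) -> ClusterSet:
    """Cluster a graph by Markov flow simulation.

    Runs on the unweighted 0/1 adjacency by default (pass ``weighted=True``
    to use ``weight`` edge attributes). Returns a full partition of the node
    set; a result that hit ``max_iterations`` without converging is returned
    with ``converged=False`` and a warning.
    """
    params = params or MCLParams()
    if net.number_of_nodes() == 0:
        raise ConfigurationError("cannot cluster an empty graph")
    nodes = sorted(net.nodes(), key=str)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)

    mat = np.zeros((n, n))
    for u, v, data in net.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        mat[index[u], index[v]] = w
        mat[index[v], index[u]] = w
    np.fill_diagonal(mat, params.self_loop_weight)
    _normalize_columns(mat)

    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        prev = mat
        mat = np.linalg.matrix_power(mat, params.expansion)
        np.power(mat, params.inflation, out=mat)
        if params.prune_threshold > 0:
            mat[mat < params.prune_threshold] = 0.0
        _normalize_columns(mat)
        if np.max(np.abs(mat - prev)) < params.convergence_tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge within %d iterations", params.max_iterations)

    clusters = _read_clusters(mat, nodes)
    return ClusterSet(
        clusters=clusters, params=params, n_iterations=it, converged=converged
    )


def _read_clusters(mat: np.ndarray, nodes: list) -> list[list]:
    """Extract the partition from the (near-)limit flow matrix.

    Attractors are nodes retaining flow on the diagonal; attractors whose
    rows overlap (shared flow) form one attractor system. Every node joins
    the system of the attractor that captures most of its column flow —
    a node drawn by several systems (rare overlap) goes to the strongest,
    ties to the lowest-indexed system — so the output is always a partition.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if mat[i, i] > _ATTRACTOR_EPS]
    if not attractors:
        # flow collapsed without a stable diagonal (non-converged edge case):
        # fall back to rows with any mass
        attractors = [i for i in range(n) if mat[i].max() > _ATTRACTOR_EPS]
    if not attractors:
        return [sorted(nodes, key=str)] if n else []

    # union attractors sharing support into attractor systems
    parent = list(range(len(attractors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    pos = {a: k for k, a in enumerate(attractors)}
    for k, a in enumerate(attractors):
        row = mat[a]
        for b in attractors:
            if b != a and row[b] > _ATTRACTOR_EPS:
                union(k, pos[b])

    system_of = {a: find(k) for k, a in enumerate(attractors)}
    systems = sorted(set(system_of.values()))
    sys_index = {s: i for i, s in enumerate(systems)}

    assignment = np.full(n, -1, dtype=int)
    attr_rows = mat[attractors, :]  # flow from column j captured by attractor a
    for j in range(n):
        flows = attr_rows[:, j]
        best = int(np.argmax(flows))
        if flows[best] <= _ATTRACTOR_EPS:
            # no attractor captures j (numerical edge case): keep j with the
            # attractor system of its strongest row entry overall
            best = int(np.argmax(flows))
        assignment[j] = sys_index[system_of[attractors[best]]]

    groups: dict[int, list] = {}
    for j, s in enumerate(assignment):
        groups.setdefault(int(s), []).append(nodes[j])
    clusters = [sorted(g, key=str) for g in groups.values()]
    clusters.sort(key=lambda c: (-len(c), str(c[0])))
    return clusters


def filter_clusters(cs: ClusterSet, min_size: int = 10) -> ClusterSet:
    """Keep clusters with >= min_size genes; count the dropped ones."""
    kept = [c for c in cs.clusters if len(c) >= min_size]
    dropped = len(cs.clusters) - len(kept)
    if not kept:
        log.warning("no cluster reaches min_size=%d", min_size)
    return ClusterSet(
        clusters=kept,
        params=cs.params,
        n_iterations=cs.n_iterations,
        converged=cs.converged,
        n_dropped=cs.n_dropped + dropped,
    )
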