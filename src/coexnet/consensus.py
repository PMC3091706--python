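"""Consensus ("Conserved") network from multiple co-expression networks.

A link is a consensus link if the same unordered gene pair is an edge in
every input network; edge weights are ignored for identity. The conserved
node set is defined as the endpoints of conserved edges (so every conserved
gene carries at least one conserved link); the plain node-set intersection
is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .errors import ConfigurationError

__all__ = ["ConsensusResult", "intersect_networks", "network_overlap"]

log = logging.getLogger(__name__)


def _edge_set(net: nx.Graph) -> set[frozenset]:
    return {frozenset((u, v)) for u, v in net.edges()}


def _non_isolated(net: nx.Graph) -> set:
    return {n for n, d in net.degree() if d > 0}


@dataclass
class ConsensusResult:
    """Output of the consensus intersection.

    ``conserved`` holds only genes incident to >= 1 conserved edge;
    ``pairwise_overlaps`` maps dataset-index pairs to shared (non-isolated)
    gene and shared edge counts; ``node_intersection_size`` counts genes
    present (non-isolated) in every input, independent of consensus edges.
    """

    conserved: nx.Graph
    pairwise_overlaps: dict[tuple[int, int], dict[str, int]]
    gene_universe: frozenset
    node_intersection_size: int

    @property
    def n_genes(self) -> int:
        return self.conserved.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.conserved.number_of_edges()


def network_overlap(a: nx.Graph, b: nx.Graph) -> tuple[int, int]:
    """(shared gene count, shared edge count) between two networks.

    Shared genes are counted over non-isolated nodes; shared edges over
    unordered gene pairs, ignoring weights.
    """
    shared_genes = len(_non_isolated(a) & _non_isolated(b))
    shared_edges = len(_edge_set(a) & _edge_set(b))
    return shared_genes, shared_edges


def intersect_networks(nets: list[nx.Graph]) -> ConsensusResult:
    """Intersect >= 2 networks into the consensus network.

    The consensus edge set is the intersection of all input edge sets; the
    consensus node set comprises the endpoints of those edges. Pairwise
    gene/edge overlaps are computed for every input pair. An empty
    gene-universe intersection produces an empty (warned) result rather
    than an error.
    """
    if len(nets) < 2:
        raise ConfigurationError(f"need >= 2 networks, got {len(nets)}")
    universe = frozenset.intersection(
        *(frozenset(net.nodes()) for net in nets)
    )
    if not universe:
        log.warning("gene universes of the input networks do not intersect")
    edges = set.intersection(*(_edge_set(net) for net in nets))
    conserved = nx.Graph()
    for pair in edges:
        u, v = sorted(pair, key=str)
        conserved.add_edge(u, v)
    # carry the (minimum) threshold annotation through when present
    taus = [net.graph.get("threshold") for net in nets]
    if all(t is not None for t in taus):
        conserved.graph["threshold"] = min(taus)

    overlaps: dict[tuple[int, int], dict[str, int]] = {}
    for i, j in combinations(range(len(nets)), 2):
        genes, shared_edges = network_overlap(nets[i], nets[j])
        overlaps[(i, j)] = {"shared_genes": genes, "shared_edges": shared_edges}

    node_intersection = frozenset.intersection(
        *(frozenset(_non_isolated(net)) for net in nets)
    )
    log.info(
        "consensus: %d genes, %d edges (node-set intersection: %d genes)",
        conserved.number_of_nodes(), conserved.number_of_edges(),
        len(node_intersection),
    )
    return ConsensusResult(
        conserved=conserved,
        pairwise_overlaps=overlaps,
        gene_universe=universe,
        node_intersection_size=len(node_intersection),
    )
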