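"""Degree-preserving randomization and consensus significance testing.

Networks are randomized by Maslov–Sneppen double-edge swaps: two edges
(a, b) and (c, d) are replaced by (a, d) and (c, b), which leaves every
node's degree unchanged. A swap is attempted 4 x |E| times by default
(rejected attempts — those that would create a self-loop or parallel edge —
count toward the total), destroying specific edge identities while
preserving the degree sequence exactly.

The significance of an observed consensus is assessed by independently
rewiring every input network per replicate, recording the randomized
consensus gene count, and expressing the observed count as a z-score
against the replicate distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .consensus import intersect_networks
from .errors import ConfigurationError

__all__ = ["NullModelParams", "NullModelResult", "rewire", "null_intersection"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullModelParams:
    """Randomization settings.

    ``swap_multiplier`` x |E| double-edge swaps are *attempted* per network;
    ``n_replicates`` randomized network sets are drawn; ``seed`` feeds a
    master stream from which each replicate derives an independent,
    order-independent substream.
    """

    swap_multiplier: int = 4
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swap_multiplier < 1:
            raise ConfigurationError("swap_multiplier must be >= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")


def rewire(
    net: nx.Graph,
    params: NullModelParams | None = None,
    rng: np.random.Generator | None = None,
) -> nx.Graph:
    """Degree-preserving randomization by attempted double-edge swaps.

    Attempts ``swap_multiplier * |E|`` swaps; each is accepted only if the
    result stays a simple graph. Graphs admitting no legal swap (stars,
    triangles) come back unchanged with a logged notice. Node degrees are
    preserved exactly by construction.
    """
    params = params or NullModelParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    m = net.number_of_edges()
    if m < 2:
        log.info("fewer than 2 edges; nothing to rewire")
        return nx.Graph(net)

    nodes = list(net.nodes())
    edges = [tuple(e) for e in net.edges()]
    edge_set = {frozenset(e) for e in edges}
    n_attempts = params.swap_multiplier * m
    accepted = 0

    idx = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.integers(0, 2, size=(n_attempts, 2))
    for (i, j), (fi, fj) in zip(idx, flips):
        if i == j:
            continue
        a, b = edges[i]
        if fi:
            a, b = b, a
        c, d = edges[j]
        if fj:
            c, d = d, c
        # proposed swap: (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue  # self-loop
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue  # parallel edge
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1

    if accepted == 0:
        log.info(
            "no legal swap found in %d attempts; returning the input unchanged",
            n_attempts,
        )
        out = nx.Graph(net)
    else:
        out = nx.Graph()
        out.add_nodes_from(nodes)
        out.add_edges_from(edges)
        out.graph.update(net.graph)
    out.graph["n_swap_attempts"] = n_attempts
    out.graph["n_swaps_accepted"] = accepted
    return out


@dataclass
class NullModelResult:
    """Randomized-intersection distribution and the observed z-score.

    ``z_score`` is (observed - null_mean) / null_sd with the sample (n-1)
    standard deviation; it is None when null_sd is 0 (degenerate null), in
    which case the raw replicate distribution is still available.
    """

    replicate_sizes: list[int]
    null_mean: float
    null_sd: float
    observed: int
    z_score: float | None
    replicate_edge_counts: list[int] | None = None
    observed_edges: int | None = None


def null_intersection(
    nets: list[nx.Graph],
    params: NullModelParams | None = None,
) -> NullModelResult:
    """Distribution of the consensus gene count under degree-preserving nulls.

    Per replicate, every input network is independently rewired and the
    randomized consensus gene count (endpoints of conserved edges) recorded;
    consensus edge counts are recorded alongside. The observed consensus of
    the unrandomized inputs is then scored as
    z = (observed - mean) / sd over the replicates.
    """
    if len(nets) < 2:
        raise ConfigurationError(f"need >= 2 networks, got {len(nets)}")
    params = params or NullModelParams()
    observed_result = intersect_networks(nets)
    observed = observed_result.n_genes

    master = np.random.SeedSequence(params.seed)
    children = master.spawn(params.n_replicates)
    sizes: list[int] = []
    edge_counts: list[int] = []
    for child in children:
        rng = np.random.default_rng(child)
        rewired = [rewire(net, params, rng=rng) for net in nets]
        res = intersect_networks(rewired)
        sizes.append(res.n_genes)
        edge_counts.append(res.n_edges)

    null_mean = float(np.mean(sizes))
    null_sd = float(np.std(sizes, ddof=1))
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
    else:
        z = None
        log.warning("null distribution is degenerate (sd = 0); z undefined")
    log.info(
        "null intersection: observed=%d, null mean=%.1f sd=%.1f, z=%s",
        observed, null_mean, null_sd, f"{z:.2f}" if z is not None else "undefined",
    )
    return NullModelResult(
        replicate_sizes=sizes,
        null_mean=null_mean,
        null_sd=null_sd,
        observed=observed,
        z_score=z,
        replicate_edge_counts=edge_counts,
        observed_edges=observed_result.n_edges,
    )
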