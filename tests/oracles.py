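"""Independent brute-force oracles used to verify the package's graph and
statistics code. Everything here is deliberately naive — exhaustive path
enumeration, explicit summation formulas, dense textbook iterations — and
shares no code path with the implementation under test."""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------- pearson
def pearson_sigma_formula(x, y) -> float:
    """Two-pass textbook PCC: sums of products of deviations."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x)) * math.sqrt(
        sum((yi - my) ** 2 for yi in y)
    )
    return num / den


# ------------------------------------------------------- shortest paths
def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest s-t paths by BFS layering + DFS back-walk."""
    dist = {s: 0}
    parents: dict = {s: []}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parents[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                parents[v].append(u)
    if t not in dist:
        return []
    paths = []

    def walk(node, acc):
        if node == s:
            paths.append(list(reversed(acc + [s])))
            return
        for p in parents[node]:
            walk(p, acc + [node])

    walk(t, [])
    return paths


def brute_betweenness(nodes, edges) -> dict:
    """Unnormalized betweenness: for every unordered pair, fractional count
    of shortest paths through each intermediate vertex."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for mid in path[1:-1]:
                btw[mid] += 1.0 / len(paths)
    return btw


def brute_distances(nodes, edges) -> dict:
    """BFS distance for every unordered pair; disconnected pairs absent."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for s in nodes:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for t, d in dist.items():
            if s < t:
                out[(s, t)] = d
    return out


def brute_cpl(nodes, edges) -> tuple[float, int]:
    """(average distance over connected pairs, disconnected pair count)."""
    dists = brute_distances(nodes, edges)
    n = len(nodes)
    total_pairs = n * (n - 1) // 2
    connected = {k: v for k, v in dists.items() if v > 0}
    if not connected:
        return float("nan"), total_pairs
    return sum(connected.values()) / len(connected), total_pairs - len(connected)


def brute_clustering(nodes, edges) -> dict:
    """Triangle enumeration: per-node local clustering coefficient."""
    adj = {v: set() for v in nodes}
    eset = set()
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
        eset.add(frozenset((u, v)))
    cc = {}
    for v in nodes:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            cc[v] = 0.0
            continue
        tri = sum(
            1
            for a, b in itertools.combinations(nbrs, 2)
            if frozenset((a, b)) in eset
        )
        cc[v] = tri / (k * (k - 1) / 2)
    return cc


def brute_components(nodes, edges) -> list[set]:
    """Union-find connected components."""
    parent = {v: v for v in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    return sorted(comps.values(), key=lambda s: (-len(s), sorted(map(str, s))))


# ------------------------------------------------------------ reference MCL
def reference_mcl(nodes, edges, inflation=2.0, expansion=2, self_loop=1.0,
                  max_iter=300, tol=1e-10):
    """Textbook dense Markov clustering, written independently of the
    package: no pruning, explicit column loops, and cluster read-out by
    merging overlapping attractor-row supports (connected components over
    row supports) rather than strongest-attractor assignment."""
    nodes = sorted(nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v in edges:
        m[index[u], index[v]] = 1.0
        m[index[v], index[u]] = 1.0
    for i in range(n):
        m[i, i] = self_loop
    for j in range(n):
        s = m[:, j].sum()
        if s > 0:
            m[:, j] /= s
    for _ in range(max_iter):
        prev = m.copy()
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        for j in range(n):
            s = m[:, j].sum()
            if s > 0:
                m[:, j] /= s
        if np.abs(m - prev).max() < tol:
            break
    # read-out: rows with support define proto-clusters; merge overlaps
    eps = 1e-6
    proto = []
    for i in range(n):
        support = set(np.nonzero(m[i] > eps)[0].tolist())
        if support:
            proto.append(support)
    merged: list[set] = []
    for s in proto:
        hits = [c for c in merged if c & s]
        for c in hits:
            merged.remove(c)
            s = s | c
        merged.append(s)
    covered = set().union(*merged) if merged else set()
    for j in range(n):
        if j not in covered:
            merged.append({j})
    clusters = [sorted(nodes[i] for i in c) for c in merged]
    clusters.sort(key=lambda c: (-len(c), str(c[0])))
    return clusters


def labels_from_clusters(clusters, nodes) -> list[int]:
    lab = {}
    for i, c in enumerate(clusters):
        for g in c:
            lab[g] = i
    return [lab[v] for v in sorted(nodes, key=str)]
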