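"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
identity is counted with a character-by-character double loop, and all graph
measures are derived from a hand-rolled BFS plus exhaustive shortest-path
enumeration.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np
import pytest

from culturemap.synthetic import SimConfig, generate_bundle

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# naive identity oracle
# ---------------------------------------------------------------------------


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_sliding_identity(query: str, subject: str):
    """Exhaustive double loop over every offset and both strands.

    Returns (identity, offset, strand) with the same tie-break conventions as
    the library (smallest offset, forward preferred), or None when the query
    is longer than the subject.
    """
    if len(query) > len(subject):
        return None
    best = (-1, None, None)
    for strand, q in (("forward", query), ("reverse", naive_revcomp(query))):
        for off in range(len(subject) - len(query) + 1):
            matches = 0
            for a, b in zip(q, subject[off : off + len(q)]):
                if a == b and a != "N":
                    matches += 1
            if matches > best[0]:
                best = (matches, off, strand)
    return 100.0 * best[0] / len(query), best[1], best[2]


# ---------------------------------------------------------------------------
# BFS graph oracles (operate on adjacency dicts)
# ---------------------------------------------------------------------------


def adjacency(network) -> dict:
    g = network.graph
    return {v: sorted(g.neighbors(v)) for v in g.nodes}


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """All shortest s-t paths, by DFS constrained to decreasing distance to t."""
    dist_t = bfs_distances(adj, t)
    if s not in dist_t:
        return []
    paths = []

    def walk(v, acc):
        if v == t:
            paths.append(tuple(acc))
            return
        for w in adj[v]:
            if w in dist_t and dist_t[w] == dist_t[v] - 1:
                walk(w, acc + [w])

    walk(s, [s])
    return paths


def oracle_betweenness(adj: dict) -> dict:
    comps = _components(adj)
    out = {}
    for comp in comps:
        n = len(comp)
        for v in comp:
            if n < 3:
                out[v] = 0.0
                continue
            total = 0.0
            for s, t in combinations(sorted(comp), 2):
                if v in (s, t):
                    continue
                paths = enumerate_shortest_paths(adj, s, t)
                if paths:
                    total += sum(v in p for p in paths) / len(paths)
            out[v] = 2.0 * total / ((n - 1) * (n - 2))
    return out


def _components(adj: dict) -> list[set]:
    seen, comps = set(), []
    for v in adj:
        if v not in seen:
            comp = set(bfs_distances(adj, v))
            seen |= comp
            comps.append(comp)
    return comps


def oracle_closeness(adj: dict) -> dict:
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(d for d in dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def oracle_radiality(adj: dict) -> dict:
    out = {}
    for comp in _components(adj):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        diam = max(
            max(bfs_distances(adj, v).values()) for v in comp
        )
        for v in comp:
            dist = bfs_distances(adj, v)
            out[v] = sum(diam + 1 - d for w, d in dist.items() if w != v) / (
                len(comp) - 1
            )
    return out


def oracle_neighborhood_connectivity(adj: dict) -> dict:
    deg = {v: len(adj[v]) for v in adj}
    return {
        v: (sum(deg[w] for w in adj[v]) / len(adj[v]) if adj[v] else float("nan"))
        for v in adj
    }


def oracle_avg_path_length(adj: dict) -> dict:
    out = {}
    for v in adj:
        dist = [d for w, d in bfs_distances(adj, v).items() if w != v]
        out[v] = sum(dist) / len(dist) if dist else float("nan")
    return out


def oracle_nearest_hub(adj: dict, hubs) -> dict:
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        reach = [dist[h] for h in hubs if h in dist]
        out[v] = float(min(reach)) if reach else float("nan")
    return out


def random_network(rng: np.random.Generator, n: int, p: float):
    """A random signed InteractionNetwork over n nodes (isolated nodes kept)."""
    from culturemap.network import InteractionNetwork

    net = InteractionNetwork()
    nodes = [f"n{i:02d}" for i in range(n)]
    for v in nodes:
        net.add_node(v, cultured=bool(rng.random() < 0.4))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                sign = "+" if rng.random() < 0.9 else "-"
                net.add_edge(nodes[i], nodes[j], sign, float(rng.uniform(0.1, 1.0)))
    return net


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


SMALL_CONFIG = dict(
    n_species=300,
    n_samples=12,
    depth_per_sample=5000,
    n_isolates=40,
    n_network_nodes=60,
    edge_density=0.05,
    n_hubs=4,
    seed=4,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic bundle shared across tests (fixed seed)."""
    return generate_bundle(SimConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    from culturemap.synthetic import write_bundle

    out = tmp_path_factory.mktemp("bundle")
    write_bundle(SimConfig(**SMALL_CONFIG), out)
    return out
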