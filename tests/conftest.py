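"""Shared fixtures: small hand-built graphs and random-graph helpers."""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from pdod import SignedDigraph, build_graph


def enumerate_shortest_path_parity(
    graph: SignedDigraph, source: str, target: str
) -> tuple[float, int, int]:
    """Independent oracle: exhaustive DFS enumeration of all minimal-length
    directed paths, tallied by inhibition-edge parity.

    Walks of length exactly dist(source, target) are precisely the shortest
    paths, so a depth-bounded DFS over signed out-edges enumerates them all
    (parallel signed edges count as distinct steps).
    """
    out: dict[str, list[tuple[str, int]]] = {}
    for u, v, s in graph.edges():
        out.setdefault(u, []).append((v, s))
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v, _ in out.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if target not in dist:
        return math.inf, 0, 0
    length = dist[target]
    tally = [0, 0]

    def dfs(node: str, depth: int, odd: int) -> None:
        if depth == length:
            if node == target:
                tally[odd] += 1
            return
        for nxt, sign in out.get(node, []):
            dfs(nxt, depth + 1, odd ^ (sign == -1))

    dfs(source, 0, 0)
    return length, tally[0], tally[1]


def random_signed_graph(rng: np.random.Generator, n_nodes: int, p: float) -> SignedDigraph:
    """Small Erdos-Renyi-style signed digraph for property tests."""
    names = [f"n{i}" for i in range(n_nodes)]
    records = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p:
                records.append((names[i], names[j], -1 if rng.random() < 0.4 else 1))
    graph = build_graph(records) if records else SignedDigraph()
    for name in names:
        graph.add_node(name)
    return graph


@pytest.fixture
def chain_graph() -> SignedDigraph:
    """A -(+1)-> X -(-1)-> B: one inhibition-like 2-hop path."""
    return build_graph([("A", "X", 1), ("X", "B", -1)])


@pytest.fixture
def diamond_graph() -> SignedDigraph:
    """Two all-activation 2-hop paths A->B."""
    return build_graph([("A", "X", 1), ("X", "B", 1), ("A", "Y", 1), ("Y", "B", 1)])


@pytest.fixture
def conflicted_fan_graph() -> SignedDigraph:
    """Nine 2-edge shortest paths r->g: eight activation-like, one inhibition-like."""
    records = []
    for i in range(8):
        records.append(("r", f"m{i}", 1))
        records.append((f"m{i}", "g", 1))
    records.append(("r", "m8", 1))
    records.append(("m8", "g", -1))
    return build_graph(records)
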