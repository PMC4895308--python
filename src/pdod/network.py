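"""Signed directed molecular networks and conflict-adjusted distances.

The central object is a directed multigraph of genes whose edges carry a
sign: ``+1`` for activation-like relations (activation, expression) and
``-1`` for inhibition-like relations (inhibition, repression).  Between an
ordered gene pair there may be several shortest paths whose net effects
disagree -- some paths activate the endpoint, some inhibit it -- a situation
called a *conflict*.  The conflict-adjusted distance

    d_c(r, g) = (n_a + n_i) / (n_a - n_i) * |d(r, g)|

keeps the hop distance ``|d(r, g)|`` when the shortest paths agree, inflates
it as the activation-like count ``n_a`` and inhibition-like count ``n_i``
approach each other, and becomes infinite when they tie or the pair is
unreachable.  A shortest path is activation-like when its number of
inhibition-signed edges is even (zero included), inhibition-like when odd.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SignedDigraph",
    "PathParityCount",
    "ConflictDistance",
    "build_graph",
    "shortest_path_parity",
    "parity_from_source",
    "conflict_distance",
    "load_edge_table",
    "EFFECT_SIGNS",
]

#: Mapping of relation effect names to edge signs.
EFFECT_SIGNS: Mapping[str, int] = {
    "activation": 1,
    "expression": 1,
    "inhibition": -1,
    "repression": -1,
}


class SignedDigraph:
    """Directed multigraph of genes with ±1 edge signs.

    Parallel edges between the same ordered pair are retained when their
    signs differ (conflicting curated assertions); duplicate identical
    edges collapse to one.  Node identifiers are opaque, case-sensitive
    strings.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        if not isinstance(node, str) or not node:
            raise ValueError(f"node id must be a non-empty string, got {node!r}")
        self._g.add_node(node)

    def add_edge(self, source: str, target: str, sign: int) -> None:
        if sign not in (1, -1):
            raise ValueError(
                f"edge ({source!r}, {target!r}, {sign!r}): sign must be +1 or -1"
            )
        for node in (source, target):
            self.add_node(node)
        # collapse exact duplicates; keep opposite-sign parallels
        if not self._g.has_edge(source, target, key=sign):
            self._g.add_edge(source, target, key=sign, sign=sign)

    # -- queries -------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self._g.edges(data=True)]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def out_edges(self, node: str) -> Iterable[tuple[str, int]]:
        for _, v, d in self._g.out_edges(node, data=True):
            yield v, d["sign"]

    def degree(self, node: str) -> int:
        """Total degree (in + out, counting parallel edges)."""
        return self._g.in_degree(node) + self._g.out_degree(node)

    def to_networkx(self) -> nx.MultiDiGraph:
        """The underlying networkx multigraph (shared, do not mutate)."""
        return self._g

    def undirected_unsigned(self) -> nx.Graph:
        """Simple undirected projection, signs and directions dropped."""
        return nx.Graph(self._g.to_undirected(as_view=False))

    def __repr__(self) -> str:  # pragma: no cover
        return f"SignedDigraph({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class PathParityCount:
    """Shortest-path census between one ordered gene pair.

    ``hop_distance`` is the unweighted shortest-path length (``math.inf``
    when unreachable); ``n_activation_like`` / ``n_inhibition_like`` count
    the shortest paths with an even / odd number of inhibition edges.
    """

    hop_distance: float
    n_activation_like: int
    n_inhibition_like: int

    def __post_init__(self) -> None:
        if math.isinf(self.hop_distance):
            if self.n_activation_like or self.n_inhibition_like:
                raise ValueError("unreachable pair must have zero path counts")
        elif self.n_activation_like + self.n_inhibition_like < 1:
            raise ValueError("reachable pair must have at least one shortest path")


@dataclass(frozen=True)
class ConflictDistance:
    """Conflict-adjusted distance d_c.

    ``value`` is finite iff the pair is reachable and the parity classes do
    not tie; otherwise it is ``math.inf`` (sign undefined, any distance
    kernel must evaluate to 0).  ``sign`` is +1 when activation-like paths
    dominate, -1 when inhibition-like paths dominate, and +1 at the hop-0
    degenerate case (a drug target that is itself the disease gene).
    """

    value: float
    is_reachable: bool

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.value)

    @property
    def sign(self) -> int:
        return -1 if self.value < 0 else 1


INFINITE_DISTANCE = ConflictDistance(value=math.inf, is_reachable=False)


def build_graph(edge_records: Iterable[tuple[str, str, int]]) -> SignedDigraph:
    """Assemble a :class:`SignedDigraph` from ``(source, target, sign)`` records.

    Duplicate identical records collapse to a single edge; opposite-sign
    parallels between the same ordered pair are both kept.  Malformed
    records (missing fields, sign outside {+1, -1}) are rejected naming the
    offending record.
    """
    graph = SignedDigraph()
    for rec in edge_records:
        try:
            source, target, sign = rec
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge record {rec!r}") from exc
        graph.add_edge(source, target, sign)
    return graph


def parity_from_source(graph: SignedDigraph, source: str) -> dict[str, PathParityCount]:
    """Single-source shortest-path parity census to every reachable node.

    Layered breadth-first dynamic programming over (node, parity) states:
    each node at BFS depth ``d`` accumulates the number of length-``d``
    paths with an even and an odd count of inhibition edges.  Parallel
    signed edges count as distinct steps.  Equivalent to exhaustively
    enumerating all minimal-length directed paths, without the
    combinatorial blow-up in dense conflict regions.
    """
    if source not in graph:
        raise KeyError(f"unknown node id {source!r}")
    dist: dict[str, int] = {source: 0}
    even: dict[str, int] = {source: 1}
    odd: dict[str, int] = {source: 0}
    queue: deque[str] = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v, sign in graph.out_edges(u):
            if v not in dist:
                dist[v] = du + 1
                even[v] = odd[v] = 0
                queue.append(v)
            if dist[v] == du + 1:
                if sign == 1:
                    even[v] += even[u]
                    odd[v] += odd[u]
                else:
                    even[v] += odd[u]
                    odd[v] += even[u]
    return {
        v: PathParityCount(hop_distance=d, n_activation_like=even[v], n_inhibition_like=odd[v])
        for v, d in dist.items()
    }


def shortest_path_parity(graph: SignedDigraph, source: str, target: str) -> PathParityCount:
    """Shortest-path hop distance and parity counts for one ordered pair.

    ``source == target`` yields hop 0 with one activation-like path (zero
    inhibition edges counts as even); an unreachable pair yields infinite
    hop distance with zero counts.
    """
    if target not in graph:
        raise KeyError(f"unknown node id {target!r}")
    census = parity_from_source(graph, source)
    if target not in census:
        return PathParityCount(math.inf, 0, 0)
    return census[target]


def conflict_distance(parity: PathParityCount) -> ConflictDistance:
    """Apply the conflict adjustment to a shortest-path census.

    Returns ``(n_a + n_i) / (n_a - n_i) * hop`` -- positive when
    activation-like paths dominate, negative when inhibition-like paths
    dominate -- and the infinity sentinel when the pair is unreachable or
    the two parity classes tie.
    """
    if math.isinf(parity.hop_distance):
        return INFINITE_DISTANCE
    n_a, n_i = parity.n_activation_like, parity.n_inhibition_like
    if n_a == n_i:
        return ConflictDistance(value=math.inf, is_reachable=True)
    value = (n_a + n_i) / (n_a - n_i) * parity.hop_distance
    return ConflictDistance(value=value, is_reachable=True)


def _effect_to_sign(effect: str) -> int:
    token = effect.strip().lower()
    if token in EFFECT_SIGNS:
        return EFFECT_SIGNS[token]
    if token in {"+1", "1"}:
        return 1
    if token == "-1":
        return -1
    raise ValueError(f"unrecognised effect value {effect!r}")


def load_edge_table(path) -> SignedDigraph:
    """Read a signed edge table into a :class:`SignedDigraph`.

    Accepts a headered TSV with columns ``source``, ``target``, ``effect``
    (effect one of activation/inhibition/expression/repression, or a
    pre-assigned ``+1``/``-1``), or a headerless SIF-like 3-column TSV in
    the same order.
    """
    try:
        head = pd.read_csv(path, sep="\t", dtype=str, nrows=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"edge table {path} is empty") from exc
    headered = {"source", "target", "effect"}.issubset(head.columns)
    if headered:
        table = pd.read_csv(path, sep="\t", dtype=str)
    else:
        table = pd.read_csv(
            path, sep="\t", dtype=str, header=None, names=["source", "target", "effect"]
        )
    if table.empty:
        raise ValueError(f"edge table {path} contains no edges")
    records = [
        (row.source, row.target, _effect_to_sign(row.effect))
        for row in table.itertuples(index=False)
    ]
    return build_graph(records)
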