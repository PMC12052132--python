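"""Population structures for the Moran Birth-death process.

A population of ``n`` sites is represented by a directed graph: nodes are
sites, a directed edge (u, v) means that an offspring born at ``u`` can
migrate to ``v``.  Undirected (two-way) structures are stored as symmetric
digraphs.  This module provides the immutable graph container, validated
constructors for the named graph families studied in colonization-time
theory (complete, cycle, star, double star, total order, backward,
lollipop), a seeded random-digraph fixture generator, reachability and
regularity predicates, and a plain-text edge-list format.

Nodes are 0-indexed.  Self-loops and duplicate edges are rejected:
reproduction always places the offspring on *another* site.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "DirectedGraph",
    "GraphFamilySpec",
    "FAMILIES",
    "build_family",
    "complete_graph",
    "cycle_graph",
    "star_graph",
    "double_star_graph",
    "total_order_graph",
    "backward_graph",
    "lollipop_graph",
    "lollipop_path_length",
    "random_reachable_digraph",
    "reachable_from",
    "is_undirected",
    "is_regular",
    "default_start",
    "read_edge_list",
    "write_edge_list",
]


class GraphError(ValueError):
    """Invalid graph construction or malformed edge-list input."""


@dataclass(frozen=True)
class DirectedGraph:
    """Immutable directed graph given by out-adjacency lists.

    Parameters
    ----------
    n:
        Number of nodes; nodes are the integers ``0 .. n-1``.
    out_neighbors:
        For each node ``u``, a tuple of distinct targets of the edges
        leaving ``u``.  Out-degree zero is legal (a sink site can be
        selected for reproduction but places no offspring).
    labels:
        Optional human-readable node names.
    """

    n: int
    out_neighbors: tuple[tuple[int, ...], ...]
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GraphError(f"graph needs at least one node, got n={self.n}")
        if len(self.out_neighbors) != self.n:
            raise GraphError(
                f"adjacency has {len(self.out_neighbors)} rows for n={self.n} nodes"
            )
        for u, nbrs in enumerate(self.out_neighbors):
            seen = set()
            for v in nbrs:
                if not (0 <= v < self.n):
                    raise GraphError(f"edge ({u}, {v}) leaves node range [0, {self.n})")
                if v == u:
                    raise GraphError(f"self-loop at node {u} is not allowed")
                if v in seen:
                    raise GraphError(f"duplicate edge ({u}, {v})")
                seen.add(v)
        if self.labels is not None and len(self.labels) != self.n:
            raise GraphError("labels length must equal n")

    def degree(self, u: int) -> int:
        """Out-degree of ``u``."""
        return len(self.out_neighbors[u])

    @property
    def degrees(self) -> tuple[int, ...]:
        return tuple(len(nbrs) for nbrs in self.out_neighbors)

    def edges(self) -> Iterator[tuple[int, int]]:
        """Iterate directed edges (u, v) in adjacency order."""
        for u, nbrs in enumerate(self.out_neighbors):
            for v in nbrs:
                yield (u, v)

    @property
    def num_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.out_neighbors)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.edges())

    @staticmethod
    def from_edges(n: int, edges: Iterable[tuple[int, int]],
                   labels: Optional[Sequence[str]] = None) -> "DirectedGraph":
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in edges:
            if not (0 <= u < n):
                raise GraphError(f"edge ({u}, {v}) leaves node range [0, {n})")
            adj[u].append(v)
        return DirectedGraph(n, tuple(tuple(row) for row in adj),
                             tuple(labels) if labels is not None else None)


# ---------------------------------------------------------------------------
# Named graph families
# ---------------------------------------------------------------------------

def complete_graph(n: int) -> DirectedGraph:
    """Complete graph K_n: every ordered pair (u, v), u != v, is an edge."""
    if n < 2:
        raise GraphError("complete graph needs n >= 2")
    return DirectedGraph(
        n, tuple(tuple(v for v in range(n) if v != u) for u in range(n))
    )


def cycle_graph(n: int) -> DirectedGraph:
    """Undirected cycle C_n: node i joined two-way to i-1 and i+1 (mod n)."""
    if n < 3:
        raise GraphError("cycle needs n >= 3")
    return DirectedGraph(
        n, tuple(tuple(sorted({(u - 1) % n, (u + 1) % n})) for u in range(n))
    )


def star_graph(n: int) -> DirectedGraph:
    """Undirected star S_n: node 0 is the center, nodes 1..n-1 are leaves."""
    if n < 2:
        raise GraphError("star needs n >= 2")
    adj = [tuple(range(1, n))] + [(0,)] * (n - 1)
    return DirectedGraph(n, tuple(adj))


def double_star_graph(k: int) -> DirectedGraph:
    """Double star D_{2k}: two stars S_k joined center-to-center (2k nodes).

    Node 0 and node 1 are the centers; nodes ``2 .. k`` are the leaves of
    center 0 and ``k+1 .. 2k-1`` the leaves of center 1.
    """
    if k < 2:
        raise GraphError("double star needs k >= 2")
    n = 2 * k
    leaves0 = tuple(range(2, k + 1))
    leaves1 = tuple(range(k + 1, n))
    adj: list[tuple[int, ...]] = [(1,) + leaves0, (0,) + leaves1]
    adj += [(0,)] * (k - 1) + [(1,)] * (k - 1)
    return DirectedGraph(n, tuple(adj))


def total_order_graph(n: int) -> DirectedGraph:
    """Total order TO_n: one-way edge i -> j for every i < j; node n-1 is a sink."""
    if n < 2:
        raise GraphError("total order needs n >= 2")
    return DirectedGraph(n, tuple(tuple(range(u + 1, n)) for u in range(n)))


def backward_graph(n: int) -> DirectedGraph:
    """Backward graph B_n: directed path 0 -> 1 -> ... -> n-1 plus every
    one-way edge j -> i for j > i (all "backward" edges).

    This is the slowest structure for colonization: starting from node 0 the
    expected number of modified-process steps is exactly n^2 (n-1) / 2.
    """
    if n < 2:
        raise GraphError("backward graph needs n >= 2")
    adj = []
    for u in range(n):
        nbrs = list(range(u))            # all backward edges u -> i, i < u
        if u < n - 1:
            nbrs.append(u + 1)           # the single forward path edge
        adj.append(tuple(nbrs))
    return DirectedGraph(n, tuple(adj))


def lollipop_path_length(n: int) -> int:
    """Path length p = round(sqrt(n)) used by the lollipop construction."""
    return max(1, int(round(np.sqrt(n))))


def lollipop_graph(n: int, attach: str = "all") -> DirectedGraph:
    """Lollipop graph: a one-way path of ~sqrt(n) nodes feeding a complete
    undirected cluster of the remaining nodes ("a stream leading to a pond").

    Nodes ``0 .. p-1`` (p = round(sqrt(n))) form the directed path
    ``i -> i+1``; nodes ``p .. n-1`` form a complete undirected cluster.
    With ``attach="all"`` the last path node sends a one-way edge to every
    cluster node; with ``attach="one"`` only to the first cluster node.
    No edges lead from the cluster back to the path, so a mutant at node 0
    can never be displaced.
    """
    if n < 4:
        raise GraphError("lollipop needs n >= 4")
    if attach not in ("all", "one"):
        raise GraphError(f"unknown attach mode {attach!r}")
    p = lollipop_path_length(n)
    if p >= n:
        raise GraphError(f"lollipop with n={n} leaves no cluster nodes")
    cluster = tuple(range(p, n))
    adj: list[tuple[int, ...]] = []
    for u in range(p - 1):
        adj.append((u + 1,))
    adj.append(cluster if attach == "all" else (p,))
    for u in cluster:
        adj.append(tuple(v for v in cluster if v != u))
    return DirectedGraph(n, tuple(adj))


def random_reachable_digraph(
    n: int,
    edge_prob: float,
    seed: int,
    undirected: bool = False,
    max_rejections: int = 1000,
) -> DirectedGraph:
    """Sample a digraph with independent edges, conditioned on every node
    being reachable from node 0 (rejection resampling).

    Deterministic given ``seed``.  Raises after ``max_rejections`` failed
    draws, which signals that ``edge_prob`` is too small for n.
    """
    if not (0.0 < edge_prob <= 1.0):
        raise GraphError(f"edge_prob must be in (0, 1], got {edge_prob}")
    if n < 2:
        raise GraphError("random digraph needs n >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_rejections):
        if undirected:
            mask = np.triu(rng.random((n, n)) < edge_prob, k=1)
            mask = mask | mask.T
        else:
            mask = rng.random((n, n)) < edge_prob
            np.fill_diagonal(mask, False)
        g = DirectedGraph(
            n, tuple(tuple(int(v) for v in np.flatnonzero(mask[u])) for u in range(n))
        )
        if len(reachable_from(g, {0})) == n:
            return g
    raise GraphError(
        f"no reachable digraph found in {max_rejections} draws "
        f"(n={n}, edge_prob={edge_prob}); increase edge_prob"
    )


FAMILIES = (
    "complete",
    "cycle",
    "star",
    "double_star",
    "total_order",
    "backward",
    "lollipop",
    "random",
)


@dataclass(frozen=True)
class GraphFamilySpec:
    """A named graph family plus its size parameters.

    ``family`` is one of :data:`FAMILIES`.  ``n`` is the node count (for
    ``double_star`` it is interpreted as 2k and must be even unless ``k``
    is given directly).  ``edge_prob``/``seed``/``undirected`` apply to the
    ``random`` family only.
    """

    family: str
    n: Optional[int] = None
    k: Optional[int] = None
    edge_prob: float = 0.5
    seed: int = 0
    undirected: bool = False
    attach: str = "all"


def build_family(spec: GraphFamilySpec) -> DirectedGraph:
    """Construct the graph described by ``spec``."""
    fam = spec.family.replace("-", "_")
    if fam not in FAMILIES:
        raise GraphError(f"unknown graph family {spec.family!r}; choose from {FAMILIES}")
    if fam == "double_star":
        if spec.k is not None:
            return double_star_graph(spec.k)
        if spec.n is None or spec.n % 2 != 0:
            raise GraphError("double star needs k, or an even node count n = 2k")
        return double_star_graph(spec.n // 2)
    if spec.n is None:
        raise GraphError(f"family {fam!r} needs a node count n")
    if fam == "complete":
        return complete_graph(spec.n)
    if fam == "cycle":
        return cycle_graph(spec.n)
    if fam == "star":
        return star_graph(spec.n)
    if fam == "total_order":
        return total_order_graph(spec.n)
    if fam == "backward":
        return backward_graph(spec.n)
    if fam == "lollipop":
        return lollipop_graph(spec.n, attach=spec.attach)
    return random_reachable_digraph(
        spec.n, spec.edge_prob, spec.seed, undirected=spec.undirected
    )


def default_start(family: str) -> int:
    """Designated default initial-mutant node for a family.

    Path-like families (backward, total order, lollipop) start at the
    leftmost node 0.  The star starts at a leaf (node 1); its colonization
    time is in fact start-independent.  All other families start at node 0.
    """
    fam = family.replace("-", "_")
    if fam == "star":
        return 1
    return 0


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------

def reachable_from(g: DirectedGraph, sources: Iterable[int]) -> frozenset[int]:
    """Forward closure of ``sources`` by breadth-first search."""
    srcs = list(sources)
    if not srcs:
        raise GraphError("sources must be non-empty")
    seen = set(srcs)
    queue = deque(srcs)
    while queue:
        u = queue.popleft()
        for v in g.out_neighbors[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return frozenset(seen)


def is_undirected(g: DirectedGraph) -> bool:
    """True iff the edge relation is symmetric."""
    es = g.edge_set()
    return all((v, u) in es for (u, v) in es)


def is_regular(g: DirectedGraph) -> bool:
    """True iff every node has the same out-degree (isothermal structure)."""
    degs = g.degrees
    return len(set(degs)) == 1


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------
# Format: one "u<TAB>v" integer pair per line; lines starting with '#' are
# comments.  A '# undirected' header makes each line stand for both
# directions.  An optional '# n <int>' header pins the node count (needed
# for trailing isolated/sink nodes).

def write_edge_list(g: DirectedGraph, path) -> None:
    """Write ``g`` in the plain-text edge-list dialect (always directed)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n {g.n}\n")
        for u, v in g.edges():
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path) -> DirectedGraph:
    """Read an edge-list file; rejects self-loops, duplicates, and malformed
    lines with the offending line number."""
    undirected = False
    n_declared: Optional[int] = None
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip().lower()
                if body == "undirected":
                    undirected = True
                elif body.startswith("n "):
                    try:
                        n_declared = int(body.split()[1])
                    except (IndexError, ValueError):
                        raise GraphError(f"line {lineno}: malformed '# n' header")
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GraphError(f"line {lineno}: expected 'u<TAB>v', got {raw!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise GraphError(f"line {lineno}: non-integer node id in {raw!r}")
            if u == v:
                raise GraphError(f"line {lineno}: self-loop ({u}, {v})")
            pairs = [(u, v), (v, u)] if undirected else [(u, v)]
            for pair in pairs:
                if pair in seen:
                    raise GraphError(f"line {lineno}: duplicate edge {pair}")
                seen.add(pair)
                edges.append(pair)
    if not edges and n_declared is None:
        raise GraphError("empty edge list and no '# n' header")
    n = n_declared if n_declared is not None else 1 + max(max(e) for e in edges)
    return DirectedGraph.from_edges(n, edges)
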