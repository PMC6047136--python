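"""Top-K loopless shortest paths (Yen's algorithm) on undirected graphs.

Dijkstra provides the single shortest path; Yen's construction then generates
candidates by forcing deviations at every spur node of each accepted path
while masking the root-path edges and nodes, keeping the K best.  Ties in
length are broken lexicographically by node sequence, so results are fully
deterministic.  Unweighted graphs use unit edge costs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .graph_core import UnipartiteGraph


@dataclass(frozen=True)
class PathResult:
    """A loopless path: ordered node labels and total length."""

    nodes: tuple[str, ...]
    length: float

    def __iter__(self):
        return iter(self.nodes)


def _adjacency_dict(g: UnipartiteGraph) -> dict[str, dict[str, float]]:
    adj = g.adjacency if g.weighted else g.binary()
    if (adj < 0).any():
        raise ValueError("negative edge weights are not supported")
    out: dict[str, dict[str, float]] = {lab: {} for lab in g.labels}
    rows, cols = np.nonzero(adj)
    for r, c in zip(rows, cols):
        out[g.labels[r]][g.labels[c]] = float(adj[r, c])
    return out


def _dijkstra(
    adj: dict[str, dict[str, float]],
    source: str,
    sink: str,
    banned_nodes: frozenset[str] = frozenset(),
    banned_edges: frozenset[tuple[str, str]] = frozenset(),
) -> PathResult | None:
    """Shortest path with lexicographic tie-break on the node sequence.

    Heap entries carry the path itself, so among equal-length paths the
    lexicographically smallest pops first.
    """
    if source == sink:
        return PathResult((source,), 0.0)
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    done: set[str] = set()
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == sink:
            return PathResult(path, dist)
        for nbr, w in adj[node].items():
            if nbr in done or nbr in banned_nodes:
                continue
            if (node, nbr) in banned_edges or (nbr, node) in banned_edges:
                continue
            heapq.heappush(heap, (dist + w, path + (nbr,)))
    return None


def shortest_path(g: UnipartiteGraph, source: str, sink: str) -> PathResult | None:
    """Dijkstra shortest path; ``None`` when the sink is unreachable."""
    if source not in g.labels or sink not in g.labels:
        raise ValueError("source and sink must be nodes of the graph")
    return _dijkstra(_adjacency_dict(g), source, sink)


def yen_k_shortest(
    g: UnipartiteGraph, source: str, sink: str, K: int
) -> list[PathResult]:
    """The K shortest distinct loopless paths, nondecreasing in length.

    Returns fewer than K paths when the graph has fewer distinct loopless
    source-sink paths.  Equal-length paths are ordered lexicographically by
    node sequence.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if source not in g.labels or sink not in g.labels:
        raise ValueError("source and sink must be nodes of the graph")
    adj = _adjacency_dict(g)
    first = _dijkstra(adj, source, sink)
    if first is None:
        return []
    accepted = [first]
    # candidate pool keyed by (length, node sequence) for deterministic order
    candidates: list[tuple[float, tuple[str, ...]]] = []
    seen: set[tuple[str, ...]] = {first.nodes}
    while len(accepted) < K:
        prev = accepted[-1].nodes
        for i in range(len(prev) - 1):
            spur = prev[i]
            root = prev[: i + 1]
            root_len = sum(adj[root[j]][root[j + 1]] for j in range(i))
            banned_edges = set()
            for p in accepted:
                if p.nodes[: i + 1] == root and len(p.nodes) > i + 1:
                    banned_edges.add((p.nodes[i], p.nodes[i + 1]))
            banned_nodes = frozenset(root[:-1])
            spur_path = _dijkstra(adj, spur, sink, banned_nodes, frozenset(banned_edges))
            if spur_path is None:
                continue
            total = root[:-1] + spur_path.nodes
            if total in seen:
                continue
            seen.add(total)
            heapq.heappush(candidates, (root_len + spur_path.length, total))
        if not candidates:
            break
        length, nodes = heapq.heappop(candidates)
        accepted.append(PathResult(nodes, length))
    return accepted
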