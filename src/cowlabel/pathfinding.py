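"""Path-finding on skeleton graphs: DFS maze solver, Dijkstra, and A*.

Three methods connect an annotated endpoint pair through the skeleton graph:

* ``dfs`` — a depth-first maze solver. Visited voxels are pushed on a stack;
  at a dead end the stack unwinds to the last voxel with an unvisited
  neighbor. The surviving stack when the goal is reached is the path. It is
  a valid path but NOT guaranteed shortest: on looped anatomy (the circle of
  Willis ring) it frequently detours the long way around a cycle.
* ``dijkstra`` — globally shortest path by total edge weight (mm).
* ``astar`` — A* with the straight-line Euclidean distance to the goal as
  heuristic. Edge weights are Euclidean lengths, so the heuristic is
  admissible (indeed consistent) and A* returns the same cost as Dijkstra.

All three are deterministic: DFS visits neighbors in lexicographic
``(dz, dy, dx)`` offset order, and Dijkstra/A* break priority ties by
popping the lexicographically smallest coordinate.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

from .errors import InputError, NoPathError, OracleRefusedError
from .skeleton import SkeletonGraph

__all__ = [
    "Path",
    "validate_path",
    "dfs_path",
    "dijkstra_path",
    "astar_path",
    "brute_force_shortest",
    "find_path",
]

Node = tuple[int, int, int]


@dataclass(frozen=True)
class Path:
    """An ordered simple voxel path with its total physical length in mm."""

    voxels: tuple[Node, ...]
    length_mm: float
    method: str

    def __len__(self) -> int:
        return len(self.voxels)

    @property
    def start(self) -> Node:
        return self.voxels[0]

    @property
    def goal(self) -> Node:
        return self.voxels[-1]


def validate_path(path: Path, graph: SkeletonGraph, start: Node, goal: Node) -> None:
    """Check every Path invariant; raises ``InputError`` on violation.

    Invariants: endpoints match the query, no voxel repeats, consecutive
    voxels are 26-adjacent graph edges, and the recorded length equals the
    sum of edge weights to within 1e-9.
    """
    if not path.voxels:
        raise InputError("empty path")
    if path.voxels[0] != tuple(start) or path.voxels[-1] != tuple(goal):
        raise InputError("path endpoints do not match the queried endpoints")
    if len(set(path.voxels)) != len(path.voxels):
        raise InputError("path revisits a voxel (not simple)")
    total = 0.0
    for u, v in zip(path.voxels, path.voxels[1:]):
        if any(abs(a - b) > 1 for a, b in zip(u, v)):
            raise InputError(f"consecutive voxels {u} and {v} are not 26-adjacent")
        if not graph.graph.has_edge(u, v):
            raise InputError(f"path uses a non-edge {u}-{v}")
        total += graph.weight(u, v)
    if not math.isclose(total, path.length_mm, rel_tol=1e-9, abs_tol=1e-9):
        raise InputError(f"recorded length {path.length_mm} != edge-weight sum {total}")


def _require_nodes(graph: SkeletonGraph, start: Node, goal: Node) -> tuple[Node, Node]:
    start, goal = tuple(start), tuple(goal)
    for p in (start, goal):
        if not graph.has_node(p):
            raise InputError(f"endpoint {p} is not a graph node")
    return start, goal


def _path_length(graph: SkeletonGraph, voxels: list[Node]) -> float:
    return sum(graph.weight(u, v) for u, v in zip(voxels, voxels[1:]))


def _dfs_neighbor_key(u: Node):
    # lexicographic over the (dz, dy, dx) offset of each neighbor
    def key(v: Node):
        return (v[2] - u[2], v[1] - u[1], v[0] - u[0])

    return key


def dfs_path(graph: SkeletonGraph, start: Node, goal: Node) -> Path:
    """Depth-first maze solver; returns the stack contents at termination."""
    start, goal = _require_nodes(graph, start, goal)
    if start == goal:
        return Path(voxels=(start,), length_mm=0.0, method="dfs")
    stack: list[Node] = [start]
    visited = {start}
    # per-stack-entry iterator over neighbors in the fixed visiting order
    iters = [iter(sorted(graph.neighbors(start), key=_dfs_neighbor_key(start)))]
    while stack:
        advanced = False
        for v in iters[-1]:
            if v in visited:
                continue
            visited.add(v)
            stack.append(v)
            if v == goal:
                return Path(
                    voxels=tuple(stack),
                    length_mm=_path_length(graph, stack),
                    method="dfs",
                )
            iters.append(iter(sorted(graph.neighbors(v), key=_dfs_neighbor_key(v))))
            advanced = True
            break
        if not advanced:
            stack.pop()
            iters.pop()
    raise NoPathError(f"goal {goal} unreachable from {start}")


def _reconstruct(pred: dict[Node, Node], goal: Node) -> list[Node]:
    chain = [goal]
    while chain[-1] in pred:
        chain.append(pred[chain[-1]])
    chain.reverse()
    return chain


def dijkstra_path(graph: SkeletonGraph, start: Node, goal: Node) -> Path:
    """Globally shortest path by summed edge weight (binary-heap Dijkstra).

    Heap entries are ``(distance, node)`` tuples, so ties in distance pop
    the lexicographically smallest coordinate first — deterministic across
    platforms.
    """
    start, goal = _require_nodes(graph, start, goal)
    if start == goal:
        return Path(voxels=(start,), length_mm=0.0, method="dijkstra")
    dist: dict[Node, float] = {start: 0.0}
    pred: dict[Node, Node] = {}
    done: set[Node] = set()
    heap: list[tuple[float, Node]] = [(0.0, start)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        if u == goal:
            voxels = _reconstruct(pred, goal)
            return Path(voxels=tuple(voxels), length_mm=d, method="dijkstra")
        done.add(u)
        for v in graph.neighbors(u):
            if v in done:
                continue
            nd = d + graph.weight(u, v)
            if nd < dist.get(v, math.inf):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    raise NoPathError(f"goal {goal} unreachable from {start}")


def astar_path(graph: SkeletonGraph, start: Node, goal: Node) -> Path:
    """A* with the Euclidean straight-line distance to the goal as heuristic.

    The heuristic is measured in the same mm units as the edge weights;
    since each edge weight is itself a Euclidean distance, the heuristic
    never overestimates and the returned cost equals the Dijkstra cost.
    """
    start, goal = _require_nodes(graph, start, goal)
    if start == goal:
        return Path(voxels=(start,), length_mm=0.0, method="astar")

    def h(node: Node) -> float:
        return graph.euclidean_mm(node, goal)

    g: dict[Node, float] = {start: 0.0}
    pred: dict[Node, Node] = {}
    done: set[Node] = set()
    heap: list[tuple[float, Node]] = [(h(start), start)]
    while heap:
        f, u = heapq.heappop(heap)
        if u in done:
            continue
        if u == goal:
            voxels = _reconstruct(pred, goal)
            return Path(voxels=tuple(voxels), length_mm=g[u], method="astar")
        done.add(u)
        for v in graph.neighbors(u):
            if v in done:
                continue
            ng = g[u] + graph.weight(u, v)
            if ng < g.get(v, math.inf):
                g[v] = ng
                pred[v] = u
                heapq.heappush(heap, (ng + h(v), v))
    raise NoPathError(f"goal {goal} unreachable from {start}")


def brute_force_shortest(
    graph: SkeletonGraph,
    start: Node,
    goal: Node,
    max_paths: int = 10**6,
) -> Path:
    """Exact minimal-cost simple path by exhaustive enumeration (test oracle).

    Refuses graphs where enumeration would exceed ``max_paths`` partial
    extensions. Intended for fixtures, never for real skeletons.
    """
    start, goal = _require_nodes(graph, start, goal)
    if start == goal:
        return Path(voxels=(start,), length_mm=0.0, method="brute_force")
    best_cost = math.inf
    best: list[Node] | None = None
    steps = 0
    path: list[Node] = [start]
    on_path = {start}

    def extend(u: Node, cost: float) -> None:
        nonlocal best_cost, best, steps
        for v in sorted(graph.neighbors(u)):
            steps += 1
            if steps > max_paths:
                raise OracleRefusedError(
                    f"enumeration guard exceeded ({max_paths} extensions)"
                )
            if v in on_path:
                continue
            c = cost + graph.weight(u, v)
            if v == goal:
                if c < best_cost:
                    best_cost = c
                    best = path + [v]
                continue
            if c >= best_cost:
                continue
            path.append(v)
            on_path.add(v)
            extend(v, c)
            path.pop()
            on_path.remove(v)

    extend(start, 0.0)
    if best is None:
        raise NoPathError(f"goal {goal} unreachable from {start}")
    return Path(voxels=tuple(best), length_mm=best_cost, method="brute_force")


_METHODS = {
    "dfs": dfs_path,
    "dijkstra": dijkstra_path,
    "astar": astar_path,
}


def find_path(graph: SkeletonGraph, start: Node, goal: Node, method: str) -> Path:
    """Dispatch to one of the three path-finding methods by name."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise InputError(f"unknown method {method!r}; choose from {sorted(_METHODS)}") from None
    return fn(graph, start, goal)
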