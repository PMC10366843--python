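"""Skeletonization and skeleton-to-graph conversion.

The binary vessel mask is thinned to a one-voxel-wide centerline with 3D
medial-axis thinning, then converted to a dense undirected graph: every
skeleton voxel is a node and every 26-adjacent pair of skeleton voxels is an
edge, weighted by the physical Euclidean distance between the two voxel
centers. Under isotropic spacing ``s`` the edge weights are therefore
exactly ``{s, s*sqrt(2), s*sqrt(3)}``.

A dense per-voxel graph (rather than a junction/branch summary) is used
because path reconstruction needs the full voxel chain of each labeled
segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import InputError, SnapError
from .segmentation import BinaryMask

__all__ = [
    "SkeletonGraph",
    "skeletonize_3d",
    "skeleton_to_graph",
    "snap_to_skeleton",
    "write_graph_edgelist",
    "read_graph_edgelist",
]

# The 13 "positive" half of the 26-neighborhood: one representative per
# unordered offset pair, so each adjacency is produced exactly once.
_HALF_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


@dataclass
class SkeletonGraph:
    """Undirected weighted graph over skeleton voxels.

    Nodes are ``(x, y, z)`` integer voxel tuples; each edge joins two
    26-adjacent voxels and carries a ``weight`` attribute equal to the
    Euclidean distance between the voxel centers in mm.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, node: tuple[int, int, int]) -> bool:
        return self.graph.has_node(tuple(node))

    def weight(self, u: tuple[int, int, int], v: tuple[int, int, int]) -> float:
        return self.graph.edges[tuple(u), tuple(v)]["weight"]

    def neighbors(self, node):
        return self.graph.neighbors(tuple(node))

    def euclidean_mm(self, u, v) -> float:
        """Physical straight-line distance between two voxel centers."""
        diff = (np.asarray(u, float) - np.asarray(v, float)) * np.asarray(self.spacing)
        return float(np.linalg.norm(diff))

    def cycle_rank(self) -> int:
        """Number of independent cycles, E - V + C."""
        c = nx.number_connected_components(self.graph)
        return self.number_of_edges - self.number_of_nodes + c


def skeletonize_3d(mask: BinaryMask) -> BinaryMask:
    """Thin a binary mask to its one-voxel-wide centerline skeleton.

    Uses 3D medial-axis thinning; the result is a subset of the input mask
    and preserves the number of 26-connected components.
    """
    data = np.asarray(mask.data, dtype=bool)
    if not data.any():
        return BinaryMask(data=np.zeros_like(data), spacing=mask.spacing)
    skel = skeletonize(data)
    return BinaryMask(data=np.asarray(skel, dtype=bool), spacing=mask.spacing)


def skeleton_to_graph(skel: BinaryMask) -> SkeletonGraph:
    """Convert a skeleton mask into a dense 26-connected weighted graph."""
    data = np.asarray(skel.data, dtype=bool)
    spacing = np.asarray(skel.spacing, dtype=float)
    g = nx.Graph()
    coords = np.argwhere(data)
    g.add_nodes_from(map(tuple, coords.tolist()))
    for off in _HALF_OFFSETS:
        shifted_pairs = _adjacent_pairs(data, off)
        if shifted_pairs.size == 0:
            continue
        w = float(np.linalg.norm(np.asarray(off, float) * spacing))
        for x, y, z in shifted_pairs.tolist():
            g.add_edge((x, y, z), (x + off[0], y + off[1], z + off[2]), weight=w)
    return SkeletonGraph(graph=g, spacing=skel.spacing)


def _adjacent_pairs(data: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    """Coordinates v such that both v and v+off are true (off has positive sign)."""
    sl_src, sl_dst = [], []
    for d in off:
        if d == 0:
            sl_src.append(slice(None))
            sl_dst.append(slice(None))
        elif d == 1:
            sl_src.append(slice(None, -1))
            sl_dst.append(slice(1, None))
        else:  # d == -1
            sl_src.append(slice(1, None))
            sl_dst.append(slice(None, -1))
    both = data[tuple(sl_src)] & data[tuple(sl_dst)]
    pairs = np.argwhere(both)
    # argwhere indexes into the sliced array; shift back to full-grid coords
    for axis, d in enumerate(off):
        if d == -1 and pairs.size:
            pairs[:, axis] += 1
    return pairs


def snap_to_skeleton(
    point: tuple[int, int, int],
    skel: BinaryMask,
    max_radius: float = 3.0,
) -> tuple[int, int, int]:
    """Nearest skeleton voxel to an annotated point, within ``max_radius`` voxels.

    Distance is Euclidean in voxel units (annotations live on the isotropic
    grid). Ties break lexicographically by coordinate. Raises
    :class:`~cowlabel.errors.SnapError` when no skeleton voxel is close enough.
    """
    coords = np.argwhere(np.asarray(skel.data, dtype=bool))
    if coords.size == 0:
        raise SnapError(f"cannot snap {tuple(point)}: skeleton is empty")
    p = np.asarray(point, dtype=float)
    d2 = ((coords - p) ** 2).sum(axis=1)
    best = d2.min()
    if best > float(max_radius) ** 2:
        raise SnapError(
            f"no skeleton voxel within {max_radius} voxels of point {tuple(point)} "
            f"(nearest is {np.sqrt(best):.2f} voxels away)"
        )
    candidates = coords[d2 == best]
    idx = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0]))[0]
    return tuple(int(c) for c in candidates[idx])


def count_components_26(mask: BinaryMask) -> int:
    """Number of 26-connected foreground components."""
    _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    return int(n)


def write_graph_edgelist(sg: SkeletonGraph, path: str | Path) -> None:
    """Debug export: one edge per line, ``x1 y1 z1 x2 y2 z2 weight``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# spacing {sg.spacing[0]} {sg.spacing[1]} {sg.spacing[2]}\n")
        for u, v, w in sorted(sg.graph.edges(data="weight")):
            fh.write(f"{u[0]} {u[1]} {u[2]} {v[0]} {v[1]} {v[2]} {w:.9f}\n")


def read_graph_edgelist(path: str | Path) -> SkeletonGraph:
    """Read a graph written by :func:`write_graph_edgelist`."""
    g = nx.Graph()
    spacing = (1.0, 1.0, 1.0)
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].split()
                if tokens[:1] == ["spacing"]:
                    spacing = tuple(float(t) for t in tokens[1:4])
                continue
            tok = line.split()
            if len(tok) != 7:
                raise InputError(f"bad edge-list line: {line!r}")
            x1, y1, z1, x2, y2, z2 = (int(t) for t in tok[:6])
            g.add_edge((x1, y1, z1), (x2, y2, z2), weight=float(tok[6]))
    return SkeletonGraph(graph=g, spacing=spacing)
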