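"""Spatial-graph data model for vessel networks.

A skeletonised vascular network is represented as a *spatial graph*: a set of
nodes (3D locations where vessels meet or end) joined by segments, where each
segment carries an ordered polyline of points with a radius at every point.
All coordinates and radii are in micrometres (world space); voxel indices only
appear inside volume operations.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "Node",
    "Segment",
    "SpatialGraph",
    "RootedTree",
    "IntegrityReport",
    "GraphError",
    "validate_graph",
    "root_tree",
]


class GraphError(ValueError):
    """Raised for structurally invalid spatial graphs."""


@dataclass(frozen=True)
class Node:
    id: int
    position: np.ndarray  # (3,) µm

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise GraphError(f"node {self.id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Segment:
    """A node-to-node vessel centreline polyline with per-point radii."""

    id: int
    start_node: int
    end_node: int
    points: np.ndarray  # (n, 3) µm, endpoints included
    radii: np.ndarray  # (n,) µm
    compartment: str | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GraphError(f"segment {self.id}: points must be (n, 3)")
        if len(self.points) < 2:
            raise GraphError(f"segment {self.id}: needs >= 2 points")
        if len(self.radii) != len(self.points):
            raise GraphError(f"segment {self.id}: radii/points length mismatch")
        if np.any(self.radii < 0):
            raise GraphError(f"segment {self.id}: negative radius")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def step_lengths(self) -> np.ndarray:
        """Length of every subsegment (consecutive point pair), µm."""
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        """Arc length: the sum of all subsegment lengths, µm."""
        return float(self.step_lengths().sum())

    @property
    def chord_length(self) -> float:
        """Euclidean start-to-end distance, µm."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())

    def reversed(self) -> "Segment":
        return replace(
            self,
            start_node=self.end_node,
            end_node=self.start_node,
            points=self.points[::-1].copy(),
            radii=self.radii[::-1].copy(),
        )

    def copy(self) -> "Segment":
        return replace(self, points=self.points.copy(), radii=self.radii.copy())


@dataclass
class SpatialGraph:
    nodes: dict[int, Node] = field(default_factory=dict)
    segments: dict[int, Segment] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise GraphError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node

    def add_segment(self, seg: Segment) -> None:
        if seg.id in self.segments:
            raise GraphError(f"duplicate segment id {seg.id}")
        for nid in (seg.start_node, seg.end_node):
            if nid not in self.nodes:
                raise GraphError(f"segment {seg.id}: unknown node {nid}")
        if seg.length <= 0:
            raise GraphError(f"segment {seg.id}: zero arc length")
        for end, nid in ((0, seg.start_node), (-1, seg.end_node)):
            if not np.allclose(seg.points[end], self.nodes[nid].position, atol=1e-6):
                raise GraphError(
                    f"segment {seg.id}: endpoint {end} does not coincide with node {nid}"
                )
        self.segments[seg.id] = seg

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_points(self) -> int:
        return sum(s.n_points for s in self.segments.values())

    def total_length(self) -> float:
        return sum(s.length for s in self.segments.values())

    def summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_segments": self.n_segments,
            "n_points": self.n_points,
            "total_length_um": self.total_length(),
        }

    def node_incidence(self) -> dict[int, list[int]]:
        """Node id -> ids of incident segments."""
        inc: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for seg in self.segments.values():
            inc[seg.start_node].append(seg.id)
            if seg.end_node != seg.start_node:
                inc[seg.end_node].append(seg.id)
        return inc

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for seg in self.segments.values():
            g.add_edge(seg.start_node, seg.end_node, key=seg.id)
        return g

    def copy(self) -> "SpatialGraph":
        return SpatialGraph(
            nodes=dict(self.nodes),
            segments={sid: s.copy() for sid, s in self.segments.items()},
            metadata=dict(self.metadata),
        )


@dataclass
class IntegrityReport:
    n_nodes: int
    n_segments: int
    n_points: int
    orphan_nodes: list[int]
    zero_length_segments: list[int]
    duplicate_edges: list[tuple[int, int]]
    cycles: list[list[int]]
    n_components: int

    @property
    def is_clean(self) -> bool:
        return (
            not self.orphan_nodes
            and not self.zero_length_segments
            and not self.duplicate_edges
            and not self.cycles
            and self.n_components == 1
        )


def validate_graph(graph: SpatialGraph) -> IntegrityReport:
    """Structural integrity audit: orphans, zero-length or duplicate segments,
    cycles (reported with their node lists) and connected-component count."""
    inc = graph.node_incidence()
    orphans = sorted(nid for nid, segs in inc.items() if not segs)

    zero_len = sorted(s.id for s in graph.segments.values() if s.length == 0)

    seen: dict[tuple[int, int], int] = {}
    dupes: list[tuple[int, int]] = []
    for seg in graph.segments.values():
        key = tuple(sorted((seg.start_node, seg.end_node)))
        if key in seen:
            dupes.append((seen[key], seg.id))
        else:
            seen[key] = seg.id

    g = graph.to_networkx()
    cycles = [list(c) for c in nx.cycle_basis(nx.Graph(g))]
    # parallel edges are 2-cycles invisible to the simple-graph cycle basis
    for a, b in dupes:
        sa, sb = graph.segments[a], graph.segments[b]
        cycles.append(sorted({sa.start_node, sa.end_node, sb.start_node, sb.end_node}))
    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0

    return IntegrityReport(
        n_nodes=graph.n_nodes,
        n_segments=graph.n_segments,
        n_points=graph.n_points,
        orphan_nodes=orphans,
        zero_length_segments=zero_len,
        duplicate_edges=dupes,
        cycles=cycles,
        n_components=n_comp,
    )


@dataclass
class RootedTree:
    """A spatial graph oriented away from a root node.

    Every segment's polyline runs proximal (start) to distal (end); ``parent``
    maps a segment to the segment upstream of it (None for root segments) and
    ``children`` lists are ordered by segment id for determinism.
    """

    graph: SpatialGraph
    root_node: int
    parent: dict[int, int | None]
    children: dict[int, list[int]]

    @property
    def root_segments(self) -> list[int]:
        return sorted(s for s, p in self.parent.items() if p is None)

    def leaves(self) -> list[int]:
        return sorted(s for s, c in self.children.items() if not c)

    def segments_postorder(self) -> list[int]:
        """Children before parents."""
        order: list[int] = []
        stack = list(reversed(self.root_segments))
        while stack:
            sid = stack.pop()
            order.append(sid)
            stack.extend(reversed(self.children[sid]))
        return order[::-1]

    def segments_preorder(self) -> list[int]:
        return self.segments_postorder()[::-1]

    def copy(self) -> "RootedTree":
        return RootedTree(
            graph=self.graph.copy(),
            root_node=self.root_node,
            parent=dict(self.parent),
            children={k: list(v) for k, v in self.children.items()},
        )


def _auto_root(graph: SpatialGraph) -> int:
    """Pick the degree-1 node whose incident segment has the largest mean
    radius — the cut stump of the feeding artery in an autopsy network."""
    inc = graph.node_incidence()
    candidates = [(nid, segs[0]) for nid, segs in inc.items() if len(segs) == 1]
    if not candidates:
        raise GraphError("auto root: no degree-1 node found")
    return max(candidates, key=lambda t: (graph.segments[t[1]].mean_radius, -t[0]))[0]


def root_tree(graph: SpatialGraph, root: int | str = "auto") -> RootedTree:
    """Orient every segment away from a root node (breadth-first).

    ``root='auto'`` selects the degree-1 node with the thickest incident
    segment. Raises on cyclic or disconnected graphs.
    """
    report = validate_graph(graph)
    if report.cycles:
        raise GraphError(
            f"graph has cycles (resolve before rooting): {report.cycles[:3]}"
        )
    if report.n_components > 1:
        comps = list(nx.connected_components(nx.Graph(graph.to_networkx())))
        raise GraphError(f"graph has {len(comps)} components: sizes {sorted(map(len, comps))}")

    root_node = _auto_root(graph) if root == "auto" else int(root)
    if root_node not in graph.nodes:
        raise GraphError(f"root node {root_node} not in graph")

    oriented = graph.copy()
    inc = oriented.node_incidence()
    parent: dict[int, int | None] = {}
    children: dict[int, list[int]] = {sid: [] for sid in oriented.segments}
    visited_nodes = {root_node}
    # queue entries: (node to expand, segment that led there or None)
    queue: deque[tuple[int, int | None]] = deque([(root_node, None)])
    while queue:
        nid, via = queue.popleft()
        for sid in sorted(inc[nid]):
            if sid == via or sid in parent:
                continue
            seg = oriented.segments[sid]
            if seg.start_node != nid:
                oriented.segments[sid] = seg = seg.reversed()
            parent[sid] = via
            if via is not None:
                children[via].append(sid)
            far = seg.end_node
            if far not in visited_nodes:
                visited_nodes.add(far)
                queue.append((far, sid))

    for c in children.values():
        c.sort()
    return RootedTree(graph=oriented, root_node=root_node, parent=parent, children=children)
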