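"""Programmatic graph builders and brute-force oracles for the test suite.

The oracles deliberately re-derive every quantity from its definition
(recursive Strahler, path counting, exhaustive all-pairs search) so they stay
independent of the library's implementations.
"""

from __future__ import annotations

import numpy as np

from vasctree import Node, RootedTree, Segment, SpatialGraph, root_tree


def straight_segment(sid, a, b, pa, pb, r, n_points=3):
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    pts = np.asarray(pa, float) + t * (np.asarray(pb, float) - np.asarray(pa, float))
    return Segment(id=sid, start_node=a, end_node=b, points=pts, radii=np.full(n_points, float(r)))


def perfect_binary_tree(
    depth: int, root_radius: float = 64.0, child_ratio: float = 0.5, seg_len: float = 100.0
) -> tuple[SpatialGraph, int]:
    """Perfect binary tree with `depth` levels of segments (2^depth − 1
    segments); child radii scale by `child_ratio` per level. Returns
    (graph, root node id)."""
    g = SpatialGraph()
    g.add_node(Node(0, np.array([0.0, 0.0, 0.0])))
    next_node = 1
    next_seg = 0
    # (proximal node id, level, lateral offset, span)
    stack = [(0, 0, 0.0, 2.0 ** (depth + 2))]
    while stack:
        nid, level, off, span = stack.pop()
        if level >= depth:
            continue
        start = g.nodes[nid].position
        end = start + np.array([off, 0.0, seg_len])
        end_id = next_node
        g.add_node(Node(end_id, end))
        next_node += 1
        g.add_segment(
            straight_segment(next_seg, nid, end_id, start, end, root_radius * child_ratio**level)
        )
        next_seg += 1
        stack.append((end_id, level + 1, span / 4, span / 2))
        stack.append((end_id, level + 1, -span / 4, span / 2))
    return g, 0


def chain_graph(n_segments: int, seg_len: float = 50.0, radius: float = 10.0) -> tuple[SpatialGraph, int]:
    """n segments joined end-to-end at degree-2 nodes."""
    g = SpatialGraph()
    g.add_node(Node(0, np.zeros(3)))
    for i in range(n_segments):
        a = g.nodes[i].position
        b = a + np.array([0.0, 0.0, seg_len])
        g.add_node(Node(i + 1, b))
        g.add_segment(straight_segment(i, i, i + 1, a, b, radius))
    return g, 0


def random_tree(rng: np.random.Generator, n_segments: int) -> RootedTree:
    """Random rooted tree: each new segment attaches to a uniformly chosen
    existing segment's distal node, giving a mix of pass-through nodes,
    bifurcations and multifurcations with random geometry and radii."""
    g = SpatialGraph()
    g.add_node(Node(0, np.zeros(3)))
    end_nodes = {}  # segment id -> distal node id
    next_node = 1
    for sid in range(n_segments):
        if sid == 0:
            start = 0
        else:
            start = end_nodes[int(rng.integers(0, sid))]
        a = g.nodes[start].position
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        b = a + direction * rng.uniform(20.0, 120.0)
        g.add_node(Node(next_node, b))
        npts = int(rng.integers(2, 6))
        t = np.linspace(0, 1, npts)[:, None]
        pts = a + t * (b - a)
        if npts > 2:
            pts[1:-1] += rng.normal(scale=2.0, size=(npts - 2, 3))
        g.add_segment(
            Segment(
                id=sid, start_node=start, end_node=next_node,
                points=pts, radii=rng.uniform(5.0, 50.0, size=npts),
            )
        )
        end_nodes[sid] = next_node
        next_node += 1
    return root_tree(g, 0)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def strahler_oracle(tree: RootedTree) -> dict[int, int]:
    """Direct recursive definition (leaves 1; +1 when the max child order is
    attained at least twice)."""

    import sys

    sys.setrecursionlimit(10000)

    def order(sid: int) -> int:
        kids = tree.children[sid]
        if not kids:
            return 1
        vals = sorted((order(k) for k in kids), reverse=True)
        if len(vals) >= 2 and vals[0] == vals[1]:
            return vals[0] + 1
        return vals[0]

    return {sid: order(sid) for sid in tree.parent}


def generation_oracle(tree: RootedTree) -> dict[int, int]:
    """Generation = 1 + number of branching nodes on the path from the root
    (counted via explicit upward walks)."""
    out = {}
    for sid in tree.parent:
        gen = 1
        cur = sid
        while tree.parent[cur] is not None:
            pid = tree.parent[cur]
            if len(tree.children[pid]) >= 2:
                gen += 1
            cur = pid
        out[sid] = gen
    return out


def tips_oracle(tree: RootedTree) -> dict[int, int]:
    """Exhaustive leaf enumeration per segment subtree."""
    leaves = set(tree.leaves())

    def count(sid: int) -> int:
        stack, n = [sid], 0
        while stack:
            cur = stack.pop()
            if cur in leaves:
                n += 1
            stack.extend(tree.children[cur])
        return n

    return {sid: count(sid) for sid in tree.parent}


def ivd_oracle(graph: SpatialGraph) -> dict[int, float]:
    """O(n²) all-pairs nearest midpoint search."""

    def midpoint(seg: Segment) -> np.ndarray:
        steps = np.linalg.norm(np.diff(seg.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        half = cum[-1] / 2
        i = int(np.searchsorted(cum, half, side="right") - 1)
        i = min(i, len(steps) - 1)
        frac = (half - cum[i]) / steps[i] if steps[i] > 0 else 0.0
        return seg.points[i] + frac * (seg.points[i + 1] - seg.points[i])

    sids = sorted(graph.segments)
    mids = {sid: midpoint(graph.segments[sid]) for sid in sids}
    out = {}
    for sid in sids:
        best = np.inf
        for other in sids:
            if other == sid:
                continue
            best = min(best, float(np.linalg.norm(mids[sid] - mids[other])))
        out[sid] = best
    return out


def tortuosity_oracle(seg: Segment) -> float:
    arc = float(np.sum(np.linalg.norm(np.diff(seg.points, axis=0), axis=1)))
    chord = float(np.linalg.norm(seg.points[-1] - seg.points[0]))
    return arc / chord if chord > 0 else float("nan")
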