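"""Synthetic vascular trees, phantom volumes and artifact injection.

The generator emulates the statistical structure of a whole-organ arterial
network so that every analysis stage can be exercised against known ground
truth: a rooted tree with a prescribed number of truncated Strahler orders,
a branching ratio γ (expected child count per junction), radii following the
symmetric radial scaling rule r_child = r_parent · m^(−a) for m children
(which makes the scaling exponent and Murray deviations exact by
construction), per-order length:diameter targets, branching-angle spread and
centreline tortuosity noise. Phantom volumes voxelize a tree into a binary
capsule-union mask; collapse injection scales graph radii down while leaving
the mask patent, mimicking a skeleton under-reading a collapsed lumen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import Node, RootedTree, Segment, SpatialGraph, root_tree
from .volumes import BinaryVolume, LabelVolume

__all__ = [
    "TreeSpec",
    "PhantomVolume",
    "generate_tree",
    "generate_rooted_tree",
    "voxelize_tree",
    "voxelize_graph_on_grid",
    "inject_collapse",
    "generate_compartments",
    "CompartmentGeometry",
]

# Per-order length:diameter targets consistent with the measured per-order
# mean lengths and radii of the reference human kidney network (length
# divided by 2 × mean radius).
DEFAULT_LENGTH_TO_DIAMETER: dict[int, float] = {
    1: 28.9, 2: 16.1, 3: 9.5, 4: 7.0, 5: 5.6, 6: 3.1, 7: 4.3, 8: 4.6, 9: 1.9,
}


@dataclass
class TreeSpec:
    """Ground-truth knobs for the synthetic arterial tree.

    Defaults mirror the measured whole-kidney network: nine truncated
    Strahler orders, branching ratio ≈ 2.9, root radius 2900 µm, radial
    scaling exponent 0.55.
    """

    n_orders: int = 9
    branching_ratio: float = 2.9
    root_radius: float = 2900.0  # µm
    radius_exponent: float = 0.55  # a in r_c = r_p · m^(−a)
    length_to_diameter: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_TO_DIAMETER)
    )
    angle_spread: float = 12.0  # degrees, SD of the child-cone half-angle
    mean_branch_angle: float = 35.0  # degrees, mean deviation from parent axis
    tortuosity_noise: float = 200.0  # µm, perpendicular noise amplitude
    points_per_segment: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.branching_ratio <= 1:
            raise ValueError("branching_ratio must exceed 1")
        if self.n_orders < 1:
            raise ValueError("n_orders must be >= 1")
        if self.root_radius <= 0:
            raise ValueError("root_radius must be positive")

    def ld_target(self, order: int) -> float:
        if order in self.length_to_diameter:
            return self.length_to_diameter[order]
        return self.length_to_diameter[min(self.length_to_diameter, key=lambda o: abs(o - order))]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, helper))
    return e1, np.cross(d, e1)


def _polyline(
    start: np.ndarray,
    end: np.ndarray,
    n_points: int,
    noise_amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Straight polyline with smooth perpendicular tortuosity noise; the
    endpoints stay fixed and the amplitude is capped at 10% of the chord."""
    t = np.linspace(0.0, 1.0, n_points)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    chord = np.linalg.norm(end - start)
    amp = min(noise_amp, 0.1 * chord)
    if amp > 0 and n_points > 2:
        e1, e2 = _perp_basis(_unit(end - start))
        envelope = np.sin(np.pi * t)  # zero at both endpoints
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        cycles = rng.integers(1, 3)
        w1 = amp * np.sin(2 * np.pi * cycles * t + phase1) * envelope
        w2 = amp * np.sin(2 * np.pi * cycles * t + phase2) * envelope
        pts = pts + w1[:, None] * e1[None, :] + w2[:, None] * e2[None, :]
    return pts


def _sample_child_count(gamma: float, rng: np.random.Generator) -> int:
    """Child count in {floor γ, ceil γ} (min 2) with mean γ."""
    lo = max(int(math.floor(gamma)), 2)
    hi = max(int(math.ceil(gamma)), 2)
    if lo == hi:
        return lo
    p_hi = gamma - math.floor(gamma) if gamma >= 2 else 0.0
    return hi if rng.random() < p_hi else lo


def _child_directions(
    parent_dir: np.ndarray, m: int, spec: TreeSpec, rng: np.random.Generator
) -> list[np.ndarray]:
    """m unit directions on a noisy cone around the parent direction,
    azimuthally spread for spatial separation."""
    e1, e2 = _perp_basis(parent_dir)
    base_az = rng.uniform(0, 2 * np.pi)
    dirs = []
    for i in range(m):
        theta = math.radians(
            np.clip(rng.normal(spec.mean_branch_angle, spec.angle_spread), 5.0, 85.0)
        )
        az = base_az + 2 * np.pi * i / m + rng.normal(0, 0.3)
        d = (
            math.cos(theta) * parent_dir
            + math.sin(theta) * (math.cos(az) * e1 + math.sin(az) * e2)
        )
        dirs.append(_unit(d))
    return dirs


def generate_tree(spec: TreeSpec) -> SpatialGraph:
    """Generate a rooted, acyclic synthetic arterial tree.

    Construction is top-down by order: the root segment carries the highest
    order; every segment above order 1 branches into m >= 2 children of the
    next order down (m sampled with mean γ), so the constructed levels are
    exactly the truncated Strahler orders of the result and segment counts
    grow by γ per order in expectation. Child radii follow
    r_c = r_p · m^(−a); segment lengths are the per-order length:diameter
    target times the local diameter. Deterministic given the seed; raises if
    the radius cascade would fall below 1 µm.
    """
    rng = np.random.default_rng(spec.seed)
    m_max = max(2, math.ceil(spec.branching_ratio))
    min_radius = spec.root_radius * m_max ** (-spec.radius_exponent * (spec.n_orders - 1))
    if min_radius < 1.0:
        raise ValueError(
            f"spec yields sub-µm radii at order 1 (≈{min_radius:.2g} µm); "
            "raise root_radius or lower n_orders"
        )

    graph = SpatialGraph(metadata={"units": "um", "provenance": "vasctree synthetic", "root_node": 0})
    next_node = 0
    next_seg = 0

    def new_node(pos: np.ndarray) -> int:
        nonlocal next_node
        nid = next_node
        graph.add_node(Node(id=nid, position=pos))
        next_node += 1
        return nid

    def add_seg(a: int, b: int, pts: np.ndarray, radius: float) -> int:
        nonlocal next_seg
        sid = next_seg
        pts = pts.copy()
        pts[0] = graph.nodes[a].position
        pts[-1] = graph.nodes[b].position
        graph.add_segment(
            Segment(id=sid, start_node=a, end_node=b, points=pts, radii=np.full(len(pts), radius))
        )
        next_seg += 1
        return sid

    root_dir = np.array([0.0, 0.0, 1.0])
    root_pos = np.zeros(3)
    root_id = new_node(root_pos)

    # stack of (proximal node, direction, radius, order)
    root_len = spec.ld_target(spec.n_orders) * 2 * spec.root_radius
    stack = [(root_id, root_dir, spec.root_radius, spec.n_orders, root_len)]
    while stack:
        nid, direction, radius, order, length = stack.pop()
        start = graph.nodes[nid].position
        end = start + length * direction
        end_id = new_node(end)
        pts = _polyline(start, end, spec.points_per_segment, spec.tortuosity_noise, rng)
        add_seg(nid, end_id, pts, radius)
        if order <= 1:
            continue
        m = _sample_child_count(spec.branching_ratio, rng)
        child_r = radius * m ** (-spec.radius_exponent)
        child_len = spec.ld_target(order - 1) * 2 * child_r
        for d in _child_directions(direction, m, spec, rng):
            stack.append((end_id, d, child_r, order - 1, child_len))
    return graph


def generate_rooted_tree(spec: TreeSpec) -> RootedTree:
    graph = generate_tree(spec)
    return root_tree(graph, graph.metadata["root_node"])


@dataclass
class PhantomVolume:
    """A voxelized phantom: binary vessel mask, optional compartment labels
    and the ground-truth spatial graph with per-point true radii."""

    mask: BinaryVolume
    graph: SpatialGraph
    labels: LabelVolume | None = None
    collapsed_segments: list[int] = field(default_factory=list)
    true_radii: dict[int, np.ndarray] = field(default_factory=dict)


def _rasterize_capsules(graph: SpatialGraph, data: np.ndarray, origin: np.ndarray, voxel: float) -> None:
    shape = np.array(data.shape)
    for seg in graph.segments.values():
        for i in range(seg.n_points - 1):
            p0, p1 = seg.points[i], seg.points[i + 1]
            r0, r1 = seg.radii[i], seg.radii[i + 1]
            rmax = max(r0, r1)
            lo = np.floor((np.minimum(p0, p1) - rmax - origin) / voxel).astype(int)
            hi = np.ceil((np.maximum(p0, p1) + rmax - origin) / voxel).astype(int) + 1
            lo = np.clip(lo, 0, shape)
            hi = np.clip(hi, 0, shape)
            if np.any(lo >= hi):
                continue
            ii, jj, kk = np.meshgrid(
                np.arange(lo[0], hi[0]),
                np.arange(lo[1], hi[1]),
                np.arange(lo[2], hi[2]),
                indexing="ij",
            )
            centres = np.stack([ii, jj, kk], axis=-1) * voxel + origin
            d = p1 - p0
            dd = float(np.dot(d, d))
            if dd == 0:
                continue
            t = np.einsum("...k,k->...", centres - p0, d) / dd
            tc = np.clip(t, 0.0, 1.0)
            closest = p0[None, None, None, :] + tc[..., None] * d[None, None, None, :]
            dist = np.linalg.norm(centres - closest, axis=-1)
            local_r = r0 + (r1 - r0) * tc
            # capsule joints bridge the wedge voids where consecutive
            # subsegments bend; the two segment termini stay flat-faced so a
            # straight tube keeps its exact πr²L volume (no end caps)
            inside = dist <= local_r
            if i == 0:
                inside &= t >= 0.0
            if i == seg.n_points - 2:
                inside &= t <= 1.0
            data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= inside


def voxelize_tree(
    graph: SpatialGraph | RootedTree,
    voxel_size: float,
    margin: float = 0.0,
    voxel_budget: int = 512**3,
) -> PhantomVolume:
    """Voxelize a tree into a binary capsule-union mask.

    A voxel is foreground iff its centre lies within the locally interpolated
    radius of any subsegment. The grid covers the graph bounding box (radii
    included) plus ``margin`` µm. Raises when the grid would exceed
    ``voxel_budget`` voxels, advising a coarser voxel size.
    """
    if isinstance(graph, RootedTree):
        graph = graph.graph
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    all_pts = np.concatenate([s.points for s in graph.segments.values()])
    all_r = np.concatenate([s.radii for s in graph.segments.values()])
    lo = (all_pts - all_r[:, None]).min(axis=0) - margin
    hi = (all_pts + all_r[:, None]).max(axis=0) + margin
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    if int(np.prod(shape)) > voxel_budget:
        raise ValueError(
            f"grid {tuple(shape)} exceeds the voxel budget ({voxel_budget}); "
            "use a coarser voxel size"
        )
    data = np.zeros(shape, dtype=bool)
    _rasterize_capsules(graph, data, lo, voxel_size)
    mask = BinaryVolume(data=data, voxel_size=voxel_size, origin=lo)
    return PhantomVolume(
        mask=mask,
        graph=graph,
        true_radii={sid: s.radii.copy() for sid, s in graph.segments.items()},
    )


def voxelize_graph_on_grid(graph: SpatialGraph, like: BinaryVolume) -> BinaryVolume:
    """Voxelize a graph onto an existing volume's grid (shape and origin)."""
    data = np.zeros(like.shape, dtype=bool)
    _rasterize_capsules(graph, data, like.origin, like.voxel_size)
    return BinaryVolume(data=data, voxel_size=like.voxel_size, origin=like.origin.copy())


def inject_collapse(
    phantom: PhantomVolume,
    fraction: float,
    severity: float,
    seed: int = 0,
    thin_mask: bool = False,
) -> PhantomVolume:
    """Plant collapse artifacts: scale the graph radii of a random fraction
    of segments by ``severity`` ∈ [0, 1) while (by default) leaving the mask
    patent — a skeleton under-reading a patent lumen. Returns a new phantom
    whose ``collapsed_segments`` lists the planted ground truth."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if not 0.0 <= severity < 1.0:
        raise ValueError("severity must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sids = sorted(phantom.graph.segments)
    n_pick = int(round(fraction * len(sids)))
    picked = sorted(rng.choice(sids, size=n_pick, replace=False).tolist()) if n_pick else []
    new_graph = phantom.graph.copy()
    for sid in picked:
        seg = new_graph.segments[sid]
        seg.radii = seg.radii * severity
    mask = phantom.mask
    if thin_mask and picked:
        thin_graph = SpatialGraph(
            nodes=dict(new_graph.nodes),
            segments={sid: new_graph.segments[sid].copy() for sid in picked},
        )
        collapsed_region = voxelize_graph_on_grid(
            SpatialGraph(nodes=dict(phantom.graph.nodes),
                         segments={sid: phantom.graph.segments[sid].copy() for sid in picked}),
            phantom.mask,
        )
        keep = voxelize_graph_on_grid(thin_graph, phantom.mask)
        data = phantom.mask.data & ~(collapsed_region.data & ~keep.data)
        mask = BinaryVolume(data=data, voxel_size=phantom.mask.voxel_size, origin=phantom.mask.origin.copy())
    return PhantomVolume(
        mask=mask,
        graph=new_graph,
        labels=phantom.labels,
        collapsed_segments=picked,
        true_radii={sid: r.copy() for sid, r in phantom.true_radii.items()},
    )


@dataclass
class CompartmentGeometry:
    """Nested ellipsoidal shells emulating organ anatomy: an inner core
    (hilum), a middle shell (medulla) crossed by angular pillar wedges, and
    an outer shell (cortex). Fractions are of the labelled organ volume."""

    semi_axes: tuple[float, float, float]  # µm
    cortex_fraction: float = 0.637
    hilum_fraction: float = 0.087
    pillar_fraction: float = 0.041
    n_pillars: int = 6

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")
        med = 1.0 - self.cortex_fraction - self.hilum_fraction
        if self.cortex_fraction <= 0 or self.hilum_fraction <= 0 or med <= 0:
            raise ValueError("shell fractions must be positive and sum below 1")
        if not 0 <= self.pillar_fraction < med:
            raise ValueError("pillar_fraction must be smaller than the medulla shell")


def generate_compartments(
    shape: tuple[int, int, int],
    voxel_size: float,
    geometry: CompartmentGeometry,
    origin: np.ndarray | None = None,
    centre: np.ndarray | None = None,
) -> LabelVolume:
    """Concentric-ellipsoid compartment label volume.

    Labels partition the organ ellipsoid with no gaps or overlaps:
    1 = cortex (outer shell), 2 = medulla (middle shell), 3 = hilum (inner
    core), 4 = intermedullary pillars (angular wedges carved out of the
    medulla shell), 0 = background. Shell radii are chosen analytically so
    the target volume fractions hold exactly in the continuum limit.
    """
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    shape_arr = np.array(shape)
    if centre is None:
        centre = origin + (shape_arr - 1) * voxel_size / 2.0
    ax = np.asarray(geometry.semi_axes, dtype=float)

    rho_hilum = geometry.hilum_fraction ** (1.0 / 3.0)
    rho_medulla = (1.0 - geometry.cortex_fraction) ** (1.0 / 3.0)

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    pos = np.stack([ii, jj, kk], axis=-1) * voxel_size + origin - centre
    rho = np.sqrt(np.sum((pos / ax) ** 2, axis=-1))

    data = np.zeros(shape, dtype=np.int32)
    data[rho <= 1.0] = 1  # cortex by default
    data[rho <= rho_medulla] = 2
    data[rho <= rho_hilum] = 3

    # pillar wedges: azimuthal sectors of the medulla shell
    medulla_frac = 1.0 - geometry.cortex_fraction - geometry.hilum_fraction
    wedge_total = 2 * np.pi * geometry.pillar_fraction / medulla_frac
    half_w = wedge_total / (2 * geometry.n_pillars)
    phi = np.arctan2(pos[..., 1], pos[..., 0])
    in_medulla = data == 2
    for p in range(geometry.n_pillars):
        centre_phi = -np.pi + (p + 0.5) * (2 * np.pi / geometry.n_pillars)
        d = np.abs((phi - centre_phi + np.pi) % (2 * np.pi) - np.pi)
        data[in_medulla & (d <= half_w)] = 4

    return LabelVolume(
        data=data,
        voxel_size=voxel_size,
        origin=origin,
        legend={0: "background", 1: "cortex", 2: "medulla", 3: "hilum", 4: "pillars"},
    )
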