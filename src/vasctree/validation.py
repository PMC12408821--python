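"""Segmentation and skeleton validation metrics.

Cross-resolution segmentation checks treat a higher-resolution segmentation
as ground truth: topological precision/recall count how much of each mask's
3D-thinned skeleton lies inside the other mask, and clDICE is their harmonic
mean. Skeleton quality against its source segmentation is scored by a
five-component super-metric: tube-volume discrepancy, connected-component
count difference, Euler-number difference, centreline sensitivity and
bifurcation DICE, combined as a weighted Euclidean norm (zero iff perfect
agreement on every component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure
from skimage.morphology import skeletonize

from .graph import RootedTree, SpatialGraph
from .volumes import BinaryVolume

__all__ = [
    "TopoPRResult",
    "SuperMetricResult",
    "topo_precision_recall",
    "detection_rate_by_radius",
    "skeleton_supermetric",
]


@dataclass
class TopoPRResult:
    precision: float | None
    recall: float | None
    cl_dice: float

    @staticmethod
    def combine(precision: float | None, recall: float | None) -> "TopoPRResult":
        if precision is None or recall is None or (precision + recall) == 0:
            return TopoPRResult(precision=precision, recall=recall, cl_dice=0.0)
        cl = 2 * precision * recall / (precision + recall)
        return TopoPRResult(precision=precision, recall=recall, cl_dice=cl)


def _skeleton_fraction_inside(source: np.ndarray, other: np.ndarray) -> float | None:
    """Fraction of ``source``'s thinned-skeleton voxels lying in ``other``."""
    if not source.any():
        return None
    skel = skeletonize(source)
    if not skel.any():
        # 3D thinning can annihilate tiny/even-width objects; fall back to
        # the mask voxels themselves so degenerate inputs stay scoreable
        skel = source
    n = int(skel.sum())
    return float(np.logical_and(skel, other).sum()) / n


def topo_precision_recall(pred_mask: BinaryVolume, gt_mask: BinaryVolume) -> TopoPRResult:
    """Topological precision/recall and clDICE between two binary masks.

    Precision: fraction of the predicted mask's skeleton inside the ground
    truth; recall: fraction of the ground-truth skeleton inside the
    prediction. Swapping the masks swaps precision and recall exactly.
    """
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {gt_mask.shape}")
    precision = _skeleton_fraction_inside(pred_mask.data, gt_mask.data)
    recall = _skeleton_fraction_inside(gt_mask.data, pred_mask.data)
    return TopoPRResult.combine(precision, recall)


def detection_rate_by_radius(
    gt_tree: RootedTree | SpatialGraph,
    pred_mask: BinaryVolume,
    radius_threshold: float,
    min_point_fraction: float = 0.5,
) -> float | None:
    """Fraction of ground-truth segments above a radius threshold that are
    detected in a predicted mask.

    A segment with mean radius > ``radius_threshold`` µm counts as detected
    when at least ``min_point_fraction`` of its centreline points fall on
    mask foreground. Returns None when no segment qualifies.
    """
    graph = gt_tree.graph if isinstance(gt_tree, RootedTree) else gt_tree
    qualifying = 0
    detected = 0
    for seg in graph.segments.values():
        if seg.mean_radius <= radius_threshold:
            continue
        qualifying += 1
        hits = sum(bool(pred_mask.value_at(p)) for p in seg.points)
        if hits / seg.n_points >= min_point_fraction:
            detected += 1
    if qualifying == 0:
        return None
    return detected / qualifying


@dataclass
class SuperMetricResult:
    volume_discrepancy: float  # |tube volume − mask volume| / mask volume
    cc_difference: float  # |ΔCC|
    euler_difference: float  # |ΔEuler|
    centreline_sensitivity: float  # ∈ [0, 1]
    bifurcation_dice: float  # ∈ [0, 1]
    weights: np.ndarray
    score: float

    def components(self) -> np.ndarray:
        """Distance-vector form (sensitivity and DICE as 1 − value)."""
        return np.array(
            [
                self.volume_discrepancy,
                self.cc_difference,
                self.euler_difference,
                1.0 - self.centreline_sensitivity,
                1.0 - self.bifurcation_dice,
            ]
        )


def _branch_points_of_graph(graph: SpatialGraph) -> np.ndarray:
    inc = graph.node_incidence()
    pts = [graph.nodes[nid].position for nid, segs in inc.items() if len(segs) >= 3]
    return np.array(pts).reshape(-1, 3)


def _branch_points_of_mask(mask: BinaryVolume) -> np.ndarray:
    """Branch points of the mask's thinned skeleton: skeleton voxels with
    three or more skeleton neighbours (26-connectivity). Adjacent branch
    voxels belong to one junction, so connected clusters are collapsed to
    their centroids; positions in µm."""
    skel = skeletonize(mask.data)
    if not skel.any():
        return np.zeros((0, 3))
    padded = np.pad(skel, 1)
    neigh = np.zeros_like(padded, dtype=np.int16)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                neigh += np.roll(padded, (dx, dy, dz), axis=(0, 1, 2))
    branch = (padded & (neigh >= 3))[1:-1, 1:-1, 1:-1]
    if not branch.any():
        return np.zeros((0, 3))
    labels = measure.label(branch, connectivity=3)
    centroids = np.array([p.centroid for p in measure.regionprops(labels)])
    return centroids * mask.voxel_size + mask.origin


def _greedy_match(a: np.ndarray, b: np.ndarray, radius: float) -> int:
    """Number of greedy nearest-neighbour matches between two point sets
    within a capture radius (deterministic: pairs taken closest first)."""
    if len(a) == 0 or len(b) == 0:
        return 0
    tree = cKDTree(b)
    pairs = []
    for i, p in enumerate(a):
        js = tree.query_ball_point(p, radius)
        for j in js:
            pairs.append((float(np.linalg.norm(p - b[j])), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches += 1
    return matches


def skeleton_supermetric(
    skeleton: SpatialGraph,
    seg_mask: BinaryVolume,
    weights: np.ndarray | None = None,
    capture_radius_voxels: float = 2.0,
) -> SuperMetricResult:
    """Five-component skeleton-vs-segmentation super-metric.

    The skeleton is reconstructed into a tube volume (capsule union on the
    mask's grid) and compared against the segmentation: relative tube/mask
    volume discrepancy, absolute connected-component and Euler-number
    differences, centreline sensitivity (fraction of skeleton points on mask
    foreground) and bifurcation DICE (branch points of the skeleton graph vs
    branch points of the mask's thinned skeleton, greedily matched within
    ``capture_radius_voxels``). The combined score is the weighted Euclidean
    norm of the component vector with sensitivity and DICE entering as
    (1 − value); it is 0 iff every component indicates perfect agreement and
    homogeneous of degree 1 in the weights.
    """
    from .synthetic import voxelize_graph_on_grid  # local import: avoids a cycle

    if not seg_mask.data.any():
        raise ValueError("skeleton_supermetric: empty segmentation mask")
    weights = np.ones(5) if weights is None else np.asarray(weights, dtype=float)
    if weights.shape != (5,) or np.any(weights < 0):
        raise ValueError("weights must be 5 non-negative values")

    tube = voxelize_graph_on_grid(skeleton, seg_mask)
    mask_vol = seg_mask.foreground_volume()
    vol_disc = abs(tube.foreground_volume() - mask_vol) / mask_vol

    cc_tube = int(measure.label(tube.data, connectivity=3).max())
    cc_mask = int(measure.label(seg_mask.data, connectivity=3).max())
    cc_diff = abs(cc_tube - cc_mask)

    euler_diff = abs(
        int(measure.euler_number(tube.data, connectivity=3))
        - int(measure.euler_number(seg_mask.data, connectivity=3))
    )

    pts = np.concatenate([s.points for s in skeleton.segments.values()])
    inside = sum(bool(seg_mask.value_at(p)) for p in pts)
    sensitivity = inside / len(pts) if len(pts) else 0.0

    bp_graph = _branch_points_of_graph(skeleton)
    bp_mask = _branch_points_of_mask(seg_mask)
    n_match = _greedy_match(
        bp_graph, bp_mask, capture_radius_voxels * seg_mask.voxel_size
    )
    denom = len(bp_graph) + len(bp_mask)
    bb_dice = 2.0 * n_match / denom if denom else 1.0

    result = SuperMetricResult(
        volume_discrepancy=vol_disc,
        cc_difference=float(cc_diff),
        euler_difference=float(euler_diff),
        centreline_sensitivity=float(sensitivity),
        bifurcation_dice=float(bb_dice),
        weights=weights,
        score=0.0,
    )
    result.score = float(np.linalg.norm(weights * result.components()))
    return result
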