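"""Per-segment branching metrics and grouped summary tables.

Metrics per segment: mean radius, arc length, tortuosity (arc/chord >= 1),
length:diameter ratio, truncated-cone volume, branching angle (child–parent
by default, child–child available), midpoint inter-vessel distance, order,
generation and anatomical compartment. Summaries group these by truncated
Strahler order (per-order table) or by compartment (per-zone table with
tissue volumes and percentages).

Two inter-vessel-distance estimators are provided: a graph estimator (the
Euclidean distance between a segment's arc-length midpoint and the nearest
other segment's midpoint) and a voxel estimator (exact 3D Euclidean distance
transform of the vessel mask, i.e. the distance of every tissue voxel to its
nearest vessel voxel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .graph import RootedTree, Segment, SpatialGraph
from .ordering import OrderingResult
from .volumes import BinaryVolume, LabelVolume

__all__ = [
    "tortuosity",
    "branching_angles",
    "segment_volume",
    "segment_midpoint",
    "ivd_midpoint",
    "ivd_voxel",
    "assign_compartments",
    "compute_morphometry",
    "summarize",
]


def tortuosity(segment: Segment) -> float:
    """Arc length over chord length (>= 1); NaN for loop-back segments whose
    endpoints coincide (the chord is zero and the ratio undefined)."""
    chord = segment.chord_length
    if chord == 0:
        return float("nan")
    return segment.length / chord


def _chord(seg: Segment) -> np.ndarray:
    """Start-to-end vector (proximal to distal), ignoring tortuosity."""
    return seg.points[-1] - seg.points[0]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def branching_angles(tree: RootedTree, mode: str = "child_parent") -> dict[int, float]:
    """Branching angles in degrees, from segment chord vectors.

    ``child_parent``: per non-root segment, the angle at the shared junction
    between the vector junction -> parent start node and the vector
    junction -> child end node, so a straight continuation scores 180°.
    ``child_child``: per junction (keyed by the parent segment id), the angle
    between the two child chords; junctions with more than two children
    report the mean over all child pairs.
    """
    graph = tree.graph
    if mode == "child_parent":
        out: dict[int, float] = {}
        for sid, pid in tree.parent.items():
            if pid is None:
                out[sid] = float("nan")
                continue
            child = graph.segments[sid]
            parent = graph.segments[pid]
            junction = child.points[0]
            to_parent_start = parent.points[0] - junction
            to_child_end = child.points[-1] - junction
            out[sid] = _angle_deg(to_parent_start, to_child_end)
        return out
    if mode == "child_child":
        out = {}
        for pid, kids in tree.children.items():
            if len(kids) < 2:
                continue
            chords = [_chord(graph.segments[k]) for k in kids]
            angles = [
                _angle_deg(chords[i], chords[j])
                for i in range(len(chords))
                for j in range(i + 1, len(chords))
            ]
            out[pid] = float(np.nanmean(angles))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def segment_volume(segment: Segment) -> float:
    """Truncated-cone (midpoint-rule) volume: Σ π r̄² ℓ over subsegments,
    with r̄ the mean of the two bounding point radii, µm³."""
    r = segment.radii
    rbar = 0.5 * (r[:-1] + r[1:])
    return float(np.sum(np.pi * rbar**2 * segment.step_lengths()))


def segment_midpoint(segment: Segment) -> np.ndarray:
    """Point at half arc length along the polyline (linear interpolation)."""
    steps = segment.step_lengths()
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half, side="right") - 1)
    i = min(i, len(steps) - 1)
    frac = (half - cum[i]) / steps[i] if steps[i] > 0 else 0.0
    return segment.points[i] + frac * (segment.points[i + 1] - segment.points[i])


def ivd_midpoint(graph: SpatialGraph | RootedTree) -> dict[int, float]:
    """Midpoint inter-vessel distance: for every segment, the Euclidean
    distance from its midpoint to the nearest other segment's midpoint
    (self excluded; exact ties broken toward the smaller segment id).
    Single-segment graphs return NaN."""
    if isinstance(graph, RootedTree):
        graph = graph.graph
    sids = sorted(graph.segments)
    if len(sids) < 2:
        return {sid: float("nan") for sid in sids}
    mids = np.array([segment_midpoint(graph.segments[sid]) for sid in sids])
    tree = cKDTree(mids)
    k = min(len(sids), 8)
    dists, idxs = tree.query(mids, k=k)
    out: dict[int, float] = {}
    for row, sid in enumerate(sids):
        best_d, best_sid = np.inf, None
        for d, j in zip(dists[row], idxs[row]):
            if j == row:
                continue
            if d < best_d - 1e-12:
                best_d, best_sid = d, sids[j]
            elif abs(d - best_d) <= 1e-12 and sids[j] < best_sid:
                best_sid = sids[j]
        out[sid] = float(best_d)
    return out


def ivd_voxel(
    vessel_mask: BinaryVolume, region_labels: LabelVolume | None = None
) -> tuple[np.ndarray, dict]:
    """Exact 3D Euclidean distance transform of the vessel mask, µm.

    Every non-vessel voxel gets its distance to the nearest vessel voxel.
    Returns the distance map and per-region statistics over non-vessel
    voxels (one pooled region ``all`` without labels).
    """
    if not vessel_mask.data.any():
        raise ValueError("ivd_voxel: empty vessel mask")
    dist = ndimage.distance_transform_edt(
        ~vessel_mask.data, sampling=vessel_mask.voxel_size
    )
    stats: dict[str, dict] = {}

    def _region_stats(mask: np.ndarray) -> dict:
        vals = dist[mask & ~vessel_mask.data]
        if vals.size == 0:
            return {"mean": None, "sd": None, "max": None, "n_voxels": 0}
        return {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "max": float(vals.max()),
            "n_voxels": int(vals.size),
        }

    if region_labels is None:
        stats["all"] = _region_stats(np.ones_like(vessel_mask.data, dtype=bool))
    else:
        for lab, name in region_labels.legend.items():
            if name == "background":
                continue
            stats[name] = _region_stats(region_labels.data == lab)
    return dist, stats


def assign_compartments(tree: RootedTree, labels: LabelVolume) -> RootedTree:
    """Label every segment with the anatomical compartment its points lie in.

    A segment whose points all carry one non-background label gets that
    compartment; segments crossing two or more compartments (or lying wholly
    in background / outside the labelled space) are marked ``excluded``.
    """
    background = {lab for lab, name in labels.legend.items() if name == "background"}
    out = tree.copy()
    for sid, seg in out.graph.segments.items():
        idx = np.rint((seg.points - labels.origin) / labels.voxel_size).astype(int)
        inside = np.all(idx >= 0, axis=1) & np.all(idx < np.array(labels.shape), axis=1)
        labs = set(labels.data[idx[inside, 0], idx[inside, 1], idx[inside, 2]].tolist())
        labs -= background
        if len(labs) == 1:
            seg.compartment = labels.legend.get(labs.pop(), "unknown")
        else:
            seg.compartment = "excluded"
    return out


_METRICS = [
    "mean_radius_um",
    "length_um",
    "tortuosity",
    "length_diameter",
    "volume_um3",
    "branching_angle_deg",
    "ivd_um",
]


def compute_morphometry(
    tree: RootedTree,
    ordering: OrderingResult | None = None,
    angle_mode: str = "child_parent",
) -> pd.DataFrame:
    """Per-segment morphometry table (one row per segment, indexed by id)."""
    graph = tree.graph
    angles = branching_angles(tree, mode=angle_mode)
    ivd = ivd_midpoint(graph)
    rows = []
    for sid in sorted(graph.segments):
        seg = graph.segments[sid]
        mean_r = seg.mean_radius
        length = seg.length
        rows.append(
            {
                "segment_id": sid,
                "mean_radius_um": mean_r,
                "length_um": length,
                "tortuosity": tortuosity(seg),
                "length_diameter": length / (2.0 * mean_r) if mean_r > 0 else np.nan,
                "volume_um3": segment_volume(seg),
                "branching_angle_deg": angles.get(sid, np.nan),
                "ivd_um": ivd[sid],
                "order": ordering.order.get(sid) if ordering else None,
                "generation": ordering.generation.get(sid) if ordering else None,
                "compartment": seg.compartment,
            }
        )
    return pd.DataFrame(rows).set_index("segment_id")


def summarize(
    records: pd.DataFrame,
    group_by: str = "order",
    labels: LabelVolume | None = None,
) -> pd.DataFrame:
    """Grouped summary: n and mean ± SD of every metric per group.

    ``group_by='order'`` yields a per-order branching-metrics table;
    ``group_by='compartment'`` yields a per-zone table which, when a label
    volume is supplied, also carries tissue volume per compartment and its
    percentage of the labelled total, plus segment-count percentages.
    """
    if group_by not in ("order", "compartment"):
        raise ValueError("group_by must be 'order' or 'compartment'")
    df = records.dropna(subset=[group_by])
    groups = df.groupby(group_by, sort=True)
    out = pd.DataFrame({"n": groups.size()})
    for metric in _METRICS:
        out[f"{metric}_mean"] = groups[metric].mean()
        out[f"{metric}_sd"] = groups[metric].std(ddof=1)
    total = len(df)
    out["pct_segments"] = 100.0 * out["n"] / total if total else np.nan
    if group_by == "compartment" and labels is not None:
        vols = labels.label_volumes()
        total_tissue = sum(vols.values())
        out["tissue_volume_um3"] = [vols.get(name) for name in out.index]
        out["pct_tissue"] = [
            100.0 * vols[name] / total_tissue if name in vols else np.nan
            for name in out.index
        ]
    return out
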