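"""Truncated Strahler ordering, topological generations and branching ratio.

Whole-organ imaging cannot resolve the true terminal vessels (afferent
arterioles), so Strahler ordering is *truncated*: the observed terminal ends
of the network are assigned order 1, and the root carries the maximum order.
Orders increase centripetally — when two (or more) children sharing the
current maximum order meet, the parent's order is one greater; otherwise the
parent inherits the maximum child order. Topological generation is the
centrifugal counterpart: the root segment is generation 1 and the generation
increments at every branching node (degree-2 pass-through nodes are geometry,
not topology, and increment neither quantity).

The branching ratio γ summarises the multiplicative growth of segment counts
per order via the log-linear relation N = N0 · exp(−O/γ): a least-squares fit
of ln N against O has slope −1/γ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import GraphError, RootedTree

__all__ = [
    "OrderingResult",
    "BranchingRatioFit",
    "assign_truncated_strahler",
    "assign_topological_generation",
    "fit_branching_ratio",
    "map_orders_to_anatomy",
    "estimate_missing_orders",
    "extrapolate_glomeruli",
]


@dataclass
class OrderingResult:
    """Per-segment truncated Strahler orders and/or topological generations."""

    order: dict[int, int] = field(default_factory=dict)
    generation: dict[int, int] = field(default_factory=dict)

    @property
    def order_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for o in self.order.values():
            counts[o] = counts.get(o, 0) + 1
        return dict(sorted(counts.items()))

    @property
    def n_orders(self) -> int:
        return len(set(self.order.values()))

    def merged_with(self, other: "OrderingResult") -> "OrderingResult":
        return OrderingResult(
            order={**self.order, **other.order},
            generation={**self.generation, **other.generation},
        )


def _branching_children(tree: RootedTree, sid: int) -> list[int]:
    return tree.children[sid]


def assign_truncated_strahler(tree: RootedTree) -> OrderingResult:
    """Assign truncated Strahler orders: leaves are order 1; at a junction the
    parent gets max(child orders) + 1 if that maximum is shared by >= 2
    children (the multifurcation generalisation), else max(child orders)."""
    if not isinstance(tree, RootedTree):
        raise GraphError("assign_truncated_strahler requires a rooted tree")
    order: dict[int, int] = {}
    for sid in tree.segments_postorder():
        kids = tree.children[sid]
        if not kids:
            order[sid] = 1
        else:
            child_orders = [order[k] for k in kids]
            top = max(child_orders)
            order[sid] = top + 1 if child_orders.count(top) >= 2 else top
    return OrderingResult(order=order)


def assign_topological_generation(tree: RootedTree) -> OrderingResult:
    """Centrifugal generations: root segment is generation 1; the generation
    increments across every branching node (>= 2 children)."""
    if not isinstance(tree, RootedTree):
        raise GraphError("assign_topological_generation requires a rooted tree")
    gen: dict[int, int] = {}
    for sid in tree.segments_preorder():
        pid = tree.parent[sid]
        if pid is None:
            gen[sid] = 1
        else:
            siblings = tree.children[pid]
            gen[sid] = gen[pid] + 1 if len(siblings) >= 2 else gen[pid]
    return OrderingResult(generation=gen)


@dataclass
class BranchingRatioFit:
    gamma: float
    n0: float
    fit_range: tuple[int, int]
    residuals: np.ndarray
    orders_used: np.ndarray
    counts_used: np.ndarray

    def predicted_counts(self) -> np.ndarray:
        return self.n0 * np.exp(-self.orders_used / self.gamma)


def fit_branching_ratio(
    order_counts: dict[int, int], fit_range: tuple[int, int] | None = None
) -> BranchingRatioFit:
    """OLS fit of ln N on O over ``fit_range`` (inclusive; default all orders).

    Returns γ = exp(−slope) and N0 = exp(intercept) so that the fitted model
    is N = N0 · exp(−O/γ). Orders with zero count inside the range are
    excluded (they have no log).
    """
    items = sorted(order_counts.items())
    if fit_range is not None:
        lo, hi = fit_range
        items = [(o, n) for o, n in items if lo <= o <= hi]
    else:
        fit_range = (items[0][0], items[-1][0]) if items else (0, 0)
    items = [(o, n) for o, n in items if n > 0]
    if len(items) < 2:
        raise ValueError("fit_branching_ratio: need >= 2 orders with positive counts")
    orders = np.array([o for o, _ in items], dtype=float)
    counts = np.array([n for _, n in items], dtype=float)
    logn = np.log(counts)
    slope, intercept = np.polyfit(orders, logn, 1)
    gamma = math.exp(-slope)
    n0 = math.exp(intercept)
    resid = logn - (intercept + slope * orders)
    return BranchingRatioFit(
        gamma=gamma,
        n0=n0,
        fit_range=tuple(fit_range),
        residuals=resid,
        orders_used=orders,
        counts_used=counts,
    )


def map_orders_to_anatomy(
    tree: RootedTree,
    ordering: OrderingResult,
    anatomy_map: dict[str, tuple[int, int]],
) -> dict[str, dict]:
    """Group segments into anatomical vessel classes by order range.

    ``anatomy_map`` maps a class name (e.g. ``interlobar``) to an inclusive
    order range; ranges may overlap (classes are reported independently, not
    as a partition). Returns per class: ``n``, ``mean_radius_um``,
    ``sd_radius_um`` (None when the class is empty).
    """
    out: dict[str, dict] = {}
    for name, (lo, hi) in anatomy_map.items():
        sids = [sid for sid, o in ordering.order.items() if lo <= o <= hi]
        radii = np.array([tree.graph.segments[sid].mean_radius for sid in sids])
        out[name] = {
            "orders": (lo, hi),
            "n": len(sids),
            "mean_radius_um": float(radii.mean()) if len(sids) else None,
            "sd_radius_um": float(radii.std(ddof=1)) if len(sids) > 1 else None,
            "segment_ids": sorted(sids),
        }
    return out


def estimate_missing_orders(n_terminal: float, gamma: float, n_endpoints_true: float) -> float:
    """Fractional number of Strahler orders between the observed terminal ends
    and the true network endpoints, assuming counts keep growing by γ per
    order: k = ln(true endpoints / observed terminals) / ln γ."""
    if n_terminal <= 0 or n_endpoints_true <= 0:
        raise ValueError("counts must be positive")
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    return math.log(n_endpoints_true / n_terminal) / math.log(gamma)


def extrapolate_glomeruli(
    voi_counts: list[float],
    voi_cortex_volumes: list[float],
    total_cortex_volume: float,
) -> dict:
    """Scale per-VOI glomerular counts by cortex volume to whole-organ
    estimates; the pooled estimate is the mean of the per-VOI estimates."""
    if len(voi_counts) != len(voi_cortex_volumes):
        raise ValueError("voi_counts and voi_cortex_volumes length mismatch")
    if any(v <= 0 for v in voi_cortex_volumes) or total_cortex_volume <= 0:
        raise ValueError("volumes must be positive")
    per_voi = [
        c * total_cortex_volume / v for c, v in zip(voi_counts, voi_cortex_volumes)
    ]
    return {"per_voi": per_voi, "pooled": float(np.mean(per_voi))}
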