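"""Radial scaling analysis: Murray's law, downstream-tip counting, the
radial scaling exponent by standard major axis (SMA) regression, and
cross-network log-linear comparison.

At a bifurcation an optimal network satisfies R_parent^(1/a) = Σ
R_child^(1/a); Murray's law (minimum work for laminar Newtonian flow under
uniform metabolic demand) gives a = 1/3, while the West–Brown–Enquist
fractal-distribution model gives a = 1/2 for large vessels. Network-wide,
the radius of a vessel scales with the number of downstream network
endpoints N_d as R ∝ N_d^a, so a is the slope of log R against log N_d.
SMA regression is used because both radius and tip count carry measurement
error: the slope is sign(r)·SD(log R)/SD(log N_d), with the standard SMA
confidence interval at α = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph import GraphError, RootedTree

__all__ = [
    "ScalingFit",
    "ComparisonResult",
    "downstream_tip_counts",
    "radial_scaling_exponent",
    "scaling_pairs",
    "sma_regression",
    "murray_table",
    "compare_order_radius_fits",
]


def downstream_tip_counts(tree: RootedTree) -> dict[int, int]:
    """Number of network endpoints downstream of every segment: leaves count
    1, internal segments sum their children, the root totals all leaves."""
    if not isinstance(tree, RootedTree):
        raise GraphError("downstream_tip_counts requires a rooted tree")
    nd: dict[int, int] = {}
    for sid in tree.segments_postorder():
        kids = tree.children[sid]
        nd[sid] = 1 if not kids else sum(nd[k] for k in kids)
    return nd


@dataclass
class ScalingFit:
    exponent: float  # a
    ci: tuple[float, float]  # 95% CI on a
    intercept: float  # of log10 R on log10 N_d
    r: float  # correlation of the log pairs
    n: int
    pairs: np.ndarray  # (n, 2): R µm, N_d
    method: str = "sma"


def sma_regression(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, float, tuple[float, float], float]:
    """Standard major axis regression of y on x.

    Returns (slope, intercept, (ci_lo, ci_hi), r). The slope is
    sign(r)·SD(y)/SD(x); the CI follows the standard SMA interval
    b·(sqrt(B+1) ± sqrt(B)) with B = F(1−α; 1, n−2)·(1−r²)/(n−2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("SMA regression needs >= 3 points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("SMA regression: zero variance in a variable")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(y.mean() - slope * x.mean())
    fcrit = stats.f.ppf(1 - alpha, 1, n - 2)
    B = fcrit * (1 - r**2) / (n - 2)
    lo = slope * (math.sqrt(B + 1) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1) + math.sqrt(B))
    if lo > hi:
        lo, hi = hi, lo
    return slope, intercept, (lo, hi), r


def radial_scaling_exponent(pairs: np.ndarray, alpha: float = 0.05) -> ScalingFit:
    """Fit R ∝ N_d^a by SMA regression of log10 R on log10 N_d.

    ``pairs`` is an (n, 2) array of (radius µm, downstream tip count); all
    entries must be positive.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (n, 2): (radius, N_d)")
    if np.any(pairs <= 0):
        raise ValueError("radii and tip counts must be positive")
    logr = np.log10(pairs[:, 0])
    lognd = np.log10(pairs[:, 1])
    slope, intercept, ci, r = sma_regression(lognd, logr, alpha=alpha)
    return ScalingFit(
        exponent=slope, ci=ci, intercept=intercept, r=r, n=len(pairs), pairs=pairs
    )


def scaling_pairs(tree: RootedTree) -> np.ndarray:
    """(mean radius, downstream tip count) for every segment of the tree."""
    nd = downstream_tip_counts(tree)
    return np.array(
        [[tree.graph.segments[sid].mean_radius, nd[sid]] for sid in sorted(nd)]
    )


def murray_table(tree: RootedTree, exponent: float = 1.0 / 3.0) -> pd.DataFrame:
    """Per-junction cube-law table: parent radius^(1/a) vs Σ child
    radius^(1/a) (Murray's case a = 1/3 by default), with the relative
    deviation (Σ r_c³ − r_p³)/r_p³. Junctions are keyed by parent segment;
    multifurcations sum over all children. Segment mean radii are used."""
    p = 1.0 / exponent
    rows = []
    for pid, kids in sorted(tree.children.items()):
        if len(kids) < 2:
            continue
        rp = tree.graph.segments[pid].mean_radius
        rc = np.array([tree.graph.segments[k].mean_radius for k in kids])
        parent_pow = rp**p
        child_pow = float(np.sum(rc**p))
        rows.append(
            {
                "parent_segment": pid,
                "n_children": len(kids),
                "parent_radius_um": rp,
                "parent_radius_pow": parent_pow,
                "sum_child_radius_pow": child_pow,
                "deviation": (child_pow - parent_pow) / parent_pow if parent_pow > 0 else np.nan,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "parent_segment",
            "n_children",
            "parent_radius_um",
            "parent_radius_pow",
            "sum_child_radius_pow",
            "deviation",
        ],
    )
    return df


@dataclass
class ComparisonResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    fit_a: tuple[float, float]  # slope, intercept of log10(radius) vs order
    fit_b: tuple[float, float]
    fit_pooled: tuple[float, float]
    ss_separate: float
    ss_pooled: float


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    ss = float(np.sum((y - (intercept + slope * x)) ** 2))
    return float(slope), float(intercept), ss


def compare_order_radius_fits(
    table_a: dict[int, float], table_b: dict[int, float], anchor_order: int | None
) -> ComparisonResult:
    """Sum-of-squares F-test comparing log-linear radius-vs-order fits of two
    networks.

    With an ``anchor_order``, each table is first normalised so that order's
    radius maps to 1 (the cross-species presentation convention); the
    normalisation is a constant shift in log space per table, so it does not
    affect the separate fits. ``anchor_order=None`` skips it. log10(radius)
    is regressed on order separately and pooled; the null hypothesis is that
    one global slope and intercept fits both:
    F = [(SS_pooled − SS_separate)/2] / [SS_separate/(n_a + n_b − 4)].

    Note that anchoring each table by its own *measured* anchor radius makes
    the two tables' residuals share that measurement's noise, so the F test
    is only exactly calibrated on unanchored (or commonly scaled) tables.
    """
    for name, tab in (("a", table_a), ("b", table_b)):
        if anchor_order is not None and anchor_order not in tab:
            raise ValueError(f"anchor order {anchor_order} missing from table {name}")
        if len(tab) < 3:
            raise ValueError(f"table {name} needs >= 3 orders")

    def _norm(tab: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
        orders = np.array(sorted(tab), dtype=float)
        radii = np.array([tab[int(o)] for o in orders], dtype=float)
        scale = tab[anchor_order] if anchor_order is not None else 1.0
        return orders, np.log10(radii / scale)

    xa, ya = _norm(table_a)
    xb, yb = _norm(table_b)
    sa, ia, ssa = _ols(xa, ya)
    sb, ib, ssb = _ols(xb, yb)
    sp, ip, ssp = _ols(np.concatenate([xa, xb]), np.concatenate([ya, yb]))
    ss_sep = ssa + ssb
    df_num = 2
    df_den = len(xa) + len(xb) - 4
    y_all = np.concatenate([ya, yb])
    eps = 1e-12 * max(float(np.sum((y_all - y_all.mean()) ** 2)), 1e-30)
    if ss_sep <= eps:
        if ssp - ss_sep <= eps:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = ((ssp - ss_sep) / df_num) / (ss_sep / df_den)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return ComparisonResult(
        f_statistic=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        fit_a=(sa, ia),
        fit_b=(sb, ib),
        fit_pooled=(sp, ip),
        ss_separate=ss_sep,
        ss_pooled=ssp,
    )
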