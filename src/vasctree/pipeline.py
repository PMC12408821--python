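"""End-to-end orchestration: root → order → smooth → flag → correct →
re-order → morphometry → scaling, with a run log and delimited outputs.

``run_pipeline`` executes the correction-and-analysis chain on a spatial
graph (optionally with a binary vessel volume for radius correction and a
compartment label volume for zonal tables) and writes every result it
computes — the corrected graph, per-order and per-compartment summary
tables, the branching-ratio and radial-scaling fits and a parameter log —
into an output directory. ``make_report`` renders the standard figures
(order histogram, log-count vs order with the γ fit, the Murray plot and the
log-log radius vs downstream-tips SMA fit) from a result bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as graph_io
from .graph import RootedTree, SpatialGraph, root_tree, validate_graph
from .morphometry import assign_compartments, compute_morphometry, summarize
from .ordering import (
    assign_topological_generation,
    assign_truncated_strahler,
    fit_branching_ratio,
)
from .scaling import murray_table, radial_scaling_exponent, scaling_pairs
from .skeleton import (
    CollapseFlags,
    SmoothingConfig,
    correct_collapsed_radii,
    flag_collapsed,
    repair_short_collapses,
)
from .volumes import BinaryVolume, LabelVolume

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_report"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    """Parameters of the full correction/analysis chain. Defaults are the
    study conditions: smoothing 0.8/0.1 × 15 at order >= 5; collapse flag at
    the 10th radius percentile; plane windowing at the 5th–95th."""

    root: int | str = "auto"
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    collapse_percentile: float = 10.0
    large_order: int = 5
    repair_percentile: float = 5.0
    window: tuple[float, float] = (5.0, 95.0)
    gamma_fit_range: tuple[int, int] | None = None
    angle_mode: str = "child_parent"
    decisions: dict[int, bool] | None = None
    seed: int = 0
    output_dir: str | Path | None = None


@dataclass
class PipelineResult:
    tree: RootedTree
    ordering: object
    morphometry: object
    order_table: object
    compartment_table: object | None
    branching_fit: object
    scaling_fit: object
    murray: object
    flags: CollapseFlags
    correction_report: dict
    log: dict


def run_pipeline(
    graph: SpatialGraph,
    config: PipelineConfig | None = None,
    volume: BinaryVolume | None = None,
    labels: LabelVolume | None = None,
) -> PipelineResult:
    """Run the full chain on a spatial graph; see the module docstring.

    Radius correction runs only when a binary ``volume`` is supplied; the
    compartment table only when ``labels`` are supplied. Raises
    :class:`PipelineError` naming the failing stage.
    """
    cfg = config or PipelineConfig()
    log: dict = {"seed": cfg.seed, "parameters": {
        "root": cfg.root,
        "smoothing": vars(cfg.smoothing),
        "collapse_percentile": cfg.collapse_percentile,
        "large_order": cfg.large_order,
        "repair_percentile": cfg.repair_percentile,
        "window": list(cfg.window),
        "gamma_fit_range": cfg.gamma_fit_range,
        "angle_mode": cfg.angle_mode,
    }}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, str(exc)) from exc

    report = stage("validate", validate_graph, graph)
    if not report.is_clean:
        raise PipelineError("validate", f"graph defects: {report}")
    tree = stage("root", root_tree, graph, cfg.root)
    ordering = stage("order", assign_truncated_strahler, tree)

    from .skeleton import smooth_centerlines

    tree = stage("smooth", smooth_centerlines, tree, ordering, cfg.smoothing)
    flags = stage(
        "flag", flag_collapsed, tree, ordering, cfg.collapse_percentile, cfg.large_order
    )
    correction_report: dict = {}
    if volume is not None:
        tree, correction_report = stage(
            "correct",
            correct_collapsed_radii,
            tree,
            volume,
            flags,
            decisions=cfg.decisions,
            window=cfg.window,
        )
    for sid in list(tree.graph.segments):
        tree.graph.segments[sid] = stage(
            "repair", repair_short_collapses, tree.graph.segments[sid], cfg.repair_percentile
        )

    ordering = stage("reorder", assign_truncated_strahler, tree).merged_with(
        stage("generations", assign_topological_generation, tree)
    )
    if labels is not None:
        tree = stage("compartments", assign_compartments, tree, labels)
    records = stage("morphometry", compute_morphometry, tree, ordering, cfg.angle_mode)
    order_table = stage("summarize", summarize, records, "order")
    compartment_table = (
        stage("summarize_zones", summarize, records, "compartment", labels)
        if labels is not None
        else None
    )
    # degenerate networks (a single order, or no tip-count spread) simply
    # have no branching-ratio / scaling fit rather than failing the run
    try:
        branching = fit_branching_ratio(ordering.order_counts, cfg.gamma_fit_range)
    except ValueError:
        branching = None
    pairs = stage("tips", scaling_pairs, tree)
    try:
        fit = radial_scaling_exponent(pairs)
    except ValueError:
        fit = None
    murray = stage("murray", murray_table, tree)

    log["stages"] = [
        "validate", "root", "order", "smooth", "flag",
        "correct" if volume is not None else "correct(skipped: no volume)",
        "repair", "reorder", "morphometry", "scaling",
    ]
    result = PipelineResult(
        tree=tree,
        ordering=ordering,
        morphometry=records,
        order_table=order_table,
        compartment_table=compartment_table,
        branching_fit=branching,
        scaling_fit=fit,
        murray=murray,
        flags=flags,
        correction_report=correction_report,
        log=log,
    )
    if cfg.output_dir is not None:
        _write_bundle(result, Path(cfg.output_dir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    graph_io.write_spatial_graph(result.tree.graph, outdir / "corrected_graph.am")
    result.morphometry.to_csv(outdir / "morphometry.csv")
    result.order_table.to_csv(outdir / "order_table.csv")
    if result.compartment_table is not None:
        result.compartment_table.to_csv(outdir / "compartment_table.csv")
    result.murray.to_csv(outdir / "murray_table.csv", index=False)
    fit = result.scaling_fit
    bf = result.branching_fit
    summary = {
        "gamma": bf.gamma if bf else None,
        "n0": bf.n0 if bf else None,
        "gamma_fit_range": list(bf.fit_range) if bf else None,
        "scaling_exponent": fit.exponent if fit else None,
        "scaling_ci": list(fit.ci) if fit else None,
        "n_segments": result.tree.graph.n_segments,
        "n_orders": len(result.ordering.order_counts),
        "order_counts": result.ordering.order_counts,
        "total_length_um": result.tree.graph.total_length(),
        "correction_report": result.correction_report,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "run_log.json").write_text(json.dumps(result.log, indent=2, default=str))


def make_report(result: PipelineResult, path: str | Path) -> Path:
    """Render the standard figure panel from a pipeline result bundle.

    Missing sections (e.g. an empty Murray table) are noted on the panel
    rather than failing. Deterministic given the bundle.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))

    counts = result.ordering.order_counts
    ax = axes[0, 0]
    ax.bar(list(counts), list(counts.values()), color="steelblue")
    ax.set_xlabel("truncated Strahler order")
    ax.set_ylabel("number of segments")

    ax = axes[0, 1]
    bf = result.branching_fit
    if bf is not None:
        ax.semilogy(bf.orders_used, bf.counts_used, "o", label="observed")
        ax.semilogy(bf.orders_used, bf.predicted_counts(), "-", label=f"γ = {bf.gamma:.2f}")
        ax.set_xlabel("truncated Strahler order")
        ax.set_ylabel("N segments")
        ax.legend()
    else:
        ax.text(0.5, 0.5, "too few orders for a branching-ratio fit", ha="center", va="center")
        ax.set_axis_off()

    ax = axes[1, 0]
    if len(result.murray):
        x = result.murray["parent_radius_pow"]
        y = result.murray["sum_child_radius_pow"]
        ax.loglog(x, y, ".", alpha=0.5)
        lim = [min(x.min(), y.min()), max(x.max(), y.max())]
        ax.loglog(lim, lim, "--", color="orange", label="Murray's law")
        ax.legend()
        ax.set_xlabel("parent radius³ (µm³)")
        ax.set_ylabel("Σ child radii³ (µm³)")
    else:
        ax.text(0.5, 0.5, "no junctions: Murray table empty", ha="center", va="center")
        ax.set_axis_off()

    ax = axes[1, 1]
    fit = result.scaling_fit
    if fit is not None:
        ax.loglog(fit.pairs[:, 1], fit.pairs[:, 0], ".", alpha=0.4)
        nd = np.array([fit.pairs[:, 1].min(), fit.pairs[:, 1].max()], dtype=float)
        ax.loglog(nd, 10**fit.intercept * nd**fit.exponent, "-", color="purple",
                  label=f"a = {fit.exponent:.2f} [{fit.ci[0]:.2f}, {fit.ci[1]:.2f}]")
        ax.set_xlabel("downstream tips $N_d$")
        ax.set_ylabel("radius (µm)")
        ax.legend()
    else:
        ax.text(0.5, 0.5, "no radial-scaling fit (degenerate tip counts)",
                ha="center", va="center")
        ax.set_axis_off()

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
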