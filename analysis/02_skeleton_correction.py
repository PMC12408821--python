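"""Closed-loop collapse correction on a voxelized phantom.

Voxelizes a compact three-order tree, injects collapse artifacts into 15% of
segments (skeleton radii scaled to 0.2 of truth, mask left patent), then runs
flagging and perimeter-based radius correction and scores the recovery
against the planted ground truth.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import vasctree as vt

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    spec = vt.TreeSpec(
        n_orders=3, branching_ratio=2.0, root_radius=250.0, tortuosity_noise=30.0,
        length_to_diameter={1: 5.0, 2: 4.0, 3: 3.0}, points_per_segment=25, seed=11,
    )
    tree = vt.generate_rooted_tree(spec)
    phantom = vt.voxelize_tree(tree, voxel_size=10.0, margin=100.0)
    injected = vt.inject_collapse(phantom, fraction=0.15, severity=0.2, seed=12)

    work = vt.root_tree(injected.graph, 0)
    ordering = vt.assign_truncated_strahler(work)
    flags = vt.flag_collapsed(work, ordering)
    recovered = sorted(set(flags.flagged()) & set(injected.collapsed_segments))

    corrected, report = vt.correct_collapsed_radii(
        work, injected.mask,
        vt.CollapseFlags(flags={s: "confirmed" for s in injected.collapsed_segments}),
    )
    errors = []
    for sid in injected.collapsed_segments:
        truth = phantom.true_radii[sid]
        got = corrected.graph.segments[sid].radii
        errors.extend((np.abs(got - truth) / truth).tolist())

    out = {
        "n_segments": tree.graph.n_segments,
        "planted_collapsed": injected.collapsed_segments,
        "flag_recovered": recovered,
        "flag_recall": len(recovered) / len(injected.collapsed_segments),
        "correction_report": report,
        "median_abs_rel_radius_error": float(np.median(errors)),
    }
    (OUT / "02_collapse_recovery.json").write_text(json.dumps(out, indent=2))
    print(f"flagged {len(recovered)}/{len(injected.collapsed_segments)} planted collapses; "
          f"median |Δr|/r after correction = {out['median_abs_rel_radius_error']:.3f}")


if __name__ == "__main__":
    main()
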