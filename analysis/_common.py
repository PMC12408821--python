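"""Shared plumbing for the numbered analysis drivers."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import vasctree as vt  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"
NETWORK_PATH = RESULTS / "synthetic_network.am"


def load_or_generate_network() -> "vt.SpatialGraph":
    """The study-scale synthetic network (written by 01_simulate_network.py;
    regenerated deterministically here if the archive is absent)."""
    if NETWORK_PATH.exists():
        return vt.read_spatial_graph(NETWORK_PATH)
    RESULTS.mkdir(exist_ok=True)
    graph = vt.generate_tree(vt.TreeSpec(seed=1))
    vt.write_spatial_graph(graph, NETWORK_PATH)
    return graph
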