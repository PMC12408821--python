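import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import perfect_binary_tree  # noqa: E402

import vasctree as vt  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def binary_tree3():
    """7-segment perfect binary tree (3 levels) rooted at node 0."""
    graph, root = perfect_binary_tree(depth=3)
    return vt.root_tree(graph, root)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact 3-order tree voxelized at 10 µm for volume-based tests."""
    spec = vt.TreeSpec(
        n_orders=3,
        branching_ratio=2.0,
        root_radius=250.0,
        tortuosity_noise=30.0,
        length_to_diameter={1: 5.0, 2: 4.0, 3: 3.0},
        points_per_segment=25,
        seed=11,
    )
    tree = vt.generate_rooted_tree(spec)
    return vt.voxelize_tree(tree, voxel_size=10.0, margin=100.0)
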