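import numpy as np
import pytest
from helpers import ivd_oracle, random_tree, straight_segment, tortuosity_oracle

import vasctree as vt
from vasctree import BinaryVolume, LabelVolume, Node, Segment, SpatialGraph
from vasctree.morphometry import segment_midpoint


class TestTortuosity:
    def test_straight_segment_is_one(self):
        seg = straight_segment(0, 0, 1, [0, 0, 0], [100, 0, 0], 5.0, n_points=7)
        assert vt.tortuosity(seg) == pytest.approx(1.0)

    def test_semicircular_arc_is_half_pi(self):
        theta = np.linspace(0, np.pi, 721)
        pts = np.stack([50 * np.cos(theta), 50 * np.sin(theta), np.zeros_like(theta)], axis=1)
        seg = Segment(0, 0, 1, pts, np.full(len(theta), 5.0))
        assert vt.tortuosity(seg) == pytest.approx(np.pi / 2, rel=1e-4)

    def test_loopback_is_nan(self):
        pts = np.array([[0, 0, 0], [50, 0, 0], [0, 0, 0]], dtype=float)
        seg = Segment(0, 0, 0, pts, np.full(3, 5.0))
        assert np.isnan(vt.tortuosity(seg))

    def test_matches_oracle_on_random_polylines(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            pts = np.cumsum(rng.normal(scale=10, size=(n, 3)), axis=0)
            seg = Segment(0, 0, 1, pts, np.full(n, 5.0))
            assert vt.tortuosity(seg) == pytest.approx(tortuosity_oracle(seg))


def _y_tree(child_angles_deg, parent_dir=(0.0, 0.0, 1.0)):
    """Parent along +z from origin, children leaving the junction at the
    given polar angles from the parent axis (in the x–z plane)."""
    g = SpatialGraph()
    g.add_node(Node(0, np.zeros(3)))
    junction = np.array([0.0, 0.0, 100.0])
    g.add_node(Node(1, junction))
    g.add_segment(straight_segment(0, 0, 1, np.zeros(3), junction, 20.0))
    for i, ang in enumerate(child_angles_deg):
        a = np.radians(ang)
        d = np.array([np.sin(a), 0.0, np.cos(a)])
        end = junction + 80.0 * d
        g.add_node(Node(2 + i, end))
        g.add_segment(straight_segment(1 + i, 1, 2 + i, junction, end, 10.0))
    return vt.root_tree(g, 0)


class TestBranchingAngles:
    def test_collinear_continuation_is_180(self):
        tree = _y_tree([0.0])
        angles = vt.branching_angles(tree, "child_parent")
        assert angles[1] == pytest.approx(180.0)

    def test_orthogonal_child_is_90(self):
        tree = _y_tree([90.0])
        angles = vt.branching_angles(tree, "child_parent")
        assert angles[1] == pytest.approx(90.0)

    def test_symmetric_y_child_child_is_120(self):
        tree = _y_tree([60.0, -60.0])
        angles = vt.branching_angles(tree, "child_child")
        assert angles[0] == pytest.approx(120.0)

    def test_rigid_motion_invariance(self, rng):
        tree = random_tree(rng, 25)
        before_cp = vt.branching_angles(tree, "child_parent")
        before_t = {sid: vt.tortuosity(s) for sid, s in tree.graph.segments.items()}
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(scale=500, size=3)
        moved = tree.copy()
        for nid, node in list(moved.graph.nodes.items()):
            moved.graph.nodes[nid] = Node(nid, node.position @ q.T + shift)
        for seg in moved.graph.segments.values():
            seg.points = seg.points @ q.T + shift
        after_cp = vt.branching_angles(moved, "child_parent")
        for sid in before_cp:
            if np.isnan(before_cp[sid]):
                continue
            assert after_cp[sid] == pytest.approx(before_cp[sid], abs=1e-8)
        for sid in before_t:
            assert vt.tortuosity(moved.graph.segments[sid]) == pytest.approx(before_t[sid])


class TestSegmentVolume:
    def test_cylinder(self):
        seg = straight_segment(0, 0, 1, [0, 0, 0], [0, 0, 100], 10.0, n_points=5)
        assert vt.segment_volume(seg) == pytest.approx(np.pi * 100 * 100, rel=1e-12)

    def test_linear_taper_matches_frustum(self):
        n = 1001
        z = np.linspace(0, 100, n)
        radii = np.linspace(10, 20, n)
        seg = Segment(0, 0, 1, np.stack([np.zeros(n), np.zeros(n), z], axis=1), radii)
        exact = np.pi * 100 / 3 * (10**2 + 10 * 20 + 20**2)
        assert vt.segment_volume(seg) == pytest.approx(exact, rel=1e-3)

    def test_zero_radius_polyline(self):
        seg = Segment(
            0, 0, 1, np.stack([np.zeros(4), np.zeros(4), np.arange(4.0)], axis=1), np.zeros(4)
        )
        assert vt.segment_volume(seg) == 0.0


class TestMidpointIVD:
    def test_two_parallel_segments(self):
        g = SpatialGraph()
        for i, x in enumerate((0.0, 500.0)):
            g.add_node(Node(2 * i, np.array([x, 0.0, 0.0])))
            g.add_node(Node(2 * i + 1, np.array([x, 0.0, 200.0])))
            g.add_segment(
                straight_segment(i, 2 * i, 2 * i + 1, [x, 0, 0], [x, 0, 200], 5.0)
            )
        ivd = vt.ivd_midpoint(g)
        assert ivd[0] == pytest.approx(500.0)
        assert ivd[1] == pytest.approx(500.0)

    def test_three_collinear_segments(self):
        from helpers import chain_graph

        g, _ = chain_graph(3, seg_len=80.0)
        ivd = vt.ivd_midpoint(g)
        assert ivd[1] == pytest.approx(80.0)
        assert ivd[0] == pytest.approx(80.0)

    def test_single_segment_is_nan(self):
        g = SpatialGraph()
        g.add_node(Node(0, np.zeros(3)))
        g.add_node(Node(1, np.array([0.0, 0.0, 10.0])))
        g.add_segment(straight_segment(0, 0, 1, [0, 0, 0], [0, 0, 10], 1.0))
        assert np.isnan(vt.ivd_midpoint(g)[0])

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(30):
            tree = random_tree(rng, int(rng.integers(2, 40)))
            got = vt.ivd_midpoint(tree.graph)
            want = ivd_oracle(tree.graph)
            for sid in want:
                assert got[sid] == pytest.approx(want[sid])

    def test_midpoint_is_at_half_arc_length(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [10, 30, 0]], dtype=float)
        seg = Segment(0, 0, 1, pts, np.full(3, 1.0))
        np.testing.assert_allclose(segment_midpoint(seg), [10.0, 10.0, 0.0])


class TestVoxelIVD:
    def test_single_vessel_voxel_corner_distance(self):
        data = np.zeros((3, 3, 3), dtype=bool)
        data[1, 1, 1] = True
        dist, stats = vt.ivd_voxel(BinaryVolume(data=data, voxel_size=1.0))
        assert dist[0, 0, 0] == pytest.approx(np.sqrt(3.0))
        assert stats["all"]["max"] == pytest.approx(np.sqrt(3.0))

    def test_all_vessel_volume_is_zero_distance(self):
        data = np.ones((4, 4, 4), dtype=bool)
        dist, stats = vt.ivd_voxel(BinaryVolume(data=data, voxel_size=2.0))
        assert dist.max() == 0.0
        assert stats["all"]["n_voxels"] == 0

    def test_straight_tube_in_box_matches_analytic_geometry(self):
        """Max distance equals the corner-to-axis distance minus nothing
        (axis voxels only): corner of the box to the nearest tube voxel."""
        nx, ny, nz = 21, 21, 9
        data = np.zeros((nx, ny, nz), dtype=bool)
        data[10, 10, :] = True  # 1-voxel axis tube spanning z
        vox = 5.0
        dist, stats = vt.ivd_voxel(BinaryVolume(data=data, voxel_size=vox))
        expected_max = np.hypot(10 * vox, 10 * vox)
        assert stats["all"]["max"] == pytest.approx(expected_max)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            vt.ivd_voxel(BinaryVolume(data=np.zeros((3, 3, 3), dtype=bool), voxel_size=1.0))


def _shell_labels(extent=200.0, vox=5.0):
    n = int(extent / vox)
    data = np.zeros((n, n, n), dtype=np.int32)
    ii = np.arange(n) * vox
    xx, yy, zz = np.meshgrid(ii, ii, ii, indexing="ij")
    c = extent / 2
    r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2)
    data[r <= 90] = 1  # cortex analogue fills a ball
    data[r <= 40] = 2  # medulla core
    return LabelVolume(
        data=data, voxel_size=vox, legend={0: "background", 1: "cortex", 2: "medulla"}
    )


class TestCompartments:
    def test_segment_inside_single_compartment(self):
        labels = _shell_labels()
        g = SpatialGraph()
        g.add_node(Node(0, np.array([100.0, 100.0, 30.0])))
        g.add_node(Node(1, np.array([100.0, 100.0, 50.0])))
        g.add_segment(straight_segment(0, 0, 1, [100, 100, 30], [100, 100, 50], 3.0))
        tree = vt.root_tree(g, 0)
        out = vt.assign_compartments(tree, labels)
        assert out.graph.segments[0].compartment == "cortex"

    def test_boundary_crossing_segment_excluded(self):
        labels = _shell_labels()
        g = SpatialGraph()
        g.add_node(Node(0, np.array([100.0, 100.0, 30.0])))
        g.add_node(Node(1, np.array([100.0, 100.0, 100.0])))
        g.add_segment(
            straight_segment(0, 0, 1, [100, 100, 30], [100, 100, 100], 3.0, n_points=15)
        )
        tree = vt.root_tree(g, 0)
        out = vt.assign_compartments(tree, labels)
        assert out.graph.segments[0].compartment == "excluded"

    def test_exclusions_match_per_point_audit(self, rng):
        labels = _shell_labels()
        tree = random_tree(rng, 40)
        # rescale the random tree into the labelled box
        for seg in tree.graph.segments.values():
            seg.points = 100.0 + seg.points * 0.4
        for nid, node in list(tree.graph.nodes.items()):
            tree.graph.nodes[nid] = Node(nid, 100.0 + node.position * 0.4)
        out = vt.assign_compartments(tree, labels)
        for sid, seg in out.graph.segments.items():
            pts = tree.graph.segments[sid].points
            labs = set()
            for p in pts:
                idx = np.rint(p / labels.voxel_size).astype(int)
                if np.all(idx >= 0) and np.all(idx < np.array(labels.shape)):
                    labs.add(int(labels.data[tuple(idx)]))
            labs.discard(0)
            if len(labs) == 1:
                assert seg.compartment == labels.legend[labs.pop()]
            else:
                assert seg.compartment == "excluded"


class TestSummaries:
    def test_one_group_table_counts_everything(self, binary_tree3):
        ordering = vt.assign_truncated_strahler(binary_tree3)
        records = vt.compute_morphometry(binary_tree3, ordering)
        records["order"] = 1  # collapse to a single group
        table = vt.summarize(records, "order")
        assert table.loc[1, "n"] == binary_tree3.graph.n_segments

    def test_generated_tree_per_order_radii_match_generator(self):
        spec = vt.TreeSpec(n_orders=5, branching_ratio=2.0, seed=21, root_radius=1000.0)
        tree = vt.generate_rooted_tree(spec)
        ordering = vt.assign_truncated_strahler(tree)
        records = vt.compute_morphometry(tree, ordering)
        table = vt.summarize(records, "order")
        # exact construction: radius per order is deterministic for γ = 2
        for level in range(5):
            order = 5 - level
            expected = 1000.0 * 2 ** (-0.55 * level)
            assert table.loc[order, "mean_radius_um_mean"] == pytest.approx(expected, rel=1e-9)

    def test_compartment_percentages_sum_to_100(self, rng):
        labels = _shell_labels()
        tree = random_tree(rng, 30)
        for seg in tree.graph.segments.values():
            seg.points = 100.0 + seg.points * 0.4
        for nid, node in list(tree.graph.nodes.items()):
            tree.graph.nodes[nid] = Node(nid, 100.0 + node.position * 0.4)
        out = vt.assign_compartments(tree, labels)
        ordering = vt.assign_truncated_strahler(out)
        records = vt.compute_morphometry(out, ordering)
        table = vt.summarize(records, "compartment", labels)
        assert table["pct_segments"].sum() == pytest.approx(100.0)
        tissue = table["pct_tissue"].dropna()
        assert tissue.sum() == pytest.approx(100.0)

    def test_total_volume_conserved_across_compartments(self, rng):
        labels = _shell_labels()
        tree = random_tree(rng, 30)
        for seg in tree.graph.segments.values():
            seg.points = 100.0 + seg.points * 0.4
        for nid, node in list(tree.graph.nodes.items()):
            tree.graph.nodes[nid] = Node(nid, 100.0 + node.position * 0.4)
        out = vt.assign_compartments(tree, labels)
        records = vt.compute_morphometry(out, vt.assign_truncated_strahler(out))
        total = records["volume_um3"].sum()
        by_comp = records.groupby("compartment")["volume_um3"].sum().sum()
        assert by_comp == pytest.approx(total)
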