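import numpy as np
import pytest
from helpers import straight_segment

import vasctree as vt
from vasctree import BinaryVolume, Node, Segment, SmoothingConfig, SpatialGraph
from vasctree.morphometry import tortuosity
from vasctree.skeleton import _smooth_polyline


def zigzag_segment(n=21, amplitude=10.0, length=400.0):
    z = np.linspace(0, length, n)
    x = amplitude * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    x[0] = x[-1] = 0.0
    pts = np.stack([x, np.zeros(n), z], axis=1)
    return Segment(0, 0, 1, pts, np.full(n, 5.0))


def oracle_smooth(points, wn, wc, iters):
    """Literal step-by-step re-implementation of the weighted averaging."""
    pts = points.astype(float).copy()
    for _ in range(iters):
        new = pts.copy()
        for i in range(1, len(pts) - 1):
            new[i] = (wn / 2 * pts[i - 1] + wc * pts[i] + wn / 2 * pts[i + 1]) / (wn + wc)
        pts = new
    return pts


class TestSmoothing:
    def test_zigzag_tortuosity_strictly_decreases_each_iteration(self):
        seg = zigzag_segment()
        prev = tortuosity(seg)
        pts = seg.points
        for _ in range(5):
            pts = _smooth_polyline(pts, SmoothingConfig(iterations=1))
            cur = tortuosity(Segment(0, 0, 1, pts, seg.radii))
            assert cur < prev
            prev = cur

    def test_straight_segment_is_fixed_point(self):
        seg = straight_segment(0, 0, 1, [0, 0, 0], [0, 0, 500], 10.0, n_points=9)
        out = _smooth_polyline(seg.points, SmoothingConfig())
        np.testing.assert_allclose(out, seg.points, atol=1e-12)

    def test_matches_literal_loop_oracle(self):
        """Sinusoid-perturbed tube, default weights and 15 iterations:
        exact agreement with an independent step-by-step recomputation."""
        n = 31
        z = np.linspace(0, 600, n)
        x = 2.0 * np.sin(2 * np.pi * z / 150.0)
        pts = np.stack([x, np.zeros(n), z], axis=1)
        cfg = SmoothingConfig()
        out = _smooth_polyline(pts, cfg)
        expected = oracle_smooth(pts, cfg.w_neighbors, cfg.w_current, cfg.iterations)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert np.max(np.linalg.norm(out - pts, axis=1)) > 0

    def test_only_high_order_segments_smoothed_and_radii_kept(self, binary_tree3):
        ordering = vt.assign_truncated_strahler(binary_tree3)
        # make every polyline wiggly so smoothing would visibly act
        tree = binary_tree3.copy()
        for seg in tree.graph.segments.values():
            mid = seg.points.copy()
            if len(mid) > 2:
                mid[1:-1] += np.array([3.0, 0.0, 0.0])
            tree.graph.segments[seg.id] = Segment(
                seg.id, seg.start_node, seg.end_node, mid, seg.radii
            )
        out = vt.smooth_centerlines(tree, ordering, SmoothingConfig(order_threshold=3))
        for sid, seg in tree.graph.segments.items():
            res = out.graph.segments[sid]
            np.testing.assert_array_equal(res.radii, seg.radii)
            np.testing.assert_allclose(res.points[0], seg.points[0])
            np.testing.assert_allclose(res.points[-1], seg.points[-1])
            if ordering.order[sid] >= 3 and seg.n_points > 2:
                assert not np.allclose(res.points, seg.points)
            else:
                np.testing.assert_array_equal(res.points, seg.points)

    def test_smoothing_reduces_squared_chord_deviation(self):
        seg = zigzag_segment()
        chord = seg.points[-1] - seg.points[0]
        chord /= np.linalg.norm(chord)

        def sq_dev(pts):
            rel = pts - pts[0]
            perp = rel - np.outer(rel @ chord, chord)
            return float(np.sum(perp**2))

        pts = seg.points
        prev = sq_dev(pts)
        for _ in range(10):
            pts = _smooth_polyline(pts, SmoothingConfig(iterations=1))
            cur = sq_dev(pts)
            assert cur <= prev + 1e-12
            prev = cur


class TestFlagging:
    def test_every_large_order_segment_flagged(self, rng):
        spec = vt.TreeSpec(n_orders=6, branching_ratio=2.5, seed=1, root_radius=2900.0)
        tree = vt.generate_rooted_tree(spec)
        ordering = vt.assign_truncated_strahler(tree)
        flags = vt.flag_collapsed(tree, ordering)
        for sid, o in ordering.order.items():
            if o >= 5:
                assert flags.flags[sid] == "auto_large"

    def test_identical_radii_produce_no_percentile_flags(self, binary_tree3):
        ordering = vt.assign_truncated_strahler(binary_tree3)
        flags = vt.flag_collapsed(binary_tree3, ordering)
        assert not [f for f in flags.flags.values() if f == "percentile_outlier"]

    def test_planted_small_vessel_outliers_recovered(self):
        spec = vt.TreeSpec(n_orders=4, branching_ratio=3.0, seed=9, root_radius=1500.0)
        tree = vt.generate_rooted_tree(spec)
        ordering = vt.assign_truncated_strahler(tree)
        rng = np.random.default_rng(4)
        small = [sid for sid, o in ordering.order.items() if o < 4]
        planted = sorted(rng.choice(small, size=len(small) // 10, replace=False).tolist())
        for sid in planted:
            seg = tree.graph.segments[sid]
            seg.radii = seg.radii * 0.2
        flags = vt.flag_collapsed(tree, ordering)
        recovered = set(flags.flagged()) & set(planted)
        assert len(recovered) >= 0.9 * len(planted)

    def test_decisions_split_confirmed_and_cleared(self, binary_tree3):
        ordering = vt.assign_truncated_strahler(binary_tree3)
        flags = vt.CollapseFlags(flags={0: "auto_large", 1: "percentile_outlier"})
        updated = flags.apply_decisions({0: True, 1: False})
        assert updated.confirmed() == [0]
        assert updated.flags[1] == "cleared"


def tube_graph(radius, length=1000.0, n=21):
    g = SpatialGraph()
    g.add_node(Node(0, np.zeros(3)))
    g.add_node(Node(1, np.array([0.0, 0.0, length])))
    z = np.linspace(0, length, n)
    pts = np.stack([np.zeros(n), np.zeros(n), z], axis=1)
    g.add_segment(Segment(0, 0, 1, pts, np.full(n, float(radius))))
    return g


class TestCrossSection:
    def test_circular_tube_equivalent_radius(self):
        ph = vt.voxelize_tree(tube_graph(100.0), voxel_size=10.0, margin=50.0)
        cs = vt.extract_cross_section(
            ph.mask, np.array([0.0, 0.0, 500.0]), np.array([0.0, 0.0, 1.0]), half_width=250.0
        )
        assert abs(cs.equivalent_radius - 100.0) < 10.0  # within one voxel

    def test_square_prism_equivalent_radius(self):
        side = 40.0
        data = np.zeros((41, 41, 60), dtype=bool)
        data[10:30, 10:30, :] = True  # 20 voxels × 2 µm = 40 µm side
        vol = BinaryVolume(data=data, voxel_size=2.0)
        cs = vt.extract_cross_section(
            vol, np.array([39.0, 39.0, 60.0]), np.array([0.0, 0.0, 1.0]), half_width=60.0
        )
        assert cs.equivalent_radius == pytest.approx(2 * side / np.pi, abs=2.0)

    def test_elliptical_tube_perimeter_near_ramanujan(self):
        a, b = 60.0, 20.0
        data = np.zeros((130, 60, 40), dtype=bool)
        ii, jj = np.meshgrid(np.arange(130), np.arange(60), indexing="ij")
        x = (ii - 64.5) * 1.0
        y = (jj - 29.5) * 1.0
        inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        data[inside, :] = True
        vol = BinaryVolume(data=data, voxel_size=1.0)
        cs = vt.extract_cross_section(
            vol, np.array([64.5, 29.5, 20.0]), np.array([0.0, 0.0, 1.0]), half_width=90.0
        )
        h = ((a - b) / (a + b)) ** 2
        ramanujan = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert cs.perimeter == pytest.approx(ramanujan, rel=0.02)

    def test_background_centre_gives_empty_section(self):
        ph = vt.voxelize_tree(tube_graph(50.0), voxel_size=10.0, margin=100.0)
        cs = vt.extract_cross_section(
            ph.mask, np.array([90.0, 90.0, 500.0]), np.array([0.0, 0.0, 1.0]), half_width=30.0
        )
        assert cs.empty


class TestRadiusCorrection:
    def test_fully_collapsed_tube_restored(self):
        graph = tube_graph(80.0)
        ph = vt.voxelize_tree(graph, voxel_size=8.0, margin=60.0)
        collapsed = graph.copy()
        collapsed.segments[0].radii = np.full_like(collapsed.segments[0].radii, 0.5)
        tree = vt.root_tree(collapsed, 0)
        flags = vt.CollapseFlags(flags={0: "confirmed"})
        corrected, report = vt.correct_collapsed_radii(tree, ph.mask, flags)
        assert report[0] == "corrected"
        mean_r = corrected.graph.segments[0].radii.mean()
        assert abs(mean_r - 80.0) / 80.0 < 0.05

    def test_patent_tube_nearly_unchanged(self):
        graph = tube_graph(80.0)
        ph = vt.voxelize_tree(graph, voxel_size=8.0, margin=60.0)
        tree = vt.root_tree(graph.copy(), 0)
        corrected, _ = vt.correct_collapsed_radii(
            tree, ph.mask, vt.CollapseFlags(flags={0: "confirmed"})
        )
        mean_r = corrected.graph.segments[0].radii.mean()
        assert abs(mean_r - 80.0) / 80.0 < 0.02

    def test_aberrant_planes_windowed_out(self, monkeypatch):
        """Exactly the three planted aberrant plane radii are excluded by
        the 5th–95th windowing; the affected points inherit the nearest
        clean plane's radius."""
        import vasctree.skeleton as sk

        graph = tube_graph(60.0, n=61)
        aberrant = {10, 25, 40}
        calls = {"i": 0}

        def scripted_section(volume, point, tangent, half_width, spacing=None):
            i = calls["i"]
            calls["i"] += 1
            r = 150.0 if i in aberrant else 60.0
            raster = np.ones((3, 3), dtype=bool)
            return sk.CrossSection(
                raster=raster, spacing=1.0, centre_index=(1, 1),
                perimeter=2 * np.pi * r, area=np.pi * r**2,
            )

        monkeypatch.setattr(sk, "extract_cross_section", scripted_section)
        tree = vt.root_tree(graph.copy(), 0)
        dummy = BinaryVolume(data=np.ones((2, 2, 2), dtype=bool), voxel_size=10.0)
        corrected, report = sk.correct_collapsed_radii(
            tree, dummy, vt.CollapseFlags(flags={0: "confirmed"})
        )
        assert report[0] == "corrected"
        np.testing.assert_allclose(corrected.graph.segments[0].radii, 60.0)

    def test_no_valid_plane_reported_uncorrected(self):
        graph = tube_graph(40.0)
        empty = BinaryVolume(data=np.zeros((30, 30, 30), dtype=bool), voxel_size=50.0)
        tree = vt.root_tree(graph.copy(), 0)
        corrected, report = vt.correct_collapsed_radii(
            tree, empty, vt.CollapseFlags(flags={0: "confirmed"})
        )
        assert report[0] == "no_valid_plane"
        np.testing.assert_array_equal(
            corrected.graph.segments[0].radii, graph.segments[0].radii
        )

    def test_topology_preserved(self, small_phantom):
        inj = vt.inject_collapse(small_phantom, fraction=0.3, severity=0.2, seed=7)
        tree = vt.root_tree(inj.graph, 0)
        corrected, _ = vt.correct_collapsed_radii(
            tree, inj.mask,
            vt.CollapseFlags(flags={s: "confirmed" for s in inj.collapsed_segments}),
        )
        assert corrected.graph.n_nodes == tree.graph.n_nodes
        assert corrected.graph.n_segments == tree.graph.n_segments
        assert corrected.graph.n_points == tree.graph.n_points


class TestShortCollapseRepair:
    def test_single_pinch_restored(self):
        radii = np.full(20, 50.0)
        radii[7] = 5.0
        seg = Segment(0, 0, 1, np.stack([np.zeros(20), np.zeros(20), np.arange(20.0)], axis=1), radii)
        out = vt.repair_short_collapses(seg)
        assert out.radii[7] == pytest.approx(50.0)
        np.testing.assert_array_equal(out.points, seg.points)

    def test_constant_radius_unchanged(self):
        seg = Segment(
            0, 0, 1,
            np.stack([np.zeros(10), np.zeros(10), np.arange(10.0)], axis=1),
            np.full(10, 33.0),
        )
        out = vt.repair_short_collapses(seg)
        np.testing.assert_array_equal(out.radii, seg.radii)

    def test_monotone_taper_alters_at_most_boundary_point(self):
        n = 20
        radii = np.linspace(10.0, 20.0, n)
        seg = Segment(0, 0, 1, np.stack([np.zeros(n), np.zeros(n), np.arange(float(n))], axis=1), radii)
        out = vt.repair_short_collapses(seg)
        changed = np.flatnonzero(out.radii != seg.radii)
        assert len(changed) <= 1
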