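"""Geometric feature extraction: analytic cases, brute-force oracles and
rigid-motion invariance."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glomcluster.io_formats import GlomerularContext, NeuronMorphology, SwcNode
from glomcluster.morphometry import (
    compute_morpho_features,
    convex_hull_volume,
    count_glomeruli,
    dendritic_density,
    dendritic_length,
    furthest_sholl,
    hull2d_area,
    lateral_dendritic_volume,
    process_volume,
    soma_equivalent_diameter,
    soma_x_dendritic_volume,
    vertical_dendritic_volume,
)

from conftest import make_nodes


def chain(points, radii):
    pts = [(points[0][0], points[0][1], points[0][2], None)]
    pts += [(p[0], p[1], p[2], i) for i, p in enumerate(points[1:])]
    structures = ["soma"] + ["dendrite"] * (len(points) - 1)
    return NeuronMorphology(nodes=make_nodes(pts, radii=radii, structures=structures),
                            soma_area=50.0)


class TestVolumesAndLengths:
    def test_cylinder_volume(self):
        # soma -> node at distance 10, both radii 1: π r² L = 10π
        m = chain([(0, 0, 0), (10, 0, 0)], [1.0, 1.0])
        assert process_volume(m) == pytest.approx(10 * math.pi)

    def test_frustum_volume(self):
        # r 1 -> 2 over L=10: π L/3 (1 + 2 + 4) = 70π/3
        m = chain([(0, 0, 0), (5, 0, 0), (15, 0, 0)], [1.0, 1.0, 2.0])
        expected = math.pi * 5 + math.pi * 10 / 3 * (1 + 2 + 4)
        assert process_volume(m) == pytest.approx(expected)

    def test_length_straight_and_forked(self):
        m = chain([(0, 0, 0), (50, 0, 0), (100, 0, 0)], [1, 1, 1])
        assert dendritic_length(m) == pytest.approx(100)
        pts = [(0, 0, 0, None), (100, 0, 0, 0), (100, 30, 0, 1), (100, -30, 0, 1)]
        m2 = NeuronMorphology(nodes=make_nodes(pts), soma_area=10)
        assert dendritic_length(m2) == pytest.approx(160)

    def test_process_volume_matches_monte_carlo_union(self):
        """Frustum-sum volume vs rejection-sampling union oracle (<2%).

        The tree is a thin backbone with fat spokes spaced so segments
        barely overlap: the union the sampler sees then matches the
        frustum-sum the implementation computes.
        """
        rng = np.random.default_rng(3)
        pts = [(0.0, 0.0, 0.0, None)]
        radii = [0.1]
        for i in range(12):  # backbone along +x
            pts.append((6.0 * (i + 1), 0.0, 0.0, i))
            radii.append(0.1)
        for i in range(12):  # one fat spoke per backbone node
            tilt = 2.0 if i % 2 else -2.0
            pts.append((6.0 * (i + 1), 8.0, tilt, i + 1))
            radii.append(float(rng.uniform(0.9, 1.4)))
        structures = ["soma"] + ["dendrite"] * 24
        m = NeuronMorphology(nodes=make_nodes(pts, radii=radii, structures=structures),
                             soma_area=10)
        analytic = process_volume(m)

        by_id = {n.node_id: n for n in m.nodes}
        segs = []
        for n in m.nodes[1:]:
            p = by_id[n.parent_id]
            r0 = n.radius if p.structure == "soma" else p.radius
            segs.append((p.xyz, n.xyz, r0, n.radius))
        xyz = np.array([[n.x, n.y, n.z] for n in m.nodes])
        rmax = max(radii)
        lo, hi = xyz.min(axis=0) - rmax, xyz.max(axis=0) + rmax
        n_pts = 3_000_000
        sample = rng.uniform(lo, hi, size=(n_pts, 3))
        inside = np.zeros(n_pts, dtype=bool)
        for p0, p1, r0, r1 in segs:
            d = p1 - p0
            L2 = float(d @ d)
            t = (sample - p0) @ d / L2
            ok = (t >= 0.0) & (t <= 1.0)
            closest = p0 + t[:, None] * d
            dist = np.linalg.norm(sample - closest, axis=1)
            inside |= ok & (dist <= r0 + t * (r1 - r0))
        mc = inside.mean() * float(np.prod(hi - lo))
        assert analytic == pytest.approx(mc, rel=0.02)


class TestHulls:
    def test_unit_cube(self):
        pts = [(0, 0, 0, None)] + [((i >> 2) & 1, (i >> 1) & 1, i & 1, 0) for i in range(1, 8)]
        m = NeuronMorphology(nodes=make_nodes(pts), soma_area=1)
        assert convex_hull_volume(m) == pytest.approx(1.0)

    def test_regular_tetrahedron(self):
        a = [(0, 0, 0), (1, 0, 0), (0.5, math.sqrt(3) / 2, 0),
             (0.5, math.sqrt(3) / 6, math.sqrt(6) / 3)]
        pts = [(a[0][0], a[0][1], a[0][2], None)] + [(p[0], p[1], p[2], 0) for p in a[1:]]
        m = NeuronMorphology(nodes=make_nodes(pts), soma_area=1)
        assert convex_hull_volume(m) == pytest.approx(math.sqrt(2) / 12, rel=1e-6)

    def test_hull_matches_exhaustive_simplex_oracle(self):
        """Hull volume equals the max over unions of 4-point simplices...
        equivalently the sum of simplex volumes of a fan triangulation; the
        oracle sums tetrahedra from an interior point over hull facets found
        by brute force (every facet is a triangle all points lie on one side
        of)."""
        rng = np.random.default_rng(5)
        pts3 = rng.normal(size=(18, 3))
        nodes = [(pts3[0][0], pts3[0][1], pts3[0][2], None)] + \
                [(p[0], p[1], p[2], 0) for p in pts3[1:]]
        m = NeuronMorphology(nodes=make_nodes(nodes), soma_area=1)
        centroid = pts3.mean(axis=0)
        vol = 0.0
        n = len(pts3)
        import itertools
        for i, j, k in itertools.combinations(range(n), 3):
            a, b, c = pts3[i], pts3[j], pts3[k]
            normal = np.cross(b - a, c - a)
            if np.linalg.norm(normal) < 1e-12:
                continue
            side = np.sign((pts3 - a) @ normal)
            side[[i, j, k]] = 0
            if (side >= 0).all() or (side <= 0).all():
                vol += abs(np.dot(np.cross(b - a, c - a), centroid - a)) / 6.0
        assert convex_hull_volume(m) == pytest.approx(vol, rel=1e-9)

    def test_degenerate_sets_return_zero(self):
        m = chain([(0, 0, 0), (1, 0, 0), (2, 0, 0)], [1, 1, 1])
        with pytest.warns(UserWarning):
            assert convex_hull_volume(m) == 0.0
        assert hull2d_area(chain([(0, 0, 0), (1, 0, 0)], [1, 1])) == 0.0

    def test_hull2d_is_projected_area(self):
        pts = [(0, 0, 0, None), (10, 0, 5, 0), (0, 10, -3, 0), (10, 10, 7, 0)]
        m = NeuronMorphology(nodes=make_nodes(pts), soma_area=1)
        assert hull2d_area(m) == pytest.approx(100.0)


class TestSholl:
    def test_straight_dendrite(self, straight_dendrite):
        assert furthest_sholl(straight_dendrite) == pytest.approx(100)

    def test_curved_dendrite_uses_chord(self):
        # path length 150 but endpoint only 90 from the soma
        m = chain([(0, 0, 0), (45, 60, 0), (90, 0, 0)], [1, 1, 1])
        assert furthest_sholl(m) == pytest.approx(max(90, math.hypot(45, 60)))

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        pts = [(0.0, 0.0, 0.0, None)]
        for i in range(1, 40):
            pts.append(tuple(rng.normal(scale=30, size=3)) + (int(rng.integers(0, i)),))
        m = NeuronMorphology(nodes=make_nodes(pts), soma_area=1)
        brute = max(np.linalg.norm([n.x, n.y, n.z]) for n in m.nodes if n.structure == "dendrite")
        assert furthest_sholl(m) == pytest.approx(brute)


class TestLayerCriteria:
    def _epl_cell(self, tip, mid=None):
        """Soma in GL (z=+5), one EPL stem from (0,0,-1) to tip."""
        pts = [(0, 0, 5, None), (0, 0, -1, 0)]
        parent = 1
        if mid is not None:
            pts.append((mid[0], mid[1], mid[2], parent))
            parent = 2
        pts.append((tip[0], tip[1], tip[2], parent))
        radii = [2.0] + [1.0] * (len(pts) - 1)
        structures = ["soma"] + ["dendrite"] * (len(pts) - 1)
        return NeuronMorphology(nodes=make_nodes(pts, radii=radii, structures=structures),
                                soma_area=50)

    def test_parallel_chord_counts_as_lateral(self, flat_context):
        m = self._epl_cell((200, 0, -1))
        vol = lateral_dendritic_volume(m, flat_context)
        assert vol == pytest.approx(process_volume(m))

    def test_45_degree_chord_is_not_lateral(self, flat_context):
        m = self._epl_cell((100, 0, -101))
        assert lateral_dendritic_volume(m, flat_context) == 0.0

    def test_vertical_cone_full_inclusion(self, flat_context):
        m = self._epl_cell((0, 0, -80))
        assert vertical_dendritic_volume(m, flat_context) == pytest.approx(
            process_volume(m))

    def test_half_in_cone_fails_85pct_rule(self, flat_context):
        # elbow: straight down 40 μm (inside cone), then horizontal 60 μm
        # (far outside) — volume fraction in the cone < 85%
        m = self._epl_cell((60, 0, -41), mid=(0, 0, -41))
        assert vertical_dendritic_volume(m, flat_context) == 0.0

    def test_gl_side_stem_never_counts(self, flat_context):
        pts = [(0, 0, 5, None), (0, 0, 8, 0), (200, 0, 8, 1)]
        m = NeuronMorphology(nodes=make_nodes(pts), soma_area=10)
        assert lateral_dendritic_volume(m, flat_context) == 0.0
        assert vertical_dendritic_volume(m, flat_context) == 0.0


class TestGlomeruli:
    def test_tuft_inside_one_sphere(self, straight_dendrite):
        ctx = GlomerularContext(plane_point=np.zeros(3), plane_normal=[0, 0, 1],
                                glomeruli=[([50, 0, 0], 80.0, "g1")])
        assert count_glomeruli(straight_dendrite, ctx) == 1

    def test_crossing_three_disjoint_spheres(self, straight_dendrite):
        ctx = GlomerularContext(
            plane_point=np.zeros(3), plane_normal=[0, 0, 1],
            glomeruli=[([10, 0, 0], 5, "a"), ([50, 0, 0], 5, "b"), ([90, 0, 0], 5, "c"),
                       ([50, 200, 0], 5, "far")])
        assert count_glomeruli(straight_dendrite, ctx) == 3

    def test_no_glomeruli_gives_zero(self, straight_dendrite, flat_context):
        assert count_glomeruli(straight_dendrite, flat_context) == 0


class TestDerivedParameters:
    def test_density_is_volume_over_hull(self, flat_context):
        pts = [(0, 0, 0, None)] + [(p[0] * 20, p[1] * 20, p[2] * 20, 0)
                                   for p in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1),
                                             (1, 1, 0), (1, 0, 1), (0, 1, 1)]]
        m = NeuronMorphology(nodes=make_nodes(pts), soma_area=10)
        v, h = process_volume(m), convex_hull_volume(m)
        assert dendritic_density(m) == pytest.approx(v / h)

    def test_soma_product_uses_largest_stem(self):
        # two stems; the fatter one dominates
        pts = [(0, 0, 0, None), (10, 0, 0, 0), (-10, 0, 0, 0)]
        radii = [2.0, 2.0, 0.5]
        structures = ["soma", "dendrite", "dendrite"]
        m = NeuronMorphology(nodes=make_nodes(pts, radii=radii, structures=structures),
                             soma_area=50.0)
        big = math.pi * 4.0 * 10
        assert soma_x_dendritic_volume(m) == pytest.approx(50.0 * big)

    @pytest.mark.parametrize("area,expected", [
        (42.2, 6.4),       # smallest-cluster median
        (107.9, 10.3),     # largest-cluster median
        (1.3 * math.pi, 2.0),
    ])
    def test_soma_equivalent_diameter(self, area, expected):
        assert round(soma_equivalent_diameter(area), 1) == expected

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            soma_equivalent_diameter(0.0)


class TestAggregateAndInvariance:
    def test_rigid_motion_leaves_features_unchanged(self, flat_context):
        from glomcluster.synthetic_data import CohortSpec, generate_morphology
        rng = np.random.default_rng(2)
        m, ctx, _ = generate_morphology("G", CohortSpec(), rng)
        f0 = compute_morpho_features(m, ctx)
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        shift = np.array([100.0, -50.0, 30.0])
        nodes = [
            SwcNode(n.node_id, n.structure, *(R @ n.xyz + shift), n.radius, n.parent_id)
            for n in m.nodes
        ]
        m2 = NeuronMorphology(nodes=nodes, soma_area=m.soma_area)
        ctx2 = GlomerularContext(
            plane_point=R @ ctx.plane_point + shift,
            plane_normal=R @ ctx.plane_normal,
            glomeruli=[(R @ c + shift, r, lab) for c, r, lab in ctx.glomeruli],
            soma_area=ctx.soma_area,
        )
        f1 = compute_morpho_features(m2, ctx2)
        for k, v in f0.as_dict().items():
            if k == "hull2d_area":
                continue  # the slice-plane projection is frame-dependent
            assert f1.as_dict()[k] == pytest.approx(v, rel=1e-6, abs=1e-9), k

    def test_soma_only_cell_is_all_zero(self, flat_context):
        m = NeuronMorphology(nodes=make_nodes([(0, 0, 0, None)]), soma_area=30)
        with pytest.warns(UserWarning):
            f = compute_morpho_features(m, flat_context)
        assert f.process_volume == 0 and f.dendritic_length == 0
        assert f.convex_hull == 0 and f.n_glomeruli == 0
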