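import math

import numpy as np
import pytest

from phenocloud.core import PointCloud, SegmentedPlant
from phenocloud.morphometry import (DegenerateGeometryError, ExtractionConfig,
                                    branch_inclination, euclidean_height,
                                    extract_traits, fit_plane, leaf_area,
                                    leaf_inclination, locate_keypoints,
                                    plane_basis, plant_height, ring_diameter,
                                    ring_select, stem_diameters)


def shoelace_hull_area(points_2d):
    """Brute-force convex hull area oracle via shapely."""
    from shapely.geometry import MultiPoint
    return MultiPoint([tuple(p) for p in np.asarray(points_2d)]).convex_hull.area


class TestKeyPoints:
    def test_two_point_stem(self):
        cloud = PointCloud(points=[[0, 0, 0], [0, 0, 1]])
        plant = SegmentedPlant(cloud=cloud, stem=[0, 1])
        kp = locate_keypoints(plant)
        assert np.array_equal(kp.p1, [0, 0, 0])
        assert np.array_equal(kp.p3, [0, 0, 1])
        # both stem points are 0.5 from mid-z; the tie goes to the first
        assert np.array_equal(kp.p2, [0, 0, 0])
        assert kp.p4 == []

    def test_p1_is_global_lowest_even_on_a_leaf(self):
        """A leaf tip below the stem base becomes p1 (lowest point of the
        whole cloud, organ regardless)."""
        pts = [[0, 0, 0.1], [0, 0, 0.5], [0.1, 0, -0.05]]
        plant = SegmentedPlant(cloud=PointCloud(points=pts), stem=[0, 1], leaves=[[2]])
        kp = locate_keypoints(plant)
        assert np.array_equal(kp.p1, [0.1, 0, -0.05])

    def test_p4_matches_insertion_heights(self, tomato):
        plant, truth = tomato
        kp = locate_keypoints(plant)
        for j, p4 in enumerate(kp.p4):
            bh_est = euclidean_height(kp.p1, p4) * 100
            assert bh_est == pytest.approx(truth.record.bh[j], rel=0.03)


class TestHeights:
    @pytest.mark.parametrize("a, b, expected", [
        ((0, 0, 0), (0, 0, 0.10), 0.10),
        ((0.01, 0.02, 0.03), (0.04, 0.06, 0.03), 0.05),
    ])
    def test_known_distances(self, a, b, expected):
        assert euclidean_height(a, b) == pytest.approx(expected)

    def test_matches_brute_force_sum_of_squares(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 3))
            exp = math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
            assert euclidean_height(a, b) == pytest.approx(exp, abs=1e-12)

    def test_metric_properties(self, rng):
        pts = rng.normal(size=(12, 3))
        for a in pts[:4]:
            assert euclidean_height(a, a) == 0.0
            for b in pts[4:8]:
                assert euclidean_height(a, b) == euclidean_height(b, a) > 0
                for c in pts[8:]:
                    assert euclidean_height(a, c) <= (
                        euclidean_height(a, b) + euclidean_height(b, c) + 1e-12)

    def test_tilted_stem_straight_line_height(self):
        """A stem of axis length 0.45 m tilted 10 degrees still yields
        PH = 45 cm: the definition is the straight-line distance, not the
        vertical drop."""
        t = np.linspace(0, 0.45, 100)
        tilt = math.radians(10)
        axis = np.array([math.sin(tilt), 0, math.cos(tilt)])
        stem = np.outer(t, axis)
        plant = SegmentedPlant(cloud=PointCloud(points=stem), stem=np.arange(100))
        kp = locate_keypoints(plant)
        assert plant_height(kp) == pytest.approx(45.0, abs=1e-9)


class TestRingDiameter:
    def test_slab_selects_by_z_distance(self):
        pts = np.array([[0, 0, 0], [1, 1, 0.004], [2, 2, 0.02]])
        sel = ring_select(pts, centroid=(0, 0, 0), radius=0.005, geometry="slab")
        assert np.array_equal(sel.selected, [0, 1])

    def test_ball_mode_on_cylinder(self, bare_cylinder):
        plant, _ = bare_cylinder
        stem_pts = plant.cloud.points[plant.stem]
        mid = np.array([0, 0, 0.15])
        sel = ring_select(stem_pts, mid, radius=0.02, geometry="ball")
        assert sel.selected.size > 0

    def test_circle_of_known_radius(self):
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        r = 0.005
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)])
        sel = ring_select(pts, (0, 0, 0), radius=0.001)
        assert ring_diameter(sel, mode="range") == pytest.approx(10.0)
        assert ring_diameter(sel, mode="half_range") == pytest.approx(5.0)

    def test_collinear_points_give_zero_range_diameter(self):
        pts = np.array([[0, 0, 0], [0.002, 0, 0], [0.004, 0, 0]])
        sel = ring_select(pts, (0, 0, 0), radius=0.01)
        assert ring_diameter(sel, mode="range") == 0.0

    def test_insufficient_points_missing(self):
        pts = np.array([[0, 0, 0], [0.001, 0, 0]])
        sel = ring_select(pts, (0, 0, 0), radius=0.01)
        assert ring_diameter(sel) is None

    def test_noiseless_cylinder_within_2pct(self, bare_cylinder):
        plant, truth = bare_cylinder
        kp = locate_keypoints(plant)
        for d in stem_diameters(plant, kp, radius=0.005):
            assert d == pytest.approx(12.0, rel=0.02)

    def test_two_point_stem_all_missing(self):
        cloud = PointCloud(points=[[0, 0, 0], [0, 0, 0.3]])
        plant = SegmentedPlant(cloud=cloud, stem=[0, 1])
        kp = locate_keypoints(plant)
        assert stem_diameters(plant, kp) == (None, None, None)

    def test_ranges_match_brute_force(self, rng):
        pts = rng.normal(scale=0.01, size=(50, 3))
        sel = ring_select(pts, (0, 0, 0), radius=0.008)
        sub = pts[np.abs(pts[:, 2]) <= 0.008]
        assert sel.range_x == pytest.approx(sub[:, 0].max() - sub[:, 0].min())
        assert sel.range_y == pytest.approx(sub[:, 1].max() - sub[:, 1].min())


class TestPlaneFit:
    def test_horizontal_plane(self, rng):
        pts = np.column_stack([rng.normal(size=(50, 2)), np.full(50, 0.3)])
        fit = fit_plane(pts)
        assert np.allclose(fit.normal, [0, 0, 1])
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_vertical_plane_sign_convention(self, rng):
        pts = np.column_stack([np.zeros(50), rng.normal(size=(50, 2))])
        fit = fit_plane(pts)
        assert np.allclose(fit.normal, [1, 0, 0])  # z = 0 so positive-x rule

    def test_collinear_degenerate(self):
        pts = np.outer(np.arange(10), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            fit_plane(pts)

    def test_noisy_plane_normal_recovery(self, rng):
        """Gaussian noise of 1% of the patch size perturbs the recovered
        normal by less than a degree at n = 1000."""
        for _ in range(5):
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            u, v = plane_basis(normal)
            coords = rng.uniform(-0.5, 0.5, size=(1000, 2))
            pts = np.outer(coords[:, 0], u) + np.outer(coords[:, 1], v)
            pts += rng.normal(scale=0.01, size=(1000, 1)) * normal
            fit = fit_plane(pts)
            cosang = abs(float(fit.normal @ normal))
            assert math.degrees(math.acos(min(1.0, cosang))) < 1.0

    def test_residual_matches_direct_computation(self, rng):
        pts = rng.normal(size=(40, 3))
        fit = fit_plane(pts)
        d = (pts - fit.centroid) @ fit.normal
        assert fit.rms_residual == pytest.approx(math.sqrt((d ** 2).mean()))
        # eigen-decomposition of the covariance is an independent TLS route
        cov = np.cov((pts - fit.centroid).T, bias=True)
        w, v = np.linalg.eigh(cov)
        assert abs(float(v[:, 0] @ fit.normal)) == pytest.approx(1.0, abs=1e-9)


class TestInclinations:
    def test_horizontal_leaf_zero(self, rng):
        pts = np.column_stack([rng.normal(size=(30, 2)), np.zeros(30)])
        assert leaf_inclination(pts) == pytest.approx(0.0, abs=1e-9)

    def test_vertical_leaf_ninety(self, rng):
        pts = np.column_stack([np.zeros(30), rng.normal(size=(30, 2))])
        assert leaf_inclination(pts) == pytest.approx(90.0)

    @pytest.mark.parametrize("tilt", [10.0, 30.0, 60.0])
    def test_tilted_flat_leaf(self, rng, tilt):
        normal = np.array([math.sin(math.radians(tilt)), 0, math.cos(math.radians(tilt))])
        u, v = plane_basis(normal)
        coords = rng.uniform(-0.04, 0.04, size=(500, 2))
        pts = np.outer(coords[:, 0], u) + np.outer(coords[:, 1], v)
        pts += rng.normal(scale=0.0005, size=(500, 1)) * normal
        assert leaf_inclination(pts) == pytest.approx(tilt, abs=0.5)

    def test_li_invariant_to_normal_flip(self, rng):
        pts = rng.normal(size=(20, 3)) * [1, 1, 0.05]
        assert leaf_inclination(pts) == pytest.approx(leaf_inclination(pts[::-1]), abs=1e-6)
        assert 0.0 <= leaf_inclination(pts) <= 90.0

    def test_vertical_petiole_zero(self):
        z = np.linspace(0, 0.1, 50)
        pts = np.column_stack([0.001 * np.cos(z * 500), 0.001 * np.sin(z * 500), z])
        assert branch_inclination(pts) == pytest.approx(0.0, abs=2.0)

    def test_horizontal_petiole_ninety(self):
        x = np.linspace(0, 0.1, 50)
        pts = np.column_stack([x, 0.001 * np.sin(x * 500), 0.001 * np.cos(x * 500)])
        assert branch_inclination(pts, stem_centroid=(0, 0, 0)) == pytest.approx(90.0, abs=2.0)

    def test_forty_degree_petiole(self, bare_cylinder):
        t = np.linspace(0, 0.12, 400)
        a = math.radians(40.0)
        axis = np.array([math.sin(a), 0, math.cos(a)])
        rng = np.random.default_rng(5)
        theta = rng.uniform(0, 2 * np.pi, 400)
        e1 = np.array([math.cos(a), 0, -math.sin(a)])
        e2 = np.array([0, 1, 0])
        pts = (np.outer(t, axis) + 0.002 * (np.outer(np.cos(theta), e1)
                                            + np.outer(np.sin(theta), e2)))
        bi = branch_inclination(pts, stem_centroid=(0, 0, 0))
        assert bi == pytest.approx(40.0, abs=1.0)

    def test_reversed_branch_supplementary_without_orientation(self):
        """Without a stem anchor the axis is oriented upward, so a branch
        and its reversed copy agree; with anchors on opposite ends they are
        supplementary."""
        t = np.linspace(0, 0.1, 60)
        a = math.radians(40.0)
        axis = np.array([math.sin(a), 0, math.cos(a)])
        pts = np.outer(t, axis) + np.random.default_rng(0).normal(scale=1e-4, size=(60, 3))
        near = branch_inclination(pts, stem_centroid=pts[0])
        far = branch_inclination(pts, stem_centroid=pts[-1])
        assert near + far == pytest.approx(180.0, abs=0.5)

    def test_plane_mode_complement(self, rng):
        pts = rng.normal(size=(50, 3)) * [1, 1, 0.01]
        assert branch_inclination(pts, mode="plane") == pytest.approx(
            90.0 - leaf_inclination(pts))


class TestLeafArea:
    def test_rectangle(self):
        pts = np.array([[0, 0, 0.3], [0.10, 0, 0.3], [0, 0.05, 0.3], [0.10, 0.05, 0.3]])
        assert leaf_area(pts) == pytest.approx(50.0)

    def test_dense_flat_ellipse(self, rng):
        a, b = 0.04, 0.02
        n = int(200 * math.pi * 4 * 2)  # 200 pts/cm^2 over ~25 cm^2
        rho = np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([a * rho * np.cos(phi), b * rho * np.sin(phi), np.zeros(n)])
        assert leaf_area(pts) == pytest.approx(math.pi * a * b * 1e4, rel=0.02)

    def test_annulus_includes_void(self, rng):
        """A leaf sampled only on an annulus reports the full outer-hull
        area: interior voids are included."""
        n = 2000
        rho = rng.uniform(0.8, 1.0, n) * 0.03
        phi = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), np.zeros(n)])
        la = leaf_area(pts)
        hull_area = shoelace_hull_area(pts[:, :2]) * 1e4
        assert la == pytest.approx(hull_area, rel=1e-9)
        assert la == pytest.approx(math.pi * 9.0, rel=0.05)  # ~ outer disk, cm^2

    def test_hull_monotone_under_added_points(self, rng):
        pts = rng.normal(size=(30, 3)) * [0.02, 0.02, 0]
        base = leaf_area(pts)
        for _ in range(5):
            extra = rng.normal(size=(5, 3)) * [0.02, 0.02, 0]
            pts = np.vstack([pts, extra])
            grown = leaf_area(pts)
            assert grown >= base - 1e-12
            base = grown

    def test_degenerate_leaf_missing(self):
        assert leaf_area(np.outer(np.arange(5), [1.0, 0, 0])) is None


class TestExtractTraits:
    def test_zero_leaves_still_heights(self, bare_cylinder):
        plant, _ = bare_cylinder
        rec = extract_traits(plant)
        assert rec.ph is not None and rec.li == [] and rec.la == []
        assert rec.bd is not None

    def test_tiny_branch_missing_marked(self):
        stem = np.array([[0, 0, z] for z in np.linspace(0, 0.3, 1000)])
        stem = stem + np.random.default_rng(0).normal(scale=1e-3, size=stem.shape) * [1, 1, 0]
        branch = np.array([[0.01, 0, 0.1], [0.02, 0, 0.12]])
        cloud = PointCloud(points=np.vstack([stem, branch]))
        plant = SegmentedPlant(cloud=cloud, stem=np.arange(1000),
                               branches=[np.array([1000, 1001])])
        rec = extract_traits(plant)
        assert rec.bi == [None]
        assert rec.bh[0] is not None   # two points still have a lowest point
        assert rec.ph is not None
        assert rec.n_missing == 1

    def test_rigid_motion_covariance(self, tomato):
        plant, _ = tomato
        cfg = ExtractionConfig()
        base = extract_traits(plant, cfg)
        # translation changes nothing
        shifted = extract_traits(plant.transformed(translation=[1.0, -2.0, 0.5]), cfg)
        assert shifted.ph == pytest.approx(base.ph)
        assert shifted.la == pytest.approx(base.la)
        # z-rotation preserves all traits
        th = 1.1
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        rotated = extract_traits(plant.transformed(rotation=rot), cfg)
        assert rotated.ph == pytest.approx(base.ph)
        assert rotated.bh == pytest.approx(base.bh)
        assert rotated.li == pytest.approx(base.li, abs=1e-6)
        assert rotated.bi == pytest.approx(base.bi, abs=1e-6)
        assert rotated.la == pytest.approx(base.la, rel=1e-6)
        # uniform scale: lengths scale by c, areas by c^2, angles fixed
        # (the ring radius is a physical length, so it scales along)
        c = 2.5
        cfg_scaled = ExtractionConfig(ring_radius_m=cfg.ring_radius_m * c)
        scaled = extract_traits(plant.transformed(scale=c), cfg_scaled)
        assert scaled.ph == pytest.approx(base.ph * c)
        assert scaled.bd == pytest.approx(base.bd * c, rel=1e-6)
        assert scaled.la == pytest.approx([v * c * c for v in base.la], rel=1e-6)
        assert scaled.li == pytest.approx(base.li, abs=1e-6)

    def test_small_plant_hand_values(self, small_plant):
        rec = extract_traits(small_plant)
        assert rec.ph == pytest.approx(50.0)
        assert rec.li[0] == pytest.approx(0.0, abs=1e-9)
        assert rec.la[0] == pytest.approx(50.0)
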