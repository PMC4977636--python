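"""Mesh/plane intersection, Hausdorff, Dice/Jaccard, validation reports."""

import math

import numpy as np
import pytest
import trimesh

from cinealign.errors import PlaneMismatchError
from cinealign.geometry import ImagePlane, SA
from cinealign.mesh import SurfaceMesh
from cinealign.validation import (INF, PlanarRegion, ValidationReport, ViewScores,
                                  dice, hausdorff, intersect_mesh_plane, jaccard,
                                  validate)

XY = ImagePlane((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1))


def square(side=1.0, offset=(0.0, 0.0)):
    s = side
    ox, oy = offset
    return np.array([[ox, oy], [ox + s, oy], [ox + s, oy + s], [ox, oy + s]])


def region(*polys):
    return PlanarRegion(XY, list(polys))


class TestIntersectMeshPlane:
    def test_icosphere_great_circle(self):
        tm = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        surf = SurfaceMesh.from_trimesh(tm)
        reg = intersect_mesh_plane(surf, XY)
        assert len(reg.boundary) == 1
        radii = np.linalg.norm(reg.boundary[0], axis=1)
        assert np.all(np.abs(radii - 1.0) < 0.05)

    def test_plane_misses_surface(self):
        tm = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        plane = ImagePlane((0, 0, 5.0), (1, 0, 0), (0, 1, 0), (1, 1))
        reg = intersect_mesh_plane(SurfaceMesh.from_trimesh(tm), plane)
        assert reg.is_empty

    def test_tangent_plane_near_degenerate(self):
        tm = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        plane = ImagePlane((0, 0, 1.0), (1, 0, 0), (0, 1, 0), (1, 1))
        reg = intersect_mesh_plane(SurfaceMesh.from_trimesh(tm), plane)
        assert reg.is_empty or reg.area() < 1e-3


class TestHausdorff:
    def test_identical_curves(self):
        pts = square(3.0)
        assert hausdorff(pts, pts) == 0.0

    def test_brute_force_example(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        Y = np.array([[0.0, 0.0], [4.0, 0.0]])
        assert abs(hausdorff(X, Y) - 3.0) < 1e-9

    def test_empty_rules(self):
        assert math.isinf(hausdorff(np.zeros((0, 2)), square()))
        assert hausdorff(np.zeros((0, 2)), np.zeros((0, 2))) == 0.0

    def test_metric_properties_on_random_polylines(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.uniform(-5, 5, size=(6, 2))
            b = rng.uniform(-5, 5, size=(7, 2))
            c = rng.uniform(-5, 5, size=(5, 2))
            hab, hba = hausdorff(a, b), hausdorff(b, a)
            assert abs(hab - hba) < 1e-9
            assert hab >= 0
            assert hab <= hausdorff(a, c) + hausdorff(c, b) + 1e-9


class TestOverlap:
    def test_identical_regions(self):
        r = region(square(3.0))
        assert abs(dice(r, r) - 1.0) < 1e-12
        assert abs(jaccard(r, r) - 1.0) < 1e-12

    def test_half_overlapping_unit_squares(self):
        a = region(square(1.0))
        b = region(square(1.0, offset=(0.5, 0.0)))
        assert abs(dice(a, b) - 0.5) < 1e-12
        assert abs(jaccard(a, b) - 1.0 / 3.0) < 1e-12

    def test_plane_mismatch(self):
        other = ImagePlane((0, 0, 5), (1, 0, 0), (0, 1, 0), (1, 1))
        with pytest.raises(PlaneMismatchError):
            dice(region(square()), PlanarRegion(other, [square()]))

    def test_jaccard_dice_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = region(square(rng.uniform(1, 3)))
            b = region(square(rng.uniform(1, 3), offset=rng.uniform(-1, 1, 2)))
            d, j = dice(a, b), jaccard(a, b)
            if d > 0:
                assert abs(j - d / (2.0 - d)) < 1e-12
        # the identity ties the published pair D=0.89, J=0.80 together
        assert round(0.89 / (2.0 - 0.89), 2) == 0.80

    def test_invariance_under_in_plane_rigid_motion(self):
        rng = np.random.default_rng(1)
        a = square(2.0)
        b = square(2.0, offset=(0.7, -0.4))
        th = 0.83
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        t = np.array([3.1, -1.2])
        d0 = dice(region(a), region(b))
        d1 = dice(region(a @ R.T + t), region(b @ R.T + t))
        assert abs(d0 - d1) < 1e-9

    def test_monotone_under_nested_growth(self):
        from shapely.geometry import Polygon

        target = square(4.0)
        prev_d, prev_j = 0.0, 0.0
        for shrink in (1.5, 1.0, 0.5, 0.0):
            tr = Polygon(target).buffer(-shrink, join_style=2)
            tr_pts = np.array(tr.exterior.coords[:-1])
            d = dice(region(target), region(tr_pts))
            j = jaccard(region(target), region(tr_pts))
            assert d >= prev_d and j >= prev_j
            prev_d, prev_j = d, j
        assert abs(prev_d - 1.0) < 1e-9


class TestViewScoresAndReport:
    def test_score_invariants(self):
        with pytest.raises(ValueError):
            ViewScores(INF, 0.5, 0.4)
        with pytest.raises(ValueError):
            ViewScores(3.0, 0.5, 0.6)

    def test_report_means_match_hand_computation(self):
        rep = ValidationReport({"2CH": ViewScores(2.0, 0.9, 0.9 / 1.1),
                                "3CH": ViewScores(4.0, 0.8, 0.8 / 1.2),
                                "4CH": ViewScores(6.0, 0.7, 0.7 / 1.3)})
        assert abs(rep.mean_hausdorff - 4.0) < 1e-12
        assert abs(rep.mean_dice - 0.8) < 1e-12

    def test_infinite_view_dominates_mean(self):
        rep = ValidationReport({"2CH": ViewScores(INF, 0.0, 0.0),
                                "3CH": ViewScores(4.0, 0.8, 0.8 / 1.2),
                                "4CH": ViewScores(6.0, 0.7, 0.7 / 1.3)})
        assert math.isinf(rep.mean_hausdorff)
        rows = rep.rows()
        assert rows[0][1] == "inf"
        assert rows[-1][1] == "inf"


class TestValidate:
    def test_phantom_self_consistency(self, phantom, truth_reconstruction):
        _, records = phantom
        lax = [r for r in records if r.view != SA]
        rep = validate(truth_reconstruction, lax)
        for view, score in rep.per_view.items():
            assert score is not None
            assert score.dice >= 0.9

    def test_surface_missing_a_plane_scores_degenerate(self, phantom):
        _, records = phantom
        lax = [r for r in records if r.view != SA]
        # a small sphere on the 2CH plane (azimuth 0) but far from the others
        tm = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        tm.apply_translation([200.0, 0.0, 0.0])
        rep = validate(SurfaceMesh.from_trimesh(tm), lax)
        assert math.isinf(rep.per_view["3CH"].hausdorff)
        assert rep.per_view["3CH"].dice == 0.0
        assert rep.per_view["3CH"].jaccard == 0.0
        assert math.isinf(rep.mean_hausdorff)

    def test_missing_view_reported_absent(self, phantom, truth_reconstruction):
        _, records = phantom
        lax = [r for r in records if r.view == "2CH"]
        rep = validate(truth_reconstruction, lax)
        assert rep.per_view["3CH"] is None
        assert rep.per_view["4CH"] is None
        assert rep.per_view["2CH"] is not None
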