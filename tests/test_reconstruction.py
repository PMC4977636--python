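"""Interpolation, Delaunay meshing, graph-cut surface extraction, post-processing."""

import math

import numpy as np
import pytest

from cinealign.errors import (DegenerateCloudError, OpenContourError, SeedError)
from cinealign.geometry import Contour2D, ImagePlane, SliceRecord
from cinealign.mesh import SurfaceMesh
from cinealign.reconstruction import (INTER, ORIGINAL, CutGraph,
                                      build_cut_graph,
                                      build_tet_mesh, cut_energy, distance_field,
                                      interpolate_contours, min_cut_surface,
                                      postprocess, reconstruct)
from tests.conftest import enumerate_min_cut

RNG = np.random.default_rng(11)


def circle_record(z, radius, n=60, index=1, phase=0.0):
    t = phase + 2 * np.pi * np.arange(n) / n
    pts = np.stack([radius * np.cos(t), radius * np.sin(t)], axis=1)
    plane = ImagePlane((0, 0, z), (1, 0, 0), (0, 1, 0), (1, 1))
    return SliceRecord("SA", index, plane, (Contour2D(pts, "LV"),))


class TestInterpolation:
    def test_linear_blend_of_matched_circles(self):
        recs = [circle_record(0.0, 20.0, index=1), circle_record(8.0, 20.0, index=2)]
        cloud = interpolate_contours(recs, intra_step=1.0, n_inter_layers=1,
                                     include_lax=False)
        inter = cloud.points.points[cloud.provenance == INTER]
        assert len(inter) > 0
        np.testing.assert_allclose(inter[:, 2], 4.0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(inter[:, :2], axis=1), 20.0,
                                   atol=1e-6)

    def test_original_points_kept_and_floor_rule(self):
        recs = [circle_record(0.0, 20.0, index=1, n=12)]
        # step far larger than the perimeter: no densification at all
        cloud = interpolate_contours(recs, intra_step=1e6, n_inter_layers=0,
                                     include_lax=False)
        assert len(cloud.points) == 12
        assert np.all(cloud.provenance == ORIGINAL)

    def test_zero_inter_layers(self):
        recs = [circle_record(0.0, 20.0, index=1), circle_record(8.0, 18.0, index=2)]
        cloud = interpolate_contours(recs, n_inter_layers=0, include_lax=False)
        assert not np.any(cloud.provenance == INTER)

    def test_open_lv_contour_rejected(self):
        pts = np.stack([np.linspace(0, 10, 8), np.zeros(8)], axis=1)
        plane = ImagePlane((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1))
        rec = SliceRecord("SA", 1, plane, (Contour2D(pts, "LV", closed=False),))
        with pytest.raises(OpenContourError):
            interpolate_contours([rec])

    def test_inputs_contained_unchanged(self, phantom):
        _, records = phantom
        cloud = interpolate_contours(records)
        originals = cloud.points.points[cloud.provenance == ORIGINAL]
        expected = np.vstack([r.plane.to_patient(c.points)
                              for r in records for c in r.contours
                              if c.label == "LV"])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(originals).query(expected)
        assert d.max() < 1e-9


class TestTetMesh:
    def test_cube_volume_conserved(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                           dtype=float)
        mesh = build_tet_mesh(corners, grid_step=100.0, margin=0.0)
        assert np.all(mesh.volumes() > 0)
        np.testing.assert_allclose(mesh.volumes().sum(), 1.0, atol=1e-9)

    def test_hull_volume_matches(self):
        pts = RNG.normal(scale=10, size=(60, 3))
        mesh = build_tet_mesh(pts, grid_step=4.0, margin=5.0)
        from scipy.spatial import ConvexHull

        hull = ConvexHull(mesh.vertices)
        np.testing.assert_allclose(mesh.volumes().sum(), hull.volume, rtol=1e-6)

    def test_cloud_points_are_vertices_and_aux_flagged(self, phantom):
        _, records = phantom
        cloud = interpolate_contours(records)
        mesh = build_tet_mesh(cloud, grid_step=4.0, margin=10.0)
        n_cloud = len(cloud.points)
        np.testing.assert_allclose(mesh.vertices[:n_cloud], cloud.points.points)
        assert not mesh.aux_flags[:n_cloud].any()
        assert mesh.aux_flags[n_cloud:].all()

    def test_coplanar_rejected(self):
        pts = np.zeros((20, 3))
        pts[:, :2] = RNG.normal(size=(20, 2))
        with pytest.raises(DegenerateCloudError):
            build_tet_mesh(pts, grid_step=1e9, margin=0.0)


class TestDistanceField:
    def test_exact_values(self):
        cloud = np.array([[0.0, 0.0, 0.0]])
        np.testing.assert_allclose(distance_field([[3, 4, 0]], cloud), [5.0])
        np.testing.assert_allclose(distance_field(cloud, cloud), [0.0])

    def test_matches_brute_force(self):
        cloud = RNG.normal(scale=20, size=(500, 3))
        q = RNG.normal(scale=25, size=(1000, 3))
        brute = np.sqrt(((q[:, None, :] - cloud[None, :, :]) ** 2).sum(-1)).min(1)
        np.testing.assert_allclose(distance_field(q, cloud), brute, atol=1e-12)


class TestGraphCut:
    def test_capacities_nonnegative_and_seed_errors(self, phantom):
        _, records = phantom
        cloud = interpolate_contours(records)
        mesh = build_tet_mesh(cloud)
        seed = cloud.points.points.mean(axis=0)
        graph = build_cut_graph(mesh, cloud, seed)
        assert np.all(graph.capacities >= 0)
        with pytest.raises(SeedError):
            build_cut_graph(mesh, cloud, (1e6, 0.0, 0.0))

    def test_min_cut_equals_enumeration_on_random_instances(self):
        """Max-flow solver vs exhaustive enumeration on 50 tiny random meshes."""
        from cinealign.reconstruction import _solve_min_cut

        rng = np.random.default_rng(123)
        tested = 0
        attempts = 0
        while tested < 50 and attempts < 500:
            attempts += 1
            n_pts = rng.integers(6, 9)
            mesh = build_tet_mesh(rng.normal(scale=10, size=(n_pts, 3)),
                                  grid_step=1e9, margin=0.0)
            m = len(mesh.tetrahedra)
            if m < 4 or m > 8:
                continue
            tested += 1
            tri = mesh._delaunay
            ti, k = np.nonzero(tri.neighbors >= 0)
            tj = tri.neighbors[ti, k]
            keep = ti < tj
            arcs = np.stack([ti[keep], tj[keep]], axis=1)
            caps = rng.uniform(0.1, 5.0, size=len(arcs))
            source = np.array([rng.integers(0, m)])
            others = [t for t in range(m) if t != source[0]]
            sinks = np.array(rng.choice(others, size=max(1, len(others) // 3),
                                        replace=False))
            graph = CutGraph(n_tets=m, arcs=arcs,
                             faces=np.zeros((len(arcs), 3), dtype=np.int64),
                             capacities=caps, source_tets=source, sink_tets=sinks)
            labels = _solve_min_cut(graph)
            cut_value = caps[labels[arcs[:, 0]] != labels[arcs[:, 1]]].sum()
            best = enumerate_min_cut(m, arcs, caps, source, sinks)
            assert abs(cut_value - best) < 1e-6 * max(best, 1.0)
            # the complementary (any other) cut cannot be cheaper
            assert cut_value <= best + 1e-6
        assert tested == 50

    def test_constant_distance_gives_minimal_area_cut(self):
        """With d ~ constant the cut approximates the minimal separating area."""
        grid = np.stack(np.meshgrid(*[np.linspace(-20, 20, 11)] * 3,
                                    indexing="ij"), -1).reshape(-1, 3)
        mesh = build_tet_mesh(grid, grid_step=1e9, margin=0.0)
        far = np.array([[1e4, 0.0, 0.0]])
        graph = build_cut_graph(mesh, far, (0.0, 0.0, 0.0), exterior_band=2.0)
        surf = min_cut_surface(graph, mesh)
        # with a constant weight the optimum is the minimal-area surface
        # separating the seeds: it wraps the source region tightly, so its
        # area approximates the source region's convex-hull area
        src_verts = mesh.vertices[mesh.tetrahedra[graph.source_tets]].reshape(-1, 3)
        hull_area = _convex_hull_area(src_verts)
        assert 0.8 * hull_area <= surf.area() <= 1.3 * hull_area

    def test_sphere_cloud_reconstruction(self):
        """Dense sphere samples reconstruct a sphere of the right size."""
        n = 4000
        u = RNG.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cloud = 20.0 * u
        mesh = build_tet_mesh(cloud, grid_step=4.0, margin=10.0)
        graph = build_cut_graph(mesh, cloud, (0.0, 0.0, 0.0))
        surf = min_cut_surface(graph, mesh)
        assert surf.is_closed()
        radii = np.linalg.norm(surf.vertices, axis=1)
        assert np.all(np.abs(radii - 20.0) <= 2 * 4.0)
        vol = 4.0 / 3.0 * math.pi * 20.0 ** 3
        assert abs(surf.volume() - vol) / vol < 0.15
        # cut cost equals the surface's discrete energy recomputed from geometry
        fv = surf.vertices[surf.triangles]
        areas = 0.5 * np.linalg.norm(np.cross(fv[:, 1] - fv[:, 0],
                                              fv[:, 2] - fv[:, 0]), axis=1)
        energy = float((areas * distance_field(fv.mean(axis=1), cloud)).sum())
        assert abs(cut_energy(graph, surf) - energy) < 1e-9 * max(energy, 1.0)


def _convex_hull_area(points):
    from scipy.spatial import ConvexHull

    return float(ConvexHull(points).area)


class TestPostprocess:
    def _noisy_sphere(self):
        import trimesh

        tm = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
        v = np.asarray(tm.vertices)
        rng = np.random.default_rng(5)
        v = v + rng.normal(scale=0.4, size=v.shape)
        return SurfaceMesh(v, np.asarray(tm.faces))

    def test_identity_when_disabled(self):
        s = self._noisy_sphere()
        out = postprocess(s, smoothing_iterations=0, target_edge=None)
        np.testing.assert_array_equal(out.vertices, s.vertices)
        np.testing.assert_array_equal(out.triangles, s.triangles)

    def test_smoothing_reduces_radius_variance(self):
        s = self._noisy_sphere()
        out = postprocess(s, smoothing_iterations=10, target_edge=None)
        r_in = np.linalg.norm(s.vertices, axis=1)
        r_out = np.linalg.norm(out.vertices, axis=1)
        assert abs(r_out.mean() - r_in.mean()) / r_in.mean() < 0.02
        assert r_out.var() < r_in.var()

    def test_open_surface_rejected(self):
        s = self._noisy_sphere()
        open_surface = SurfaceMesh(s.vertices, s.triangles[:-10])
        with pytest.raises(Exception):
            postprocess(open_surface)


class TestReconstruct:
    def test_truth_contours_give_accurate_surface(self, phantom,
                                                  truth_reconstruction):
        from cinealign.pipeline import mean_surface_distance

        truth_mesh, _ = phantom
        surf = truth_reconstruction
        assert surf.is_closed()
        assert surf.volume() > 0
        assert mean_surface_distance(surf, truth_mesh) < 2.0

    def test_postprocess_volume_stability_on_phantom(self, phantom):
        """Smoothing/re-meshing changes the enclosed volume by < 5 %."""
        _, records = phantom
        from cinealign.reconstruction import (build_cut_graph, build_tet_mesh,
                                              interpolate_contours,
                                              min_cut_surface)

        cloud = interpolate_contours(records)
        mesh = build_tet_mesh(cloud)
        lv = cloud.points.select(label="LV")
        graph = build_cut_graph(mesh, cloud, lv.points.mean(axis=0))
        raw = min_cut_surface(graph, mesh)
        post = postprocess(raw)
        assert abs(post.volume() - raw.volume()) / raw.volume() < 0.05

    def test_realigned_beats_unrealigned_in_most_runs(self, study):
        rows, _ = study
        wins = [r["surface_distance_after"] <= r["surface_distance_before"]
                for r in rows]
        assert np.mean(wins) >= 0.9
        # and strictly on average
        assert (np.mean([r["surface_distance_after"] for r in rows])
                < np.mean([r["surface_distance_before"] for r in rows]))

    def test_empty_sa_set_rejected(self, phantom):
        _, records = phantom
        with pytest.raises(ValueError):
            reconstruct([r for r in records if r.view != "SA"])
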