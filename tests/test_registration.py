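"""Generalized ICP and the iterative slice realignment."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from cinealign.errors import InsufficientPointsError, RegistrationFailedError
from cinealign.geometry import PointCloud3D, RigidTransform, project_record
from cinealign.phantom import PerturbationSpec, perturb
from cinealign.pipeline import rms_to_truth
from cinealign.registration import (GicpParams, estimate_point_covariances,
                                    gicp, realign)

RNG = np.random.default_rng(7)


def cloud_of(points, label="LV"):
    pts = np.asarray(points, float)
    return PointCloud3D(pts, [("SA", 1, label)] * len(pts))


def classic_icp(src, tgt, iterations=100, tol=1e-10):
    """Reference point-to-point ICP: nearest neighbors + Kabsch per iteration."""
    from cinealign.geometry import best_fit_rigid

    T = RigidTransform.identity()
    tree = cKDTree(tgt)
    for _ in range(iterations):
        cur = T.apply(src)
        _, j = tree.query(cur)
        T_new = best_fit_rigid(src, tgt[j])
        if np.abs(T_new.matrix() - T.matrix()).max() < tol:
            return T_new
        T = T_new
    return T


class TestPointCovariances:
    def test_collinear_points_give_line_covariance(self):
        pts = np.stack([np.linspace(0, 30, 40), np.zeros(40), np.zeros(40)], axis=1)
        eps = 0.01
        cov = estimate_point_covariances(cloud_of(pts),
                                         GicpParams(covariance_epsilon=eps))
        w, v = np.linalg.eigh(cov)
        # dominant eigenvector along x, eigenvalue ratio 1/eps
        dominant = np.abs(v[:, :, 2])
        np.testing.assert_allclose(dominant[:, 0], 1.0, atol=1e-9)
        np.testing.assert_allclose(w[:, 2] / w[:, 0], 1.0 / eps, rtol=1e-9)

    def test_epsilon_one_reduces_to_identity(self):
        pts = RNG.normal(size=(30, 3))
        cov = estimate_point_covariances(cloud_of(pts),
                                         GicpParams(covariance_epsilon=1.0))
        np.testing.assert_allclose(cov, np.broadcast_to(np.eye(3), (30, 3, 3)),
                                   atol=1e-12)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            estimate_point_covariances(cloud_of(RNG.normal(size=(3, 3))),
                                       GicpParams(k_neighbors=8))


class TestGicp:
    def test_identical_clouds_fixed_point(self, phantom):
        _, records = phantom
        cloud = project_record(next(r for r in records if r.key == ("SA", 7)))
        T = gicp(cloud, cloud)
        assert np.abs(T.matrix() - np.eye(4)).max() < 1e-6

    def test_recovers_known_transform(self, phantom):
        # slice with two structures (atrium + aorta): no rotational symmetry
        _, records = phantom
        cloud = project_record(next(r for r in records if r.key == ("SA", 3)))
        T_true = RigidTransform.from_rotvec([0, 0, np.deg2rad(5.0)], (3.0, -2.0, 1.0))
        target = PointCloud3D(T_true.apply(cloud.points), list(cloud.source))
        T = gicp(cloud, target)
        assert np.linalg.norm(T.translation - T_true.translation) < 0.05
        rel = Rotation.from_matrix(T.rotation @ T_true.rotation.T)
        assert np.degrees(np.linalg.norm(rel.as_rotvec())) < 0.05

    def test_distant_clouds_fail_gate(self):
        a = cloud_of(RNG.normal(size=(30, 3)))
        b = cloud_of(RNG.normal(size=(30, 3)) + np.array([100.0, 0, 0]))
        with pytest.raises(RegistrationFailedError):
            gicp(a, b, params=GicpParams(max_correspondence_distance=20.0))

    def test_epsilon_one_matches_classic_icp(self, phantom):
        """With isotropic covariances the estimator coincides with classic ICP."""
        _, records = phantom
        cloud = project_record(next(r for r in records if r.key == ("SA", 3)))
        T_true = RigidTransform.from_rotvec([0.01, -0.02, 0.04], (2.0, 1.0, -1.5))
        target = T_true.apply(cloud.points)
        params = GicpParams(covariance_epsilon=1.0, inner_tolerance=1e-9,
                            max_inner_iterations=200)
        T = gicp(cloud, PointCloud3D(target, list(cloud.source)), params=params)
        T_ref = classic_icp(cloud.points, target)
        assert np.abs(T.matrix() - T_ref.matrix()).max() < 1e-6

    def test_objective_decreases(self, phantom):
        _, records = phantom
        cloud = project_record(next(r for r in records if r.key == ("SA", 3)))
        T_true = RigidTransform.from_rotvec([0, 0, 0.03], (2.0, -1.0, 0.5))
        target = PointCloud3D(T_true.apply(cloud.points), list(cloud.source))
        _, history = gicp(cloud, target, return_history=True)
        diffs = np.diff(history)
        assert np.all(diffs <= 1e-9 * max(history))


class TestRealign:
    def test_aligned_phantom_is_near_fixed_point(self, phantom):
        _, records = phantom
        result = realign(records)
        probe = np.array([[30.0, 0, 0], [0, 30.0, 0], [0, 0, 30.0]])
        for T in result.transforms.values():
            # correction stays small over the whole heart (lever arm ~30 mm)
            assert np.linalg.norm(T.apply(probe) - probe, axis=1).max() < 0.35
        # converges essentially immediately
        assert result.outer_iterations_used <= 3

    def test_recovery_improves_alignment(self, phantom):
        _, truth = phantom
        perturbed, _ = perturb(truth, PerturbationSpec(seed=3))
        result = realign(perturbed)
        assert rms_to_truth(result.realigned, truth) < rms_to_truth(perturbed, truth)
        assert len(result.transforms) == len(truth)
        assert all(d >= 0 for d in result.displacement_history)

    def test_equivariance_under_global_rigid_motion(self, phantom):
        _, truth = phantom
        perturbed, _ = perturb(truth, PerturbationSpec(seed=5))
        G = RigidTransform.from_rotvec([0.5, 0.2, -0.1], (20.0, -10.0, 5.0))
        moved = [G.apply(r) for r in perturbed]
        res_a = realign(perturbed)
        res_b = realign(moved)
        truth_moved = [G.apply(r) for r in truth]
        rms_a = rms_to_truth(res_a.realigned, truth)
        rms_b = rms_to_truth(res_b.realigned, truth_moved)
        assert abs(rms_a - rms_b) < 1e-3

    def test_too_few_slices(self, phantom):
        _, records = phantom
        with pytest.raises(ValueError):
            realign([r for r in records if r.view == "SA"])
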