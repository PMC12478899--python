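"""Alignment: centering, PCA orientation, cone-target RANSAC registration."""

import numpy as np
import pytest

from sensillum3d.align import (AmbiguousAxisError, align_chamber, center_cloud,
                               make_cone_target, pca_orient, ransac_register)
from sensillum3d.clouds import SensillumCloud
from sensillum3d.synthgen import ConeSpec, make_sensillum_cloud
from sensillum3d.transforms import rotation_about_axis


def _cylinder(axis="x", n=2000, length=10.0, radius=0.5, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(-length / 2, length / 2, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    yz = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    pts = {"x": np.column_stack([t, yz]),
           "z": np.column_stack([yz, t])}[axis]
    return SensillumCloud(points=pts)


class TestCenterCloud:
    def test_centroid_moves_to_origin(self):
        cloud = SensillumCloud(points=np.random.default_rng(0).random((50, 3)) + 5)
        centered, _ = center_cloud(cloud)
        np.testing.assert_allclose(centered.centroid, 0.0, atol=1e-12)

    def test_already_centered_unchanged(self):
        pts = np.random.default_rng(1).random((50, 3))
        pts -= pts.mean(axis=0)
        cloud = SensillumCloud(points=pts)
        centered, _ = center_cloud(cloud)
        np.testing.assert_allclose(centered.points, pts, atol=1e-12)

    def test_repeated_point_maps_to_origin(self):
        cloud = SensillumCloud(points=np.full((5, 3), 3.7))
        centered, _ = center_cloud(cloud)
        np.testing.assert_allclose(centered.points, 0.0, atol=1e-12)


class TestPcaOrient:
    def test_cylinder_along_x_rotates_to_z(self):
        oriented, _ = pca_orient(_cylinder("x"))
        spans = oriented.points.max(axis=0) - oriented.points.min(axis=0)
        assert spans[2] > 8.0 and max(spans[:2]) < 1.5

    def test_cone_base_down_keeps_identity_up_to_tolerance(self, chamber1_cone):
        cloud = make_sensillum_cloud(chamber1_cone, seed=0)
        oriented, tf = pca_orient(cloud)
        angle = np.degrees(np.arccos(np.clip(tf.rotation[2, 2], -1, 1)))
        assert angle < 2.0

    def test_apex_down_cone_gets_flipped(self, chamber1_cone):
        cloud = make_sensillum_cloud(chamber1_cone, seed=0)
        upside_down = cloud.replace_points(
            cloud.points @ rotation_about_axis([1, 0, 0], np.pi).T)
        oriented, _ = pca_orient(upside_down)
        pts = oriented.points
        z = pts[:, 2]
        r = np.hypot(pts[:, 0], pts[:, 1])
        lo, hi = np.quantile(z, [0.25, 0.75])
        assert r[z <= lo].mean() > r[z >= hi].mean()  # base ends up at low z

    def test_squat_cloud_raises_ambiguous_axis(self, squat_cone):
        # width ~ height: the leading eigenvalue is radial, not axial
        cloud = make_sensillum_cloud(squat_cone, seed=0)
        with pytest.raises(AmbiguousAxisError):
            pca_orient(cloud)

    def test_transform_is_rigid(self, chamber1_cone):
        cloud = make_sensillum_cloud(chamber1_cone, seed=1)
        oriented, _ = pca_orient(cloud)
        from scipy.spatial.distance import pdist
        before = pdist(cloud.points[:200])
        after = pdist(oriented.points[:200])
        np.testing.assert_allclose(after, before, rtol=1e-6)

    def test_provenance_replays_to_aligned_cloud(self, chamber1_cone):
        cloud = make_sensillum_cloud(chamber1_cone, seed=2)
        oriented, _ = pca_orient(cloud)
        replay = cloud.points.copy()
        for step in oriented.provenance:
            replay = replay @ np.asarray(step["rotation"]).T + np.asarray(step["translation"])
        np.testing.assert_allclose(replay, oriented.points, atol=1e-9)


class TestConeTarget:
    def test_half_height_width_is_half_base(self):
        target = make_cone_target(3.0, 6.0, points_n=4000)
        pts = target.points
        band = pts[np.abs(pts[:, 2] - 3.0) < 0.1]
        widths = 2 * np.hypot(band[:, 0], band[:, 1])
        assert widths.max() == pytest.approx(1.5, abs=0.06)

    def test_all_points_within_base_radius(self):
        target = make_cone_target(3.0, 6.0, points_n=2000)
        assert np.hypot(target.points[:, 0], target.points[:, 1]).max() <= 1.5 + 1e-9

    def test_pca_of_elongated_target_is_self_consistent(self):
        target = make_cone_target(2.0, 8.0, points_n=3000)
        oriented, tf = pca_orient(target)
        angle = np.degrees(np.arccos(np.clip(tf.rotation[2, 2], -1, 1)))
        assert angle < 2.0


class TestRansacRegister:
    def test_exact_copy_registers_to_identity(self, squat_cone):
        cloud = make_sensillum_cloud(squat_cone, seed=1)
        centered, _ = center_cloud(cloud)
        _, tf = ransac_register(centered, centered, voxel=0.15, seed=0)
        assert tf.fitness > 0.95
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=0.05)

    def test_rotated_target_realigned_below_rmsd_bound(self):
        from scipy.spatial import cKDTree
        target, _ = center_cloud(make_cone_target(3.0, 6.0, points_n=1500))
        rot = rotation_about_axis([0, 1, 0], np.radians(30))
        moving = target.replace_points(target.points @ rot.T)
        voxel = 0.04 * np.linalg.norm(moving.points.max(0) - moving.points.min(0))
        aligned, tf = ransac_register(moving, target, voxel, seed=5)
        assert tf.succeeded
        rmsd = np.sqrt((cKDTree(target.points).query(aligned.points)[0] ** 2).mean())
        assert rmsd < 2 * voxel

    def test_squat_cone_axis_recovered_within_ten_degrees(self, squat_cone):
        rng = np.random.default_rng(3)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        spec = ConeSpec(**{**squat_cone.to_dict(), "axis_direction": tuple(v)})
        cloud = make_sensillum_cloud(spec, seed=4)
        moving, _ = center_cloud(cloud)
        target, _ = center_cloud(make_cone_target(spec.base_width, spec.effective_height,
                                                  points_n=1500))
        voxel = 0.04 * np.linalg.norm(moving.points.max(0) - moving.points.min(0))
        _, tf = ransac_register(moving, target, voxel, seed=0)
        angle = np.degrees(np.arccos(np.clip((tf.rotation @ v)[2], -1, 1)))
        assert angle < 10.0

    def test_invalid_voxel_rejected(self, squat_cone):
        cloud = make_sensillum_cloud(squat_cone, seed=0)
        with pytest.raises(ValueError):
            ransac_register(cloud, cloud, voxel=0.0)

    def test_registration_is_seeded(self, squat_cone):
        cloud = make_sensillum_cloud(squat_cone, seed=1)
        centered, _ = center_cloud(cloud)
        target, _ = center_cloud(make_cone_target(3.3, 3.44, points_n=1000))
        _, t1 = ransac_register(centered, target, 0.2, seed=11)
        _, t2 = ransac_register(centered, target, 0.2, seed=11)
        np.testing.assert_array_equal(t1.rotation, t2.rotation)


class TestAlignChamber:
    def test_identical_cones_align_pairwise_within_five_degrees(self, chamber1_cone):
        rng = np.random.default_rng(0)
        clouds = []
        for i in range(4):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            spec = ConeSpec(**{**chamber1_cone.to_dict(), "axis_direction": tuple(v),
                               "points_n": 1200})
            clouds.append(make_sensillum_cloud(spec, seed=50 + i,
                                               sensillum_id=f"s{i}"))
        results = align_chamber(clouds, strategy="pca_then_ransac", seed=0)
        axes = []
        for cloud, tf in results:
            assert tf.succeeded
            _, evecs = np.linalg.eigh(np.cov((cloud.points - cloud.centroid).T))
            axes.append(evecs[:, -1] * np.sign(evecs[2, -1]))
        for a in axes[1:]:
            angle = np.degrees(np.arccos(np.clip(abs(np.dot(axes[0], a)), -1, 1)))
            assert angle < 5.0

    def test_single_cloud_is_just_pca_oriented(self, chamber1_cone):
        cloud = make_sensillum_cloud(chamber1_cone, seed=0)
        results = align_chamber([cloud], strategy="pca_then_ransac")
        assert len(results) == 1
        oriented, tf = results[0]
        expected, _ = pca_orient(cloud)
        np.testing.assert_allclose(oriented.points, expected.points, atol=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            align_chamber([])

    def test_cone_target_strategy_handles_squat_chamber(self, squat_cone):
        rng = np.random.default_rng(1)
        clouds = []
        truths = []
        for i in range(3):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            truths.append(v)
            spec = ConeSpec(**{**squat_cone.to_dict(), "axis_direction": tuple(v)})
            clouds.append(make_sensillum_cloud(spec, seed=60 + i,
                                               sensillum_id=f"s{i}"))
        results = align_chamber(clouds, strategy="cone_target", seed=0,
                                cone_dims=(3.3, 3.44))
        for (cloud, tf), v in zip(results, truths):
            assert tf.succeeded
            angle = np.degrees(np.arccos(np.clip((tf.rotation @ v)[2], -1, 1)))
            assert angle < 10.0
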