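"""Camera model, turntable kinematics, fiducial detection and pose solve."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from insecthull.camera import (
    CameraIntrinsics,
    CameraView,
    FiducialMatSpec,
    RigGeometry,
    RigidPose,
    TurntableState,
    detect_fiducial_markers,
    estimate_pose_from_mat,
    load_pose_table,
    pose_from_turntable,
    project_point,
    project_points,
    refine_poses,
    save_pose_table,
    specimen_rotation,
)
from insecthull.errors import (
    DegenerateConfigurationError,
    InsufficientMarkersError,
)
from insecthull.render import SyntheticScene, render_view


def rotation_angle_deg(Ra, Rb):
    cos = (np.trace(Ra @ Rb.T) - 1.0) / 2.0
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


INTR = CameraIntrinsics(2000.0, (240.0, 240.0), (480, 480))


class TestTurntable:
    def test_zero_angles_is_rig_pose(self):
        rig = RigGeometry(200.0)
        pose = pose_from_turntable(TurntableState(0, 0, 200.0), rig)
        assert np.allclose(pose.rotation, rig.base_pose.rotation)
        assert np.allclose(pose.translation, rig.base_pose.translation)

    def test_full_turn_periodicity(self):
        a = pose_from_turntable(TurntableState(0.0, 0.0, 150.0))
        b = pose_from_turntable(TurntableState(359.9999999999, 0.0, 150.0))
        assert np.allclose(a.rotation, b.rotation, atol=1e-9)

    def test_pan_composition(self):
        """Two successive 90-degree pans equal one 180-degree pan."""
        r90 = specimen_rotation(90.0, 0.0)
        r180 = specimen_rotation(180.0, 0.0)
        assert np.allclose(r90 @ r90, r180, atol=1e-12)
        pose_twice = RigGeometry(150.0).base_pose.compose_world_rotation(
            r90 @ r90)
        pose_180 = pose_from_turntable(TurntableState(180.0, 0.0, 150.0))
        assert np.allclose(pose_twice.rotation, pose_180.rotation, atol=1e-12)

    def test_pan_sweep_centres_on_circle(self):
        """Camera centres of a full pan sweep lie on a circle of the rig
        radius, in the tilt-dependent plane."""
        for tilt in (0.0, 25.0):
            centres = np.array([
                pose_from_turntable(
                    TurntableState(p, tilt, 150.0)).camera_center
                for p in np.linspace(0, 360, 37)])
            radii = np.linalg.norm(centres, axis=1)
            assert np.abs(radii - 150.0).max() < 1e-9

    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            TurntableState(0.0, 120.0, 150.0)
        with pytest.raises(ValueError):
            TurntableState(0.0, 0.0, -1.0)


class TestProjection:
    def test_on_axis_point_hits_principal_point(self):
        pose = pose_from_turntable(TurntableState(33.0, -12.0, 150.0))
        uv, behind = project_point([0.0, 0.0, 0.0], INTR, pose)
        assert not behind
        assert np.allclose(uv, INTR.principal_point, atol=1e-9)

    def test_similar_triangles_offset(self):
        pose = RigGeometry(100.0).base_pose
        # offset along the camera-x axis (= world +Y) by 1 mm at depth 100
        uv, _ = project_point([0.0, 1.0, 0.0], INTR, pose)
        assert np.allclose(uv, [240.0 + 2000.0 * 1.0 / 100.0, 240.0])

    def test_matches_homogeneous_matrix_oracle(self):
        rng = np.random.default_rng(42)
        pose = pose_from_turntable(TurntableState(71.0, 18.0, 150.0))
        P = INTR.matrix @ pose.matrix_3x4          # 3x4 projection matrix
        pts = rng.uniform(-20, 20, size=(50, 3))
        uv, in_front = project_points(pts, INTR, pose)
        hom = np.hstack([pts, np.ones((50, 1))]) @ P.T
        assert in_front.all()
        assert np.allclose(uv, hom[:, :2] / hom[:, 2:3], atol=1e-9)

    def test_behind_camera_flag(self):
        pose = RigGeometry(100.0).base_pose
        uv, behind = project_point([200.0, 0.0, 0.0], INTR, pose)
        assert behind and uv is None


class TestRigidPose:
    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidPose(np.eye(3) * 1.001, np.zeros(3))

    def test_rejects_reflection(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidPose(R, np.zeros(3))


class TestFiducialDetection:
    SPEC = FiducialMatSpec()

    def mat_view(self, tilt):
        pose = pose_from_turntable(TurntableState(0.0, tilt, 200.0))
        return CameraView(0, INTR, pose)

    def test_frontal_render_all_markers_subpixel(self):
        view = self.mat_view(90.0)        # camera straight above the mat
        img, _, _ = render_view(SyntheticScene((), mat=self.SPEC), view)
        markers = detect_fiducial_markers(img, self.SPEC)
        assert len(markers) == self.SPEC.marker_count
        truth, _ = project_points(self.SPEC.marker_positions(), INTR,
                                  view.pose)
        for mid, uv in markers:
            assert np.linalg.norm(uv - truth[mid]) < 0.5

    def test_oblique_render_finds_enough_markers(self):
        view = self.mat_view(30.0)        # 60 degrees off fronto-parallel
        img, _, _ = render_view(SyntheticScene((), mat=self.SPEC), view)
        markers = detect_fiducial_markers(img, self.SPEC)
        assert len(markers) >= 4

    def test_uniform_image_insufficient(self):
        img = np.full((120, 120, 3), 128, dtype=np.uint8)
        with pytest.raises(InsufficientMarkersError):
            detect_fiducial_markers(img, self.SPEC)

    def test_codes_must_be_distinct(self):
        with pytest.raises(ValueError):
            FiducialMatSpec(id_coding=(1, 1, 2, 3), marker_count=4)


class TestPoseFromMat:
    SPEC = FiducialMatSpec()

    def synthetic_markers(self, pose, noise=0.0, seed=0):
        uv, _ = project_points(self.SPEC.marker_positions(), INTR, pose)
        if noise:
            uv = uv + np.random.default_rng(seed).normal(0, noise, uv.shape)
        return [(i, uv[i]) for i in range(len(uv))]

    def test_noiseless_recovery(self):
        truth = pose_from_turntable(TurntableState(40.0, 35.0, 220.0))
        est, rms = estimate_pose_from_mat(
            self.synthetic_markers(truth), self.SPEC, INTR)
        assert rms < 1e-6
        assert rotation_angle_deg(est.rotation, truth.rotation) < 0.1
        assert (np.linalg.norm(est.translation - truth.translation)
                / np.linalg.norm(truth.translation)) < 1e-3

    def test_noisy_recovery_within_half_degree(self):
        truth = pose_from_turntable(TurntableState(40.0, 35.0, 220.0))
        est, _ = estimate_pose_from_mat(
            self.synthetic_markers(truth, noise=0.5, seed=11),
            self.SPEC, INTR)
        assert rotation_angle_deg(est.rotation, truth.rotation) < 0.5

    def test_collinear_markers_degenerate(self):
        markers = [(i, np.array([10.0 * i, 20.0 * i])) for i in range(4)]
        with pytest.raises(DegenerateConfigurationError):
            estimate_pose_from_mat(markers, self.SPEC, INTR)

    def test_too_few_markers(self):
        truth = pose_from_turntable(TurntableState(0.0, 45.0, 220.0))
        with pytest.raises(InsufficientMarkersError):
            estimate_pose_from_mat(self.synthetic_markers(truth)[:3],
                                   self.SPEC, INTR)


class TestRefinePoses:
    SPEC = FiducialMatSpec()

    def build(self, n=4, perturb_deg=0.0, seed=3):
        rng = np.random.default_rng(seed)
        views, markers = [], []
        for i in range(n):
            truth = pose_from_turntable(
                TurntableState(90.0 * i, 30.0, 220.0))
            uv, _ = project_points(self.SPEC.marker_positions(), INTR, truth)
            markers.append([(j, uv[j]) for j in range(len(uv))])
            pose = truth
            if perturb_deg:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                dR = Rotation.from_rotvec(
                    np.radians(perturb_deg) * axis).as_matrix()
                pose = RigidPose(dR @ truth.rotation, truth.translation)
            views.append(CameraView(i, INTR, pose))
        return views, markers

    @staticmethod
    def total_rms(views, markers, spec):
        from insecthull.camera import reprojection_rms
        pos = spec.marker_positions()
        per = []
        for v, mk in zip(views, markers):
            obj = np.array([pos[m] for m, _ in mk])
            uv = np.array([p for _, p in mk])
            per.append(reprojection_rms(obj, uv, v.intrinsics, v.pose))
        return float(np.sqrt(np.mean(np.square(per))))

    def test_optimal_poses_are_fixed_point(self):
        views, markers = self.build()
        out = refine_poses(views, markers, self.SPEC)
        for a, b in zip(views, out):
            assert np.allclose(a.pose.rotation, b.pose.rotation, atol=1e-6)
            assert np.allclose(a.pose.translation, b.pose.translation,
                               atol=1e-6)

    def test_perturbed_poses_improve(self):
        views, markers = self.build(perturb_deg=1.0, seed=5)
        before = self.total_rms(views, markers, self.SPEC)
        out = refine_poses(views, markers, self.SPEC)
        after = self.total_rms(out, markers, self.SPEC)
        assert after <= before
        assert after < 0.01       # essentially exact on noiseless markers

    def test_single_view_unchanged(self):
        views, markers = self.build(n=1, perturb_deg=2.0)
        out = refine_poses(views, markers, self.SPEC)
        assert out[0] is views[0]


def test_pose_table_round_trip(tmp_path):
    views = [CameraView(i, INTR,
                        pose_from_turntable(TurntableState(30.0 * i, 9.0,
                                                           150.0)))
             for i in range(5)]
    path = tmp_path / "poses.txt"
    save_pose_table(path, views)
    loaded = load_pose_table(path, INTR)
    assert len(loaded) == 5
    for a, b in zip(views, loaded):
        assert a.view_id == b.view_id
        assert np.allclose(a.pose.matrix_3x4, b.pose.matrix_3x4, atol=1e-10)
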