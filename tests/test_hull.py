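"""Voxel carving, octree equivalence, surface extraction, cleanup."""

import numpy as np
import pytest

from insecthull.camera import CameraIntrinsics, CameraView, RigidPose
from insecthull.errors import DegenerateGridError, NoViewsError
from insecthull.hull import (
    IsoMesh,
    VoxelGrid,
    carve,
    carve_octree,
    keep_largest_component,
    mesh_from_grid,
)
from insecthull.render import Primitive, SyntheticScene, render_view
from insecthull.silhouette import SilhouetteMask

from conftest import render_mattes, ring_views

INTR = CameraIntrinsics(4800.0, (120.0, 120.0), (240, 240))
SPHERE = SyntheticScene((Primitive("sphere", (5.0,)),))
SPHERE_VOL = 4.0 / 3.0 * np.pi * 125.0


def look_at_pose(camera_pos, roll_seed=0):
    """Pose of a camera at ``camera_pos`` looking at the origin."""
    rng = np.random.default_rng(roll_seed)
    C = np.asarray(camera_pos, float)
    z = -C / np.linalg.norm(C)
    up = rng.normal(size=3)
    up -= up @ z * z
    up /= np.linalg.norm(up)
    x = np.cross(up, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    return RigidPose(R, -R @ C)


def random_sphere_views(n, seed, dist=300.0):
    rng = np.random.default_rng(seed)
    views = []
    for i in range(n):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        views.append(CameraView(i, INTR,
                                look_at_pose(d * dist, roll_seed=seed + i)))
    return views


class TestCarve:
    def test_all_foreground_mask_carves_nothing_in_frustum(self):
        h, w = INTR.image_size[1], INTR.image_size[0]
        mask = SilhouetteMask(np.ones((h, w), dtype=bool))
        views = ring_views(INTR, 1, (0.0,))
        grid = carve([mask], views, (-6, -6, -6), (6, 6, 6),
                     resolution=(24, 24, 24))
        # box is well inside the frustum here, so nothing is carved
        assert grid.occupancy.all()

    def test_sphere_volume_within_tolerance(self):
        views = ring_views(INTR, 12, (-40.0, 0.0, 40.0))
        masks, _ = render_mattes(SPHERE, views)
        grid = carve(masks, views, (-8, -8, -8), (8, 8, 8),
                     resolution=(96, 96, 96))
        assert abs(grid.volume_mm3 - SPHERE_VOL) / SPHERE_VOL < 0.05

    def test_no_views_error(self):
        with pytest.raises(NoViewsError):
            carve([], [], (-1, -1, -1), (1, 1, 1))

    def test_empty_hull_warns(self):
        h, w = INTR.image_size[1], INTR.image_size[0]
        mask = SilhouetteMask(np.zeros((h, w), dtype=bool))
        views = ring_views(INTR, 1, (0.0,))
        with pytest.warns(UserWarning, match="empty hull"):
            grid = carve([mask], views, (-2, -2, -2), (2, 2, 2),
                         resolution=(8, 8, 8))
        assert not grid.occupancy.any()

    def test_corner_sampling_is_superset_of_centre_sampling(self):
        views = ring_views(INTR, 8, (0.0, 45.0))
        masks, _ = render_mattes(SPHERE, views)
        g1 = carve(masks, views, (-7, -7, -7), (7, 7, 7),
                   resolution=(24, 24, 24), samples_per_voxel=1)
        g8 = carve(masks, views, (-7, -7, -7), (7, 7, 7),
                   resolution=(24, 24, 24), samples_per_voxel=8)
        assert (g1.occupancy <= g8.occupancy).all()

    def test_superset_invariant_random_pose_sweep(self):
        """Visual hull property: with (dilated) exact silhouettes, every
        voxel centre inside the true object survives carving."""
        from skimage.morphology import dilation, disk

        views = random_sphere_views(20, seed=101)
        masks = []
        for v in views:
            _, matte, _ = render_view(SPHERE, v)
            masks.append(SilhouetteMask(dilation(matte, disk(1))))
        grid = carve(masks, views, (-7, -7, -7), (7, 7, 7),
                     resolution=(48, 48, 48))
        inside = SPHERE.contains(grid.centers()).reshape(grid.resolution)
        violations = inside & ~grid.occupancy
        assert violations.sum() == 0

    def test_monotone_in_views(self):
        """Adding views never increases the occupied voxel count."""
        views = ring_views(INTR, 6, (-30.0, 30.0))
        masks, _ = render_mattes(SPHERE, views)
        counts = []
        for n in (1, 3, 6, 12):
            g = carve(masks[:n], views[:n], (-7, -7, -7), (7, 7, 7),
                      resolution=(32, 32, 32))
            counts.append(int(g.occupancy.sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_convex_convergence_bounded_below_by_analytic(self):
        views = ring_views(INTR, 12, (-45.0, 0.0, 45.0))
        masks, _ = render_mattes(SPHERE, views)
        vols = []
        for n in (4, 9, 18, 36):
            g = carve(masks[:n], views[:n], (-7, -7, -7), (7, 7, 7),
                      resolution=(48, 48, 48))
            vols.append(g.volume_mm3)
        assert all(a >= b for a, b in zip(vols, vols[1:]))
        # voxelization can dither around the analytic value by half a
        # voxel shell; require the bound up to that quantization margin
        assert vols[-1] >= SPHERE_VOL * 0.97


class TestOctree:
    def seeded_scene(self, seed):
        rng = np.random.default_rng(seed)
        shapes = ["sphere", "box", "ellipsoid", "cylinder"]
        prims = []
        for k in range(rng.integers(1, 4)):
            shape = shapes[rng.integers(0, len(shapes))]
            size = {"sphere": (rng.uniform(1.5, 3.0),),
                    "box": tuple(rng.uniform(1.0, 2.5, 3)),
                    "ellipsoid": tuple(rng.uniform(1.0, 3.0, 3)),
                    "cylinder": (rng.uniform(0.5, 1.5),
                                 rng.uniform(1.0, 3.0))}[shape]
            prims.append(Primitive(shape, size,
                                   centre=tuple(rng.uniform(-2, 2, 3))))
        return SyntheticScene(tuple(prims))

    @pytest.mark.parametrize("seed", [11, 22, 33])
    def test_matches_dense_carve_bitwise(self, seed):
        scene = self.seeded_scene(seed)
        views = ring_views(INTR, 6, (-35.0, 20.0))
        masks, _ = render_mattes(scene, views)
        dense = carve(masks, views, (-8, -8, -8), (8, 8, 8),
                      resolution=(32, 32, 32))
        octree = carve_octree(masks, views, (-8, -8, -8), (8, 8, 8),
                              max_depth=5)
        assert np.array_equal(dense.occupancy, octree.occupancy)

    def test_all_background_mask_empty_at_any_depth(self):
        h, w = INTR.image_size[1], INTR.image_size[0]
        mask = SilhouetteMask(np.zeros((h, w), dtype=bool))
        views = ring_views(INTR, 1, (0.0,))
        for depth in (1, 3):
            with pytest.warns(UserWarning, match="empty hull"):
                g = carve_octree([mask], views, (-2, -2, -2), (2, 2, 2),
                                 max_depth=depth)
            assert not g.occupancy.any()

    def test_depth_one_matches_dense_2cubed(self):
        views = ring_views(INTR, 4, (0.0,))
        masks, _ = render_mattes(SPHERE, views)
        dense = carve(masks, views, (-6, -6, -6), (6, 6, 6),
                      resolution=(2, 2, 2))
        octree = carve_octree(masks, views, (-6, -6, -6), (6, 6, 6),
                              max_depth=1)
        assert np.array_equal(dense.occupancy, octree.occupancy)


class TestMeshFromGrid:
    def test_single_voxel_is_topological_sphere(self):
        occ = np.zeros((3, 3, 3), dtype=bool)
        occ[1, 1, 1] = True
        grid = VoxelGrid((0, 0, 0), (3, 3, 3), occ)
        mesh = mesh_from_grid(grid)
        tm = mesh.to_trimesh()
        assert tm.is_watertight
        assert tm.euler_number == 2

    def test_carved_sphere_mesh_volume(self):
        views = ring_views(INTR, 12, (-40.0, 0.0, 40.0))
        masks, _ = render_mattes(SPHERE, views)
        grid = carve(masks, views, (-8, -8, -8), (8, 8, 8),
                     resolution=(64, 64, 64))
        mesh = mesh_from_grid(grid)
        assert abs(mesh.volume_mm3 - SPHERE_VOL) / SPHERE_VOL < 0.05

    def test_degenerate_grids_rejected(self):
        with pytest.raises(DegenerateGridError):
            mesh_from_grid(VoxelGrid((0, 0, 0), (1, 1, 1),
                                     np.zeros((4, 4, 4), dtype=bool)))
        with pytest.raises(DegenerateGridError):
            mesh_from_grid(VoxelGrid((0, 0, 0), (1, 1, 1),
                                     np.ones((4, 4, 4), dtype=bool)))

    def test_vertices_in_mm_frame(self):
        occ = np.zeros((4, 4, 4), dtype=bool)
        occ[1:3, 1:3, 1:3] = True
        grid = VoxelGrid((-2, -2, -2), (2, 2, 2), occ)
        mesh = mesh_from_grid(grid)
        assert np.abs(mesh.vertices).max() <= 2.0
        assert np.allclose(mesh.vertices.mean(axis=0), 0.0, atol=0.05)


class TestKeepLargest:
    @staticmethod
    def two_blob_grid():
        occ = np.zeros((12, 6, 6), dtype=bool)
        occ[1:6, 1:5, 1:5] = True          # 80 voxels
        occ[8:10, 2:4, 2:4] = True         # 8 voxels
        return VoxelGrid((0, 0, 0), (12, 6, 6), occ)

    def test_single_component_unchanged(self):
        occ = np.zeros((4, 4, 4), dtype=bool)
        occ[1:3, 1:3, 1:3] = True
        mesh = mesh_from_grid(VoxelGrid((0, 0, 0), (4, 4, 4), occ))
        out = keep_largest_component(mesh)
        assert out is mesh

    def test_small_component_dropped(self):
        mesh = mesh_from_grid(self.two_blob_grid())
        out = keep_largest_component(mesh)
        big = mesh.to_trimesh().split(only_watertight=False)
        assert len(big) == 2
        assert len(out.faces) == max(len(b.faces) for b in big)
        assert len(out.to_trimesh().split(only_watertight=False)) == 1

    def test_equal_components_tie_breaks_to_lowest_vertex(self):
        occ = np.zeros((7, 3, 3), dtype=bool)
        occ[1, 1, 1] = True
        occ[5, 1, 1] = True
        mesh = mesh_from_grid(VoxelGrid((0, 0, 0), (7, 3, 3), occ))
        out = keep_largest_component(mesh)
        # marching cubes emits the lower-x voxel's vertices first
        assert 0 in out.faces.flatten() or \
            np.isclose(out.vertices[:, 0].mean(), 1.5, atol=0.6)
        assert out.vertices[:, 0].max() < 3.0
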