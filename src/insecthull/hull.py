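"""Visual-hull reconstruction: silhouette carving and surface extraction.

The visual hull is the intersection of the back-projected silhouette
cones — the maximal shape consistent with every view's silhouette, always
a superset of the true object.  ``carve`` realizes it on a voxel grid: a
voxel survives iff, in every view, at least one of its sample points
projects inside that view's silhouette; voxels a view cannot see (outside
its image bounds, or behind the camera) are never carved by that view,
matching the physical rig where the mat occludes the underside.
``carve_octree`` accelerates the identical decision rule by hierarchical
interior/exterior pruning, and ``mesh_from_grid`` extracts the marching-
cubes isosurface of the occupancy field in specimen (mm) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from insecthull.camera import CameraView
from insecthull.errors import DegenerateGridError, NoViewsError
from insecthull.silhouette import SilhouetteMask

__all__ = ["VoxelGrid", "IsoMesh", "carve", "carve_octree", "mesh_from_grid",
           "keep_largest_component"]


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned occupancy volume in specimen (mm) coordinates."""

    bbox_min: np.ndarray
    bbox_max: np.ndarray
    occupancy: np.ndarray          # bool, shape (nx, ny, nz)

    def __post_init__(self):
        lo = np.asarray(self.bbox_min, dtype=float).reshape(3)
        hi = np.asarray(self.bbox_max, dtype=float).reshape(3)
        occ = np.asarray(self.occupancy)
        if occ.dtype != bool:
            occ = occ.astype(bool)
        if occ.ndim != 3 or min(occ.shape) < 1:
            raise ValueError("occupancy must be a 3D array")
        if not (hi > lo).all():
            raise ValueError("bbox must have positive extent on all axes")
        object.__setattr__(self, "bbox_min", lo)
        object.__setattr__(self, "bbox_max", hi)
        object.__setattr__(self, "occupancy", occ)

    @property
    def resolution(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return (self.bbox_max - self.bbox_min) / np.asarray(self.resolution)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def volume_mm3(self) -> float:
        """Occupied volume: voxel count x voxel volume."""
        return float(self.occupancy.sum()) * self.voxel_volume_mm3

    def centers(self) -> np.ndarray:
        """(N, 3) world coordinates of all voxel centres, C-order."""
        nx, ny, nz = self.resolution
        vs = self.voxel_size
        ax = [self.bbox_min[d] + (np.arange((nx, ny, nz)[d]) + 0.5) * vs[d]
              for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # -- debug export -------------------------------------------------------

    def save(self, path_prefix: str):
        """Raw bitmap + JSON header (``<prefix>.npy`` / ``<prefix>.json``)."""
        import json
        np.save(str(path_prefix) + ".npy", self.occupancy)
        with open(str(path_prefix) + ".json", "w") as fh:
            json.dump({"bbox_min": self.bbox_min.tolist(),
                       "bbox_max": self.bbox_max.tolist(),
                       "resolution": list(self.resolution)}, fh)


@dataclass(frozen=True)
class IsoMesh:
    """Triangle surface mesh in mm, with per-vertex normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if self.normals is not None:
            object.__setattr__(self, "normals",
                               np.asarray(self.normals, float).reshape(-1, 3))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @property
    def volume_mm3(self) -> float:
        """Signed volume by the divergence theorem (sum over components)."""
        return float(abs(self.to_trimesh().volume))

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.clip(norm, 1e-30, None)


# ---------------------------------------------------------------------------
# Dense carving
# ---------------------------------------------------------------------------

def _sample_offsets(grid_vs: np.ndarray, samples_per_voxel: int) -> np.ndarray:
    """Sample-point offsets from the voxel centre, in mm."""
    if samples_per_voxel == 1:
        return np.zeros((1, 3))
    if samples_per_voxel == 8:
        half = grid_vs / 2.0
        corners = np.array([[sx, sy, sz] for sx in (-1, 1)
                            for sy in (-1, 1) for sz in (-1, 1)], float)
        return corners * half
    raise ValueError("samples_per_voxel must be 1 (centre) or 8 (corners)")


def _carved_by_view(points: np.ndarray, mask: np.ndarray,
                    view: CameraView) -> np.ndarray:
    """True where a sample point is seen by the view and lands outside
    its silhouette (i.e. the view vetoes it)."""
    intr = view.intrinsics
    cam = points @ view.pose.rotation.T + view.pose.translation
    z = cam[:, 2]
    in_front = z > 1e-9
    zs = np.where(in_front, z, 1.0)
    f = intr.focal_length_px
    cx, cy = intr.principal_point
    uf = np.round(f * cam[:, 0] / zs + cx)
    vf = np.round(f * cam[:, 1] / zs + cy)
    h, w = mask.shape
    inside_img = in_front & (uf >= 0) & (uf < w) & (vf >= 0) & (vf < h)
    out = np.zeros(len(points), dtype=bool)
    idx = np.flatnonzero(inside_img)
    out[idx] = ~mask[vf[idx].astype(np.int64), uf[idx].astype(np.int64)]
    return out


def carve(masks: list[SilhouetteMask], views: list[CameraView],
          bbox_min, bbox_max, resolution=(128, 128, 128),
          samples_per_voxel: int = 1,
          chunk_voxels: int = 1 << 20) -> VoxelGrid:
    """Carve a voxel grid to the visual hull of the silhouettes.

    A voxel stays occupied iff for every view at least one of its sample
    points (centre, or the 8 corners) projects inside the silhouette or is
    unseen by that view.  Processing is chunked along the flattened grid
    to bound memory.

    Raises ``NoViewsError`` with an empty view list; warns when every
    voxel is carved.
    """
    if len(views) == 0 or len(masks) != len(views):
        raise NoViewsError("need equally many masks and views, >= 1")
    grid = VoxelGrid(bbox_min, bbox_max,
                     np.ones(tuple(int(r) for r in resolution), dtype=bool))
    offsets = _sample_offsets(grid.voxel_size, samples_per_voxel)
    occ = np.ones(int(np.prod(grid.resolution)), dtype=bool)
    centers = grid.centers()
    n = len(centers)
    for start in range(0, n, chunk_voxels):
        sl = slice(start, min(start + chunk_voxels, n))
        alive = np.flatnonzero(occ[sl]) + start
        if alive.size == 0:
            continue
        for sil, view in zip(masks, views):
            if alive.size == 0:
                break
            vetoed = np.ones(alive.size, dtype=bool)
            for off in offsets:
                vetoed &= _carved_by_view(centers[alive] + off,
                                          sil.mask, view)
                if not vetoed.any():
                    break
            occ[alive[vetoed]] = False
            alive = alive[~vetoed]
    occupancy = occ.reshape(grid.resolution)
    if not occupancy.any():
        warnings.warn("empty hull: every voxel was carved", stacklevel=2)
    return VoxelGrid(bbox_min, bbox_max, occupancy)


# ---------------------------------------------------------------------------
# Octree carving (identical decision rule, hierarchically pruned)
# ---------------------------------------------------------------------------

def _integral(mask: np.ndarray) -> np.ndarray:
    s = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=s[1:, 1:])
    return s


def _box_sum(integral: np.ndarray, v0: int, v1: int, u0: int, u1: int) -> int:
    """Foreground count over pixel rows [v0, v1] x cols [u0, u1], clipped."""
    h, w = integral.shape[0] - 1, integral.shape[1] - 1
    v0, u0 = max(v0, 0), max(u0, 0)
    v1, u1 = min(v1, h - 1), min(u1, w - 1)
    if v1 < v0 or u1 < u0:
        return 0
    return int(integral[v1 + 1, u1 + 1] - integral[v0, u1 + 1]
               - integral[v1 + 1, u0] + integral[v0, u0])


def _classify_node(corners: np.ndarray, sil_int: np.ndarray,
                   view: CameraView) -> str:
    """Conservative node-vs-silhouette test from the 8 projected corners.

    Returns "empty" (every point in the node is vetoed by this view),
    "full" (no point can be vetoed), or "mixed" (must recurse).  Any
    corner at non-positive depth defeats the convexity argument, so the
    node is "mixed" unless provably unseen.
    """
    intr = view.intrinsics
    cam = corners @ view.pose.rotation.T + view.pose.translation
    z = cam[:, 2]
    if (z <= 1e-9).any():
        return "mixed"
    f = intr.focal_length_px
    cx, cy = intr.principal_point
    u = f * cam[:, 0] / z + cx
    v = f * cam[:, 1] / z + cy
    h, w = sil_int.shape[0] - 1, sil_int.shape[1] - 1
    # +-1 px pad covers the nearest-pixel rounding of the dense rule
    u0, u1 = int(np.floor(u.min())) - 1, int(np.ceil(u.max())) + 1
    v0, v1 = int(np.floor(v.min())) - 1, int(np.ceil(v.max())) + 1
    if u1 < 0 or u0 > w - 1 or v1 < 0 or v0 > h - 1:
        return "full"          # wholly outside the image: unseen, uncarved
    inside = (u0 >= 0) and (u1 <= w - 1) and (v0 >= 0) and (v1 <= h - 1)
    fg = _box_sum(sil_int, v0, v1, u0, u1)
    if fg == 0 and inside:
        return "empty"
    if inside and fg == (v1 - v0 + 1) * (u1 - u0 + 1):
        return "full"
    return "mixed"


def carve_octree(masks: list[SilhouetteMask], views: list[CameraView],
                 bbox_min, bbox_max, max_depth: int = 5) -> VoxelGrid:
    """Hierarchical carve, bit-identical to ``carve`` at 2^depth per side.

    Cubic nodes whose projected bound lies entirely outside (or inside)
    every silhouette are resolved without descending; leaves fall back to
    the dense voxel-centre rule, so the resulting occupancy equals
    ``carve(..., resolution=(2**max_depth,)*3, samples_per_voxel=1)``.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if len(views) == 0 or len(masks) != len(views):
        raise NoViewsError("need equally many masks and views, >= 1")
    res = 2 ** max_depth
    lo = np.asarray(bbox_min, dtype=float).reshape(3)
    hi = np.asarray(bbox_max, dtype=float).reshape(3)
    vs = (hi - lo) / res
    occ = np.zeros((res, res, res), dtype=bool)
    integrals = [_integral(s.mask) for s in masks]

    corner_unit = np.array([[sx, sy, sz] for sx in (0, 1)
                            for sy in (0, 1) for sz in (0, 1)], float)

    def fill_dense(i0, j0, k0, size):
        """Leaf-level exact evaluation of a size^3 block."""
        idx = np.array([(i, j, k)
                        for i in range(i0, i0 + size)
                        for j in range(j0, j0 + size)
                        for k in range(k0, k0 + size)])
        pts = lo + (idx + 0.5) * vs
        alive = np.ones(len(pts), dtype=bool)
        for sil, view in zip(masks, views):
            if not alive.any():
                break
            vet = _carved_by_view(pts[alive], sil.mask, view)
            keep = np.flatnonzero(alive)
            alive[keep[vet]] = False
        for (i, j, k), a in zip(idx, alive):
            occ[i, j, k] = a

    def recurse(i0, j0, k0, size):
        node_lo = lo + np.array([i0, j0, k0]) * vs
        corners = node_lo + corner_unit * (vs * size)
        all_full = True
        for sil_int, view in zip(integrals, views):
            c = _classify_node(corners, sil_int, view)
            if c == "empty":
                return                       # carved wholesale
            if c != "full":
                all_full = False
        if all_full:
            occ[i0:i0 + size, j0:j0 + size, k0:k0 + size] = True
            return
        if size == 1:
            fill_dense(i0, j0, k0, 1)
            return
        half = size // 2
        for di in (0, half):
            for dj in (0, half):
                for dk in (0, half):
                    recurse(i0 + di, j0 + dj, k0 + dk, half)

    recurse(0, 0, 0, res)
    if not occ.any():
        warnings.warn("empty hull: every voxel was carved", stacklevel=2)
    return VoxelGrid(lo, hi, occ)


# ---------------------------------------------------------------------------
# Surface extraction and cleanup
# ---------------------------------------------------------------------------

def mesh_from_grid(grid: VoxelGrid, iso_level: float = 0.5) -> IsoMesh:
    """Marching-cubes surface of the occupancy field, in mm coordinates.

    The field is zero-padded by one voxel so occupancy touching the grid
    boundary still closes; vertices are mapped so lattice point ``i``
    sits at the centre of voxel ``i``.

    Raises ``DegenerateGridError`` for all-empty or all-occupied grids.
    """
    occ = grid.occupancy
    if not occ.any():
        raise DegenerateGridError("all voxels empty: no surface")
    if occ.all():
        raise DegenerateGridError("all voxels occupied: no surface")
    field = np.pad(occ.astype(np.float32), 1)
    verts, faces, normals, _ = marching_cubes(field, level=iso_level)
    verts = grid.bbox_min + (verts - 1.0 + 0.5) * grid.voxel_size
    return IsoMesh(verts, faces, normals)


def keep_largest_component(mesh: IsoMesh) -> IsoMesh:
    """Retain only the largest face-connected component.

    Size is face count; an exact tie goes to the component containing the
    lowest vertex index.
    """
    tm = mesh.to_trimesh()
    groups = trimesh.graph.connected_components(
        tm.face_adjacency, nodes=np.arange(len(mesh.faces)))
    if len(groups) <= 1:
        return mesh
    def key(g):
        return (len(g), -int(mesh.faces[g].min()))
    best = max(groups, key=key)
    faces = mesh.faces[np.sort(best)]
    used = np.unique(faces)
    remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    normals = mesh.normals[used] if mesh.normals is not None else None
    return IsoMesh(mesh.vertices[used], remap[faces], normals)
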