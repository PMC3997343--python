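"""Natural-colour texture baking, 3D pin removal, and mesh export.

Each mesh face is textured from the single calibrated view that sees it
best: among views where the face centroid passes a depth-buffer
visibility test, the one whose viewing direction is most parallel to the
face normal wins — surface regions never imaged face-on end up flagged
"unseen", which is exactly how sparse pose coverage degrades a model's
colour.  Faces are packed as right triangles into a square atlas and
filled by bilinear sampling of the source photographs.  The mounting pin
can be edited out of the reconstructed mesh (deleting secondary
components, or all faces inside a user-given cylinder around the pin
axis), and results export to OBJ(+MTL), PLY, STL and X3D.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image
from scipy import ndimage

from insecthull.camera import CameraView, project_points
from insecthull.errors import AtlasOverflowError, UnsupportedFormatError
from insecthull.hull import IsoMesh

__all__ = ["TexturedMesh", "select_best_view", "bake_atlas", "remove_pin",
           "export_mesh", "load_obj"]

UNSEEN = -1
UNSEEN_COLOUR = (255, 0, 255)          # magenta flag for untextured texels


@dataclass(frozen=True)
class TexturedMesh:
    """Mesh + atlas + per-face UV triangle + per-face source view id."""

    mesh: IsoMesh
    atlas: np.ndarray
    face_uv: np.ndarray                 # (F, 3, 2) in [0, 1]^2
    face_view: np.ndarray               # (F,), UNSEEN where no view applies
    metadata: dict = field(default_factory=lambda: {
        "unseen_colour": UNSEEN_COLOUR})

    def __post_init__(self):
        uv = np.asarray(self.face_uv, dtype=float)
        fv = np.asarray(self.face_view, dtype=np.int64)
        if uv.shape != (len(self.mesh.faces), 3, 2):
            raise ValueError("face_uv must be (F, 3, 2)")
        if fv.shape != (len(self.mesh.faces),):
            raise ValueError("face_view must be (F,)")
        if uv.size and (uv.min() < -1e-9 or uv.max() > 1 + 1e-9):
            raise ValueError("UVs must lie in [0, 1]^2")
        object.__setattr__(self, "face_uv", uv)
        object.__setattr__(self, "face_view", fv)

    def subset_faces(self, face_idx: np.ndarray) -> "TexturedMesh":
        """New TexturedMesh restricted to the given faces (atlas shared)."""
        face_idx = np.asarray(face_idx)
        sub = IsoMesh(self.mesh.vertices, self.mesh.faces[face_idx],
                      self.mesh.normals)
        return TexturedMesh(sub, self.atlas, self.face_uv[face_idx],
                            self.face_view[face_idx], dict(self.metadata))


# ---------------------------------------------------------------------------
# Visibility and view selection
# ---------------------------------------------------------------------------

def _project_cam(points: np.ndarray, view: CameraView):
    cam = points @ view.pose.rotation.T + view.pose.translation
    z = cam[:, 2]
    f = view.intrinsics.focal_length_px
    cx, cy = view.intrinsics.principal_point
    zs = np.where(z > 1e-12, z, 1.0)
    return np.column_stack([f * cam[:, 0] / zs + cx,
                            f * cam[:, 1] / zs + cy]), z


def _depth_id_buffers(mesh: IsoMesh, view: CameraView,
                      chunk: int = 8192) -> tuple[np.ndarray, np.ndarray]:
    """Rasterized nearest-depth and winning-face-id buffers for a view.

    All faces are rasterized in vectorized chunks over a common square
    pixel window sized to the largest on-screen triangle; depth is
    interpolated affinely in screen space (not perspective-correct),
    which for marching-cubes-sized triangles is far below the visibility
    tolerance.  ``idbuf`` holds the face index owning each pixel (-1
    where nothing is drawn).
    """
    w, h = view.intrinsics.image_size
    zbuf = np.full(h * w, np.inf)
    idbuf = np.full(h * w, -1, dtype=np.int64)
    uv, z = _project_cam(mesh.vertices, view)
    tri_uv = uv[mesh.faces]          # (F, 3, 2)
    tri_z = z[mesh.faces]
    valid = (tri_z > 1e-9).all(axis=1)
    # discard faces fully off-screen
    valid &= (tri_uv[:, :, 0].max(axis=1) >= 0) & \
             (tri_uv[:, :, 0].min(axis=1) <= w - 1) & \
             (tri_uv[:, :, 1].max(axis=1) >= 0) & \
             (tri_uv[:, :, 1].min(axis=1) <= h - 1)
    face_ids = np.flatnonzero(valid)
    tri_uv, tri_z = tri_uv[valid], tri_z[valid]
    if len(tri_uv) == 0:
        return zbuf.reshape(h, w), idbuf.reshape(h, w)
    ext = np.ceil(tri_uv.max(axis=1) - tri_uv.min(axis=1)).max() + 2
    win = int(min(max(ext, 2), 64))
    offs = np.arange(win)
    frag_px, frag_z, frag_id = [], [], []
    for s in range(0, len(tri_uv), chunk):
        p = tri_uv[s:s + chunk]
        zv = tri_z[s:s + chunk]
        fid = face_ids[s:s + chunk]
        x0 = np.floor(p[:, :, 0].min(axis=1)).astype(np.int64)
        y0 = np.floor(p[:, :, 1].min(axis=1)).astype(np.int64)
        gx = np.broadcast_to(x0[:, None, None] + offs[None, None, :],
                             (len(p), win, win))
        gy = np.broadcast_to(y0[:, None, None] + offs[None, :, None],
                             (len(p), win, win))
        d = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        d = np.where(np.abs(d) < 1e-12, np.inf, d)[:, None, None]
        dx = gx - p[:, 0, 0][:, None, None]
        dy = gy - p[:, 0, 1][:, None, None]
        e1 = (p[:, 2, 1] - p[:, 0, 1])[:, None, None]
        e2 = (p[:, 2, 0] - p[:, 0, 0])[:, None, None]
        e3 = (p[:, 1, 0] - p[:, 0, 0])[:, None, None]
        e4 = (p[:, 1, 1] - p[:, 0, 1])[:, None, None]
        w1 = (dx * e1 - e2 * dy) / d
        w2 = (e3 * dy - dx * e4) / d
        w0 = 1.0 - w1 - w2
        eps = -1e-9
        inside = (w0 >= eps) & (w1 >= eps) & (w2 >= eps) & \
                 (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h)
        depth = (w0 * zv[:, 0][:, None, None]
                 + w1 * zv[:, 1][:, None, None]
                 + w2 * zv[:, 2][:, None, None])
        frag_px.append((gy * w + gx)[inside])
        frag_z.append(depth[inside])
        frag_id.append(np.broadcast_to(fid[:, None, None],
                                       inside.shape)[inside])
    px = np.concatenate(frag_px)
    fz = np.concatenate(frag_z)
    fi = np.concatenate(frag_id)
    # nearest fragment wins: write in decreasing depth order
    order = np.argsort(-fz, kind="stable")
    zbuf[px[order]] = fz[order]
    idbuf[px[order]] = fi[order]
    return zbuf.reshape(h, w), idbuf.reshape(h, w)


def select_best_view(mesh: IsoMesh, views: list[CameraView],
                     depth_tol_mm: float | None = None) -> np.ndarray:
    """Assign each face the view that sees it most face-on.

    A face is a candidate in a view when it is unoccluded there: it owns
    at least one pixel of the view's rasterized face-id buffer, or — for
    sub-pixel faces — its centroid passes a depth-buffer test against the
    mesh itself (tolerance: 2x the median edge length unless overridden).
    Among candidates the view maximizing |cos| between face normal and
    the direction to the camera wins; ties break to the lower view id.
    Faces with no candidate in any view get ``UNSEEN``.
    """
    if len(views) == 0:
        raise ValueError("need >= 1 view")
    if depth_tol_mm is None:
        e = mesh.vertices[mesh.faces]
        edges = np.linalg.norm(
            np.diff(np.concatenate([e, e[:, :1]], axis=1), axis=1), axis=2)
        depth_tol_mm = 2.0 * float(np.median(edges)) if edges.size else 0.1
    centroids = mesh.face_centroids()
    # score against neighbourhood-smoothed normals: raw marching-cubes
    # facet normals alternate at the voxel scale and would favour grazing
    # views of the underlying surface
    vn = mesh.to_trimesh().vertex_normals
    normals = vn[mesh.faces].mean(axis=1)
    normals /= np.clip(np.linalg.norm(normals, axis=1, keepdims=True),
                       1e-30, None)
    n_faces = len(mesh.faces)
    best_score = np.full(n_faces, -np.inf)
    best_view = np.full(n_faces, UNSEEN, dtype=np.int64)
    for view in sorted(views, key=lambda v: v.view_id):
        w, h = view.intrinsics.image_size
        zbuf, idbuf = _depth_id_buffers(mesh, view)
        owns = np.zeros(n_faces, dtype=bool)
        owned = idbuf[idbuf >= 0]
        owns[owned] = True
        uv, z = _project_cam(centroids, view)
        ui = np.round(uv[:, 0]).astype(np.int64)
        vi_px = np.round(uv[:, 1]).astype(np.int64)
        ok = (z > 1e-9) & (uv[:, 0] >= 0) & (uv[:, 0] < w) \
            & (uv[:, 1] >= 0) & (uv[:, 1] < h)
        ui, vi_px = np.clip(ui, 0, w - 1), np.clip(vi_px, 0, h - 1)
        visible = owns | (ok & (z <= zbuf[vi_px, ui] + depth_tol_mm))
        to_cam = view.pose.camera_center - centroids
        to_cam /= np.clip(np.linalg.norm(to_cam, axis=1, keepdims=True),
                          1e-30, None)
        score = np.abs((normals * to_cam).sum(axis=1))
        better = visible & (score > best_score)
        best_score[better] = score[better]
        best_view[better] = view.view_id
    return best_view


# ---------------------------------------------------------------------------
# Atlas baking
# ---------------------------------------------------------------------------

def _bilinear(image: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Bilinear sample (N, 2) pixel coordinates from an RGB image."""
    coords = np.stack([uv[:, 1], uv[:, 0]])
    out = np.empty((len(uv), image.shape[2]))
    for c in range(image.shape[2]):
        out[:, c] = ndimage.map_coordinates(image[:, :, c].astype(float),
                                            coords, order=1, mode="nearest")
    return out


def bake_atlas(mesh: IsoMesh, assignments: np.ndarray,
               images: dict | list, views: list[CameraView],
               atlas_size: int = 2048) -> TexturedMesh:
    """Rasterize every face into a square texture atlas.

    Faces are laid out one per grid cell as axis-aligned right triangles;
    each texel maps barycentrically to a surface point, projects into the
    face's assigned source image and bilinearly samples its colour.
    Unseen faces are filled with the magenta flag colour.

    Raises ``AtlasOverflowError`` when the faces cannot be packed at the
    requested size (cells would be under 2 px).
    """
    n_faces = len(mesh.faces)
    if n_faces == 0:
        raise ValueError("mesh has no faces")
    cells = int(np.ceil(np.sqrt(n_faces)))
    cell_px = atlas_size // cells
    if cell_px < 2:
        raise AtlasOverflowError(
            f"{n_faces} faces need >= {2 * cells} px atlas, got {atlas_size}")
    view_by_id = {v.view_id: v for v in views}
    if isinstance(images, (list, tuple)):
        images = {v.view_id: img for v, img in zip(views, images)}
    atlas = np.full((atlas_size, atlas_size, 3), 255, dtype=np.uint8)
    face_uv = np.zeros((n_faces, 3, 2))
    margin = 0.5 if cell_px <= 3 else 1.0
    for f in range(n_faces):
        r, c = divmod(f, cells)
        x0, y0 = c * cell_px, r * cell_px
        # right triangle with the right angle at the cell origin
        p = np.array([[x0 + margin, y0 + margin],
                      [x0 + cell_px - margin, y0 + margin],
                      [x0 + margin, y0 + cell_px - margin]])
        face_uv[f] = p / atlas_size
        vid = int(assignments[f])
        xi0, xi1 = int(np.floor(p[:, 0].min())), int(np.ceil(p[:, 0].max()))
        yi0, yi1 = int(np.floor(p[:, 1].min())), int(np.ceil(p[:, 1].max()))
        gx, gy = np.meshgrid(np.arange(xi0, xi1), np.arange(yi0, yi1))
        px = np.column_stack([gx.ravel() + 0.5, gy.ravel() + 0.5])
        # barycentric in the right triangle (legs along +x, +y)
        leg = cell_px - 2 * margin
        w1 = (px[:, 0] - p[0, 0]) / leg
        w2 = (px[:, 1] - p[0, 1]) / leg
        w0 = 1.0 - w1 - w2
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        if vid == UNSEEN or vid not in view_by_id:
            colours = np.tile(np.asarray(UNSEEN_COLOUR, np.uint8),
                              (int(inside.sum()), 1))
        else:
            tri = mesh.vertices[mesh.faces[f]]
            pts3d = (w0[inside, None] * tri[0] + w1[inside, None] * tri[1]
                     + w2[inside, None] * tri[2])
            uv_img, in_front = project_points(
                pts3d, view_by_id[vid].intrinsics, view_by_id[vid].pose)
            colours = np.clip(np.round(
                _bilinear(np.asarray(images[vid]), uv_img)), 0, 255
            ).astype(np.uint8)
        atlas[px[inside, 1].astype(int), px[inside, 0].astype(int)] = colours
    return TexturedMesh(mesh, atlas, face_uv,
                        np.asarray(assignments, np.int64))


def face_mean_colours(tm: TexturedMesh) -> np.ndarray:
    """Mean atlas colour per face — the face-level colour readout used by
    the texture-accuracy checks."""
    out = np.zeros((len(tm.mesh.faces), 3))
    size = tm.atlas.shape[0]
    for f in range(len(tm.mesh.faces)):
        p = tm.face_uv[f] * size
        xi0, xi1 = int(np.floor(p[:, 0].min())), int(np.ceil(p[:, 0].max()))
        yi0, yi1 = int(np.floor(p[:, 1].min())), int(np.ceil(p[:, 1].max()))
        gx, gy = np.meshgrid(np.arange(xi0, xi1), np.arange(yi0, yi1))
        px = np.column_stack([gx.ravel() + 0.5, gy.ravel() + 0.5])
        leg = p[1, 0] - p[0, 0]
        w1 = (px[:, 0] - p[0, 0]) / leg
        w2 = (px[:, 1] - p[0, 1]) / leg
        inside = (w1 >= 0) & (w2 >= 0) & (1.0 - w1 - w2 >= 0)
        texels = tm.atlas[px[inside, 1].astype(int), px[inside, 0].astype(int)]
        out[f] = texels.reshape(-1, 3).mean(axis=0) if inside.any() else np.nan
    return out


# ---------------------------------------------------------------------------
# Pin removal (3D mesh editing)
# ---------------------------------------------------------------------------

def _boundary_edge_count(faces: np.ndarray) -> int:
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts == 1).sum())


def remove_pin(tm: TexturedMesh, method: str = "component",
               axis_point=None, axis_dir=(0.0, 0.0, 1.0),
               radius_mm: float = 0.3) -> tuple[TexturedMesh, dict]:
    """Edit the mounting pin out of a reconstructed model.

    ``component`` deletes every face-connected component except the
    largest (a pin separated from the body by the mounting gap carves to
    its own component).  ``cylinder`` deletes faces whose centroids lie
    within ``radius_mm`` of the infinite line through ``axis_point``
    along ``axis_dir`` — for pins fused to the body — then keeps the
    largest remaining component.  Returns ``(mesh, info)`` where ``info``
    reports faces removed and the boundary-edge count of the hole left
    behind; warns "nothing removed" when no face matched.
    """
    faces = tm.mesh.faces
    if method == "component":
        groups = trimesh.graph.connected_components(
            tm.mesh.to_trimesh().face_adjacency, nodes=np.arange(len(faces)))
        if len(groups) <= 1:
            warnings.warn("nothing removed: mesh has one component",
                          stacklevel=2)
            return tm, {"faces_removed": 0, "boundary_edges": 0}
        best = max(groups, key=lambda g: (len(g), -int(faces[g].min())))
        keep = np.sort(best)
    elif method == "cylinder":
        if axis_point is None:
            raise ValueError("cylinder method needs axis_point")
        a = np.asarray(axis_point, float)
        d = np.asarray(axis_dir, float)
        d = d / np.linalg.norm(d)
        cen = tm.mesh.face_centroids()
        rel = cen - a
        radial = rel - np.outer(rel @ d, d)
        inside = np.linalg.norm(radial, axis=1) <= radius_mm
        if not inside.any():
            warnings.warn("nothing removed: no faces in cylinder",
                          stacklevel=2)
            return tm, {"faces_removed": 0, "boundary_edges": 0}
        keep = np.flatnonzero(~inside)
        sub = tm.subset_faces(keep)
        groups = trimesh.graph.connected_components(
            sub.mesh.to_trimesh().face_adjacency,
            nodes=np.arange(len(keep)))
        if len(groups) > 1:
            best = max(groups,
                       key=lambda g: (len(g), -int(sub.mesh.faces[g].min())))
            keep = keep[np.sort(best)]
    else:
        raise ValueError(f"unknown pin-removal method {method!r}")
    removed = len(faces) - len(keep)
    out = tm.subset_faces(keep)
    return out, {"faces_removed": removed,
                 "boundary_edges": _boundary_edge_count(out.mesh.faces)}


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def _as_textured(mesh_or_tm) -> TexturedMesh:
    if isinstance(mesh_or_tm, TexturedMesh):
        return mesh_or_tm
    mesh = mesh_or_tm
    n = len(mesh.faces)
    return TexturedMesh(mesh, np.full((4, 4, 3), 255, np.uint8),
                        np.zeros((n, 3, 2)), np.full(n, UNSEEN, np.int64))


def export_mesh(tm, path, fmt: str | None = None) -> list[Path]:
    """Write a (textured) mesh to OBJ, PLY, STL or X3D.

    OBJ carries the atlas via MTL + PNG and per-corner ``vt`` records;
    PLY is binary little-endian and STL binary (both geometry-only by
    format semantics here); X3D wraps an IndexedFaceSet with an
    ImageTexture.  Returns the list of files written.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    tm = _as_textured(tm)
    mesh = tm.mesh
    if fmt == "obj":
        return _export_obj(tm, path)
    if fmt == "ply":
        data = mesh.to_trimesh().export(file_type="ply", encoding="binary")
        path.write_bytes(data)
        return [path]
    if fmt == "stl":
        data = mesh.to_trimesh().export(file_type="stl")
        path.write_bytes(data)
        return [path]
    if fmt == "x3d":
        return _export_x3d(tm, path)
    raise UnsupportedFormatError(f"unsupported format {fmt!r}")


def _export_obj(tm: TexturedMesh, path: Path) -> list[Path]:
    mtl_path = path.with_suffix(".mtl")
    png_path = path.with_suffix(".png")
    Image.fromarray(tm.atlas).save(png_path)
    mtl_path.write_text(
        "newmtl atlas\nKa 1 1 1\nKd 1 1 1\n"
        f"map_Kd {png_path.name}\n")
    lines = [f"mtllib {mtl_path.name}", "usemtl atlas"]
    for v in tm.mesh.vertices:
        lines.append(f"v {v[0]:.8f} {v[1]:.8f} {v[2]:.8f}")
    for f in range(len(tm.mesh.faces)):
        for k in range(3):
            u, vv = tm.face_uv[f, k]
            lines.append(f"vt {u:.8f} {1.0 - vv:.8f}")
    for f, face in enumerate(tm.mesh.faces):
        t = 3 * f
        lines.append(f"f {face[0]+1}/{t+1} {face[1]+1}/{t+2} "
                     f"{face[2]+1}/{t+3}")
    path.write_text("\n".join(lines) + "\n")
    return [path, mtl_path, png_path]


def load_obj(path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Minimal OBJ reader: returns (vertices, faces, face_uv or None)."""
    verts, uvs, faces, face_uv = [], [], [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "vt":
            uvs.append([float(x) for x in parts[1:3]])
        elif parts[0] == "f":
            vi, ti = [], []
            for tok in parts[1:4]:
                sub = tok.split("/")
                vi.append(int(sub[0]) - 1)
                if len(sub) > 1 and sub[1]:
                    ti.append(int(sub[1]) - 1)
            faces.append(vi)
            if len(ti) == 3:
                face_uv.append(ti)
    v = np.asarray(verts, float)
    f = np.asarray(faces, np.int64)
    uv = None
    if face_uv and uvs:
        uvarr = np.asarray(uvs, float)
        uv = uvarr[np.asarray(face_uv)]
        uv[:, :, 1] = 1.0 - uv[:, :, 1]
    return v, f, uv


def _export_x3d(tm: TexturedMesh, path: Path) -> list[Path]:
    png_path = path.with_suffix(".png")
    Image.fromarray(tm.atlas).save(png_path)
    mesh = tm.mesh
    x3d = ET.Element("X3D", profile="Interchange", version="3.3")
    scene = ET.SubElement(x3d, "Scene")
    shape = ET.SubElement(scene, "Shape")
    app = ET.SubElement(shape, "Appearance")
    ET.SubElement(app, "ImageTexture", url=f'"{png_path.name}"')
    coord_index = " ".join(
        " ".join(str(i) for i in f) + " -1" for f in mesh.faces)
    tex_index = " ".join(
        " ".join(str(3 * f + k) for k in range(3)) + " -1"
        for f in range(len(mesh.faces)))
    ifs = ET.SubElement(shape, "IndexedFaceSet", solid="false",
                        coordIndex=coord_index, texCoordIndex=tex_index)
    ET.SubElement(ifs, "Coordinate", point=" ".join(
        f"{x:.6f}" for x in mesh.vertices.ravel()))
    ET.SubElement(ifs, "TextureCoordinate", point=" ".join(
        f"{u:.6f} {1.0 - v:.6f}" for uvtri in tm.face_uv
        for (u, v) in uvtri))
    tree = ET.ElementTree(x3d)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
    return [path, png_path]
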