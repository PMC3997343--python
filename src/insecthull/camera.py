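"""Camera model, turntable kinematics and fiducial-mat pose estimation.

Conventions (used everywhere in the package):

* World frame: right-handed, specimen-centred, ``+Z`` up along the pin axis.
  All lengths are in millimetres; angles are degrees at API boundaries and
  radians internally.
* Camera frame: ``x_cam = R @ x_world + t`` with ``+z`` forward (into the
  scene), ``+x`` image-right, ``+y`` image-down.  Pixels: origin top-left,
  ``u = f * x/z + cx``, ``v = f * y/z + cy``.
* The rig camera sits on the world ``+X`` axis at the configured distance and
  looks at the origin; turntable pan rotates the specimen about ``+Z``,
  tilt about ``+Y`` (positive tilt leans the specimen's top toward the
  camera).  A capture at pan/tilt is therefore equivalent to a virtual
  camera whose extrinsics compose the fixed rig pose with the inverse
  specimen rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from insecthull.errors import DegenerateConfigurationError, InsufficientMarkersError

__all__ = [
    "CameraIntrinsics",
    "RigidPose",
    "TurntableState",
    "RigGeometry",
    "CameraView",
    "FiducialMatSpec",
    "pose_from_turntable",
    "project_point",
    "project_points",
    "detect_fiducial_markers",
    "estimate_pose_from_mat",
    "refine_poses",
    "save_pose_table",
    "load_pose_table",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: square pixels, no distortion.

    Parameters
    ----------
    focal_length_px : float
        Focal length expressed in pixels (``f = f_mm / pixel_pitch_mm``).
    principal_point : tuple of float
        ``(cx, cy)`` in pixels, inside the image.
    image_size : tuple of int
        ``(width, height)`` in pixels.
    """

    focal_length_px: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]

    def __post_init__(self):
        f = float(self.focal_length_px)
        if not math.isfinite(f) or f <= 0:
            raise ValueError("focal_length_px must be finite and positive")
        w, h = self.image_size
        cx, cy = self.principal_point
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("principal_point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 calibration matrix K."""
        f = self.focal_length_px
        cx, cy = self.principal_point
        return np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class RigidPose:
    """World-to-camera rigid transform: ``x_cam = R @ x_world + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must have det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def camera_center(self) -> np.ndarray:
        """Camera centre in world coordinates, ``C = -R^T t``."""
        return -self.rotation.T @ self.translation

    @property
    def matrix_3x4(self) -> np.ndarray:
        return np.hstack([self.rotation, self.translation.reshape(3, 1)])

    def compose_world_rotation(self, R_world: np.ndarray) -> "RigidPose":
        """Pose seen after the world (specimen) is rotated by ``R_world``."""
        return RigidPose(self.rotation @ R_world, self.translation)


@dataclass(frozen=True)
class TurntableState:
    """One turntable setting: pan in [0, 360), tilt in [-90, 90], distance mm."""

    pan_deg: float
    tilt_deg: float
    camera_distance_mm: float

    def __post_init__(self):
        if not (0.0 <= self.pan_deg % 360.0 < 360.0):
            raise ValueError("pan_deg must be finite")
        if not (-90.0 <= self.tilt_deg <= 90.0):
            raise ValueError("tilt_deg must lie in [-90, 90]")
        if self.camera_distance_mm <= 0:
            raise ValueError("camera_distance_mm must be positive")


@dataclass(frozen=True)
class RigGeometry:
    """Fixed rig: camera on the +X axis looking at the origin."""

    camera_distance_mm: float = 150.0

    @property
    def base_pose(self) -> RigidPose:
        # rows = camera axes expressed in world coords:
        # image-right = +Y_w, image-down = -Z_w, forward = -X_w
        R0 = np.array([[0.0, 1.0, 0.0],
                       [0.0, 0.0, -1.0],
                       [-1.0, 0.0, 0.0]])
        C0 = np.array([self.camera_distance_mm, 0.0, 0.0])
        return RigidPose(R0, -R0 @ C0)


@dataclass(frozen=True)
class CameraView:
    """Calibrated view: intrinsics + pose, with an id for provenance."""

    view_id: int
    intrinsics: CameraIntrinsics
    pose: RigidPose


@dataclass(frozen=True)
class FiducialMatSpec:
    """Printed calibration mat: a ring of colour-coded circular dots.

    ``marker_count`` dots of diameter ``marker_diameter_mm`` are evenly
    spaced on a circle of diameter ``ring_diameter_mm`` in the mat plane
    (world ``Z = 0``), marker ``i`` at angle ``2*pi*i/marker_count`` from
    ``+X``.  Each marker carries a 6-bit id code rendered as its fill
    colour: two bits per RGB channel select one of four intensity levels,
    so ids survive any viewing angle without decoding a perspective-warped
    pattern.
    """

    ring_diameter_mm: float = 40.0
    marker_count: int = 12
    marker_diameter_mm: float = 3.0
    id_coding: tuple[int, ...] = field(default=None)

    _LEVELS = (40, 100, 160, 220)

    def __post_init__(self):
        if self.marker_count < 4:
            raise ValueError("marker_count must be >= 4")
        if self.id_coding is None:
            object.__setattr__(self, "id_coding",
                               tuple(range(1, self.marker_count + 1)))
        codes = tuple(int(c) for c in self.id_coding)
        if len(codes) != self.marker_count or len(set(codes)) != len(codes):
            raise ValueError("id_coding must give one distinct code per marker")
        if any(not (0 <= c < 64) for c in codes):
            raise ValueError("codes must fit in 6 bits")
        object.__setattr__(self, "id_coding", codes)

    def marker_positions(self) -> np.ndarray:
        """(N, 3) marker centres in world mm, on the Z=0 mat plane."""
        ang = 2.0 * np.pi * np.arange(self.marker_count) / self.marker_count
        r = self.ring_diameter_mm / 2.0
        return np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                np.zeros(self.marker_count)])

    def code_colour(self, code: int) -> tuple[int, int, int]:
        """RGB colour encoding a 6-bit id code (2 bits per channel)."""
        lv = self._LEVELS
        return (lv[(code >> 4) & 3], lv[(code >> 2) & 3], lv[code & 3])

    def marker_colours(self) -> np.ndarray:
        return np.array([self.code_colour(c) for c in self.id_coding],
                        dtype=np.uint8)

    def decode_colour(self, rgb) -> int | None:
        """Nearest-level decode of an observed mean marker colour."""
        lv = np.asarray(self._LEVELS, dtype=float)
        bits = []
        for ch in rgb:
            d = np.abs(lv - float(ch))
            if d.min() > 28.0:       # half the inter-level gap: reject junk
                return None
            bits.append(int(np.argmin(d)))
        code = (bits[0] << 4) | (bits[1] << 2) | bits[2]
        return code if code in self.id_coding else None


# ---------------------------------------------------------------------------
# Turntable kinematics and projection
# ---------------------------------------------------------------------------

def _rot_z(rad: float) -> np.ndarray:
    c, s = math.cos(rad), math.sin(rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(rad: float) -> np.ndarray:
    c, s = math.cos(rad), math.sin(rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def specimen_rotation(pan_deg: float, tilt_deg: float) -> np.ndarray:
    """Rotation the two-axis turntable applies to the specimen.

    Pan spins the specimen about its vertical ``+Z`` axis; the pan stage
    itself tilts about the horizontal ``+Y`` axis (perpendicular to the
    camera direction), so ``R = R_y(tilt) @ R_z(pan)``.
    """
    return _rot_y(math.radians(tilt_deg)) @ _rot_z(math.radians(pan_deg))


def pose_from_turntable(state: TurntableState,
                        rig: RigGeometry | None = None) -> RigidPose:
    """Virtual camera pose equivalent to a turntable setting.

    Rotating the specimen by ``R_s`` under a fixed camera is the same as
    leaving the specimen alone and moving the camera by the inverse
    rotation; the returned extrinsics are the fixed rig pose composed with
    the specimen rotation.
    """
    if rig is None:
        rig = RigGeometry(camera_distance_mm=state.camera_distance_mm)
    Rs = specimen_rotation(state.pan_deg, state.tilt_deg)
    return rig.base_pose.compose_world_rotation(Rs)


def project_points(points: np.ndarray, intr: CameraIntrinsics,
                   pose: RigidPose) -> tuple[np.ndarray, np.ndarray]:
    """Pinhole-project (N, 3) world points.

    Returns ``(uv, in_front)``: (N, 2) pixel coordinates and a boolean
    mask that is False where the camera-frame depth is <= 0 (the pixel
    coordinates there are meaningless).
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    cam = p @ pose.rotation.T + pose.translation
    z = cam[:, 2]
    in_front = z > 0
    zs = np.where(in_front, z, 1.0)
    f = intr.focal_length_px
    cx, cy = intr.principal_point
    uv = np.column_stack([f * cam[:, 0] / zs + cx, f * cam[:, 1] / zs + cy])
    return uv, in_front


def project_point(point, intr: CameraIntrinsics,
                  pose: RigidPose) -> tuple[np.ndarray | None, bool]:
    """Project one world point; returns ``(uv, behind_camera)``."""
    uv, in_front = project_points(np.asarray(point, float).reshape(1, 3),
                                  intr, pose)
    if not in_front[0]:
        return None, True
    return uv[0], False


# ---------------------------------------------------------------------------
# Fiducial detection
# ---------------------------------------------------------------------------

def detect_fiducial_markers(image: np.ndarray, spec: FiducialMatSpec,
                            min_area_px: int = 12,
                            colour_tol: float = 35.0) -> list[tuple[int, np.ndarray]]:
    """Find and identify mat dots in a colour image.

    Pixels within ``colour_tol`` (Euclidean RGB) of any marker code colour
    are segmented into connected components; each sufficiently large
    component is decoded from its mean colour and reported with its
    sub-pixel centroid ``(u, v)``.

    Raises
    ------
    InsufficientMarkersError
        When fewer than four distinct markers are identified.
    """
    from scipy import ndimage

    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    colours = spec.marker_colours().astype(float)          # (M, 3)
    d2 = ((img[:, :, None, :] - colours[None, None, :, :]) ** 2).sum(-1)
    candidate = d2.min(axis=2) <= colour_tol ** 2

    labels, n = ndimage.label(candidate)
    found: dict[int, tuple[float, np.ndarray]] = {}
    if n:
        areas = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        coms = ndimage.center_of_mass(candidate, labels,
                                      index=np.arange(1, n + 1))
        means = [ndimage.mean(img[:, :, c], labels,
                              index=np.arange(1, n + 1)) for c in range(3)]
        for k in range(n):
            if areas[k] < min_area_px:
                continue
            code = spec.decode_colour([means[c][k] for c in range(3)])
            if code is None:
                continue
            marker_id = spec.id_coding.index(code)
            row, col = coms[k]
            # keep the largest blob per id (spurious speckle protection)
            if marker_id not in found or areas[k] > found[marker_id][0]:
                found[marker_id] = (areas[k], np.array([col, row]))
    if len(found) < 4:
        raise InsufficientMarkersError(
            f"only {len(found)} marker(s) identified; need >= 4")
    return sorted(((mid, uv) for mid, (_, uv) in found.items()),
                  key=lambda m: m[0])


# ---------------------------------------------------------------------------
# Pose from markers (planar PnP)
# ---------------------------------------------------------------------------

def _check_not_collinear(uv: np.ndarray):
    c = uv - uv.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[0] < 1e-12 or s[1] / s[0] < 1e-6:
        raise DegenerateConfigurationError("image markers are collinear")


def _homography_dlt(obj_xy: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Normalized DLT homography mapping mat-plane (x, y) to pixels."""
    def normalize(pts):
        m = pts.mean(axis=0)
        d = np.sqrt(((pts - m) ** 2).sum(axis=1)).mean()
        s = math.sqrt(2) / max(d, 1e-12)
        T = np.array([[s, 0, -s * m[0]], [0, s, -s * m[1]], [0, 0, 1.0]])
        ph = np.column_stack([pts, np.ones(len(pts))]) @ T.T
        return ph[:, :2], T

    x, Tx = normalize(obj_xy)
    u, Tu = normalize(uv)
    rows = []
    for (X, Y), (U, V) in zip(x, u):
        rows.append([-X, -Y, -1, 0, 0, 0, U * X, U * Y, U])
        rows.append([0, 0, 0, -X, -Y, -1, V * X, V * Y, V])
    A = np.asarray(rows)
    _, _, vt = np.linalg.svd(A)
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Tu) @ H @ Tx
    return H / H[2, 2]


def _pose_from_homography(H: np.ndarray, K: np.ndarray) -> RigidPose:
    """Initial pose from a mat-plane homography (Zhang-style decomposition)."""
    B = np.linalg.inv(K) @ H
    lam = (np.linalg.norm(B[:, 0]) + np.linalg.norm(B[:, 1])) / 2.0
    B = B / lam
    if B[2, 2] < 0:  # enforce the mat in front of the camera
        B = -B
    r1, r2, t = B[:, 0], B[:, 1], B[:, 2]
    R_approx = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(R_approx)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return RigidPose(R, t)


def _refine_single(obj: np.ndarray, uv: np.ndarray, intr: CameraIntrinsics,
                   pose0: RigidPose, tol: float = 1e-10,
                   max_iter: int = 100) -> tuple[RigidPose, float]:
    """Nonlinear reprojection refinement; returns (pose, RMS px)."""
    def residual(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        cam = obj @ R.T + x[3:6]
        z = np.clip(cam[:, 2], 1e-9, None)
        f = intr.focal_length_px
        cx, cy = intr.principal_point
        pred = np.column_stack([f * cam[:, 0] / z + cx,
                                f * cam[:, 1] / z + cy])
        return (pred - uv).ravel()

    x0 = np.concatenate([Rotation.from_matrix(pose0.rotation).as_rotvec(),
                         pose0.translation])
    sol = least_squares(residual, x0, method="lm", xtol=tol, ftol=tol,
                        gtol=tol, max_nfev=max_iter * (len(x0) + 1))
    pose = RigidPose(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:6])
    rms = math.sqrt(np.mean((sol.fun.reshape(-1, 2) ** 2).sum(axis=1)))
    return pose, rms


def reprojection_rms(obj: np.ndarray, uv: np.ndarray,
                     intr: CameraIntrinsics, pose: RigidPose) -> float:
    pred, _ = project_points(obj, intr, pose)
    return float(np.sqrt(np.mean(((pred - uv) ** 2).sum(axis=1))))


def estimate_pose_from_mat(markers: list[tuple[int, np.ndarray]],
                           spec: FiducialMatSpec,
                           intr: CameraIntrinsics) -> tuple[RigidPose, float]:
    """Recover the camera pose from >= 4 identified mat markers.

    A direct linear estimate (normalized-DLT homography of the mat plane,
    decomposed with the known intrinsics) is refined by iterative
    reprojection least squares.  Returns ``(pose, rms_px)``.
    """
    if len(markers) < 4:
        raise InsufficientMarkersError(f"need >= 4 markers, got {len(markers)}")
    pos = spec.marker_positions()
    obj = np.array([pos[mid] for mid, _ in markers])
    uv = np.array([np.asarray(p, float) for _, p in markers])
    _check_not_collinear(uv)
    H = _homography_dlt(obj[:, :2], uv)
    pose0 = _pose_from_homography(H, intr.matrix)
    pose, rms = _refine_single(obj, uv, intr, pose0)
    return pose, rms


def refine_poses(views: list[CameraView],
                 markers_per_view: list[list[tuple[int, np.ndarray]]],
                 spec: FiducialMatSpec) -> list[CameraView]:
    """Refine all view poses against fiducial reprojection error.

    Intrinsics and mat geometry are fixed, so the joint objective
    decomposes per view; each pose is re-optimized from its current value
    and kept only if its reprojection RMS does not increase.  With fewer
    than two views (nothing to refine jointly) the input is returned
    unchanged.
    """
    if len(views) < 2:
        return list(views)
    pos = spec.marker_positions()
    out = []
    for view, markers in zip(views, markers_per_view):
        if len(markers) < 4:
            out.append(view)
            continue
        obj = np.array([pos[mid] for mid, _ in markers])
        uv = np.array([np.asarray(p, float) for _, p in markers])
        before = reprojection_rms(obj, uv, view.intrinsics, view.pose)
        try:
            pose, after = _refine_single(obj, uv, view.intrinsics, view.pose)
        except Exception:
            out.append(view)
            continue
        if after <= before:
            out.append(CameraView(view.view_id, view.intrinsics, pose))
        else:
            out.append(view)
    return out


# ---------------------------------------------------------------------------
# Pose table interchange
# ---------------------------------------------------------------------------

def save_pose_table(path, views: list[CameraView]):
    """Plain-text per-view pose table: id then the 3x4 matrix row-major."""
    with open(path, "w") as fh:
        fh.write("# view_id  r11 r12 r13 t1  r21 r22 r23 t2  r31 r32 r33 t3\n")
        for v in views:
            vals = " ".join(f"{x:.12g}" for x in v.pose.matrix_3x4.ravel())
            fh.write(f"{v.view_id} {vals}\n")


def load_pose_table(path, intr: CameraIntrinsics) -> list[CameraView]:
    views = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            vid = int(parts[0])
            m = np.array([float(x) for x in parts[1:13]]).reshape(3, 4)
            views.append(CameraView(vid, intr, RigidPose(m[:, :3], m[:, 3])))
    return views
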