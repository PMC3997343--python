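"""Analytic scene renderer standing in for the physical camera rig.

Scenes are unions of quadric/box primitives (sphere, ellipsoid, cylinder,
box) plus an optional fiducial mat on the ``Z = 0`` plane.  Rendering is
exact ray casting with flat shading — no lighting model — so silhouettes,
colours and depths are analytic ground truth for every downstream stage.
Macro-mode defocus is simulated by depth-binned Gaussian blur with a
linear circle-of-confusion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from insecthull.camera import CameraView, FiducialMatSpec
from insecthull.errors import OverlappingPrimitivesError

__all__ = [
    "Primitive",
    "SyntheticScene",
    "DefocusModel",
    "render_view",
    "render_focus_stack",
    "analytic_volume",
    "synthetic_weevil",
]

_INF = np.inf


@dataclass(frozen=True)
class Primitive:
    """One analytic solid.

    ``size`` semantics by shape: sphere ``(r,)``; ellipsoid semi-axes
    ``(a, b, c)``; cylinder ``(radius, half_length)`` along local ``+z``;
    box half-extents ``(hx, hy, hz)``.  ``colour2``/``split_axis`` give a
    two-tone material: points with ``dot(p_local, split_axis) >= 0`` take
    ``colour``, the rest ``colour2`` (used for texture-recovery oracles).
    """

    shape: str
    size: tuple
    centre: tuple = (0.0, 0.0, 0.0)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    colour: tuple = (200, 60, 40)
    colour2: tuple | None = None
    split_axis: tuple | None = None

    def __post_init__(self):
        if self.shape not in ("sphere", "ellipsoid", "cylinder", "box"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(s <= 0 for s in self.size):
            raise ValueError("primitive sizes must be positive")
        if not all(0 <= c <= 255 for c in self.colour):
            raise ValueError("colour channels must lie in [0, 255]")
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=float))

    # ---- geometry helpers -------------------------------------------------

    def volume(self) -> float:
        s = self.size
        if self.shape == "sphere":
            return 4.0 / 3.0 * np.pi * s[0] ** 3
        if self.shape == "ellipsoid":
            return 4.0 / 3.0 * np.pi * s[0] * s[1] * s[2]
        if self.shape == "cylinder":
            return np.pi * s[0] ** 2 * (2.0 * s[1])
        return 8.0 * s[0] * s[1] * s[2]

    def bounding_radius(self) -> float:
        s = self.size
        if self.shape == "sphere":
            return s[0]
        if self.shape == "ellipsoid":
            return max(s)
        if self.shape == "cylinder":
            return float(np.hypot(s[0], s[1]))
        return float(np.linalg.norm(s))

    def aabb(self) -> tuple[np.ndarray, np.ndarray]:
        """Tight world-space axis-aligned bounding box."""
        c = np.asarray(self.centre, float)
        R = self.rotation
        s = np.asarray(self.size, float)
        if self.shape == "sphere":
            ext = np.full(3, s[0])
        elif self.shape == "ellipsoid":
            # support function of an ellipsoid along the world axes
            ext = np.sqrt(((R * s[None, :]) ** 2).sum(axis=1))
        elif self.shape == "cylinder":
            axis = R[:, 2]
            ext = s[1] * np.abs(axis) + \
                s[0] * np.sqrt(np.clip(1.0 - axis ** 2, 0.0, None))
        else:
            ext = np.abs(R) @ s
        return c - ext, c + ext

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (N, 3) world points."""
        p = (np.asarray(points, float) - np.asarray(self.centre)) @ self.rotation
        s = self.size
        if self.shape == "sphere":
            return (p ** 2).sum(-1) <= s[0] ** 2
        if self.shape == "ellipsoid":
            return ((p / np.asarray(s)) ** 2).sum(-1) <= 1.0
        if self.shape == "cylinder":
            return (p[:, 0] ** 2 + p[:, 1] ** 2 <= s[0] ** 2) & \
                   (np.abs(p[:, 2]) <= s[1])
        return (np.abs(p) <= np.asarray(s)).all(-1)

    # ---- ray intersection -------------------------------------------------

    def intersect(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Smallest positive ray parameter t per ray, inf where missed."""
        R = self.rotation
        o = (origins - np.asarray(self.centre)) @ R
        d = dirs @ R
        s = self.size
        if self.shape in ("sphere", "ellipsoid"):
            ax = np.asarray(s if self.shape == "ellipsoid" else (s[0],) * 3,
                            float)
            o2, d2 = o / ax, d / ax
            a = (d2 ** 2).sum(-1)
            b = 2.0 * (o2 * d2).sum(-1)
            c = (o2 ** 2).sum(-1) - 1.0
            disc = b * b - 4 * a * c
            ok = disc >= 0
            sq = np.sqrt(np.where(ok, disc, 0.0))
            t1 = (-b - sq) / (2 * a)
            t2 = (-b + sq) / (2 * a)
            t = np.where(t1 > 1e-9, t1, np.where(t2 > 1e-9, t2, _INF))
            return np.where(ok, t, _INF)
        if self.shape == "cylinder":
            r, h = s
            a = d[:, 0] ** 2 + d[:, 1] ** 2
            b = 2 * (o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1])
            c = o[:, 0] ** 2 + o[:, 1] ** 2 - r * r
            disc = b * b - 4 * a * c
            ok = (disc >= 0) & (a > 1e-15)
            sq = np.sqrt(np.where(ok, disc, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = (-b - sq) / (2 * a)
                t2 = (-b + sq) / (2 * a)
            t_side = np.full(len(o), _INF)
            for tc in (t1, t2):
                z = o[:, 2] + tc * d[:, 2]
                good = ok & (tc > 1e-9) & (np.abs(z) <= h)
                t_side = np.where(good & (tc < t_side), tc, t_side)
            # caps at z = +-h
            t_cap = np.full(len(o), _INF)
            with np.errstate(divide="ignore", invalid="ignore"):
                for zc in (-h, h):
                    tc = (zc - o[:, 2]) / d[:, 2]
                    x = o[:, 0] + tc * d[:, 0]
                    y = o[:, 1] + tc * d[:, 1]
                    good = (tc > 1e-9) & (x * x + y * y <= r * r) & \
                        np.isfinite(tc)
                    t_cap = np.where(good & (tc < t_cap), tc, t_cap)
            return np.minimum(t_side, t_cap)
        # box: slab method
        ext = np.asarray(s, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / d
            tlo = (-ext - o) * inv
            thi = (ext - o) * inv
        tmin = np.minimum(tlo, thi).max(axis=1)
        tmax = np.maximum(tlo, thi).min(axis=1)
        hit = (tmax >= tmin) & (tmax > 1e-9)
        t = np.where(tmin > 1e-9, tmin, tmax)
        return np.where(hit, t, _INF)

    def colour_at(self, points_world: np.ndarray) -> np.ndarray:
        """(N, 3) uint8 colours at world surface points (two-tone aware)."""
        n = len(points_world)
        out = np.tile(np.asarray(self.colour, np.uint8), (n, 1))
        if self.colour2 is not None and self.split_axis is not None:
            p = (points_world - np.asarray(self.centre)) @ self.rotation
            neg = p @ np.asarray(self.split_axis, float) < 0
            out[neg] = np.asarray(self.colour2, np.uint8)
        return out


@dataclass(frozen=True)
class SyntheticScene:
    """Primitives + optional fiducial mat + uniform chroma background."""

    primitives: tuple
    mat: FiducialMatSpec | None = None
    background: tuple = (0, 140, 0)          # chroma green

    def __post_init__(self):
        object.__setattr__(self, "primitives", tuple(self.primitives))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        inside = np.zeros(len(pts), dtype=bool)
        for prim in self.primitives:
            inside |= prim.contains(pts)
        return inside

    def bounding_radius(self) -> float:
        r = 0.0
        for p in self.primitives:
            r = max(r, float(np.linalg.norm(p.centre)) + p.bounding_radius())
        return r


@dataclass(frozen=True)
class DefocusModel:
    """Linear circle-of-confusion: blur sigma = gain * |depth - focal plane|.

    ``blur_gain`` is in pixels of Gaussian sigma per millimetre of defocus;
    0 disables defocus entirely.
    """

    focal_plane_mm: float
    blur_gain: float = 4.0

    def __post_init__(self):
        if self.blur_gain < 0:
            raise ValueError("blur_gain must be >= 0")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _mat_pattern_colour(xy: np.ndarray, spec: FiducialMatSpec) -> np.ndarray:
    """Colour of the printed mat at (N, 2) mat-plane coordinates (mm)."""
    n = len(xy)
    out = np.full((n, 3), 245, dtype=np.uint8)       # near-white card
    centres = spec.marker_positions()[:, :2]
    colours = spec.marker_colours()
    r2 = (spec.marker_diameter_mm / 2.0) ** 2
    for c, col in zip(centres, colours):
        hit = ((xy - c) ** 2).sum(-1) <= r2
        out[hit] = col
    return out


def render_view(scene: SyntheticScene, view: CameraView,
                size: tuple[int, int] | None = None):
    """Ray-cast one calibrated view.

    Returns ``(image, matte, depth)``: uint8 RGB image, boolean foreground
    matte (primitives only, mat excluded), and per-pixel camera-frame depth
    in mm (inf where nothing is hit).
    """
    intr = view.intrinsics
    w, h = size if size is not None else intr.image_size
    pose = view.pose
    C = pose.camera_center
    f = intr.focal_length_px
    cx, cy = intr.principal_point

    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    dirs_cam = np.stack([(u - cx) / f, (v - cy) / f, np.ones_like(u)], axis=-1)
    dirs = dirs_cam.reshape(-1, 3) @ pose.rotation          # R^T applied rowwise
    origins = np.broadcast_to(C, dirs.shape)

    n = dirs.shape[0]
    t_best = np.full(n, _INF)
    idx_best = np.full(n, -1, dtype=int)
    for i, prim in enumerate(scene.primitives):
        t = prim.intersect(origins, dirs)
        closer = t < t_best
        t_best = np.where(closer, t, t_best)
        idx_best = np.where(closer, i, idx_best)

    # fiducial mat on the Z=0 plane (rendered, but not part of the matte)
    t_mat = np.full(n, _INF)
    if scene.mat is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            tm = -C[2] / dirs[:, 2]
        mat_radius = scene.mat.ring_diameter_mm / 2.0 \
            + 1.5 * scene.mat.marker_diameter_mm
        xy = C[:2] + tm[:, None] * dirs[:, :2]
        on_mat = (tm > 1e-9) & np.isfinite(tm) & \
            ((xy ** 2).sum(-1) <= mat_radius ** 2)
        t_mat = np.where(on_mat, tm, _INF)

    image = np.tile(np.asarray(scene.background, np.uint8), (n, 1))
    matte = (idx_best >= 0) & (t_best < t_mat)
    for i, prim in enumerate(scene.primitives):
        sel = matte & (idx_best == i)
        if sel.any():
            pts = origins[sel] + t_best[sel, None] * dirs[sel]
            image[sel] = prim.colour_at(pts)
    if scene.mat is not None:
        sel = (t_mat < t_best)
        if sel.any():
            xy_hit = C[:2] + t_mat[sel, None] * dirs[sel, :2]
            image[sel] = _mat_pattern_colour(xy_hit, scene.mat)

    t_vis = np.minimum(t_best, t_mat)
    # camera-frame z depth = t * z-component of the unit-z-normalized ray
    depth = t_vis * dirs_cam.reshape(-1, 3)[:, 2]

    return (image.reshape(h, w, 3), matte.reshape(h, w),
            depth.reshape(h, w))


def render_focus_stack(scene: SyntheticScene, view: CameraView,
                       defocus_positions, blur_gain: float = 4.0,
                       depth_bins: int = 16):
    """Simulate a macro-rail focus sweep.

    For each focal-plane depth a frame is produced by blurring the sharp
    render with per-pixel Gaussian sigma ``blur_gain * |depth - plane|``,
    approximated by quantizing depth into ``depth_bins`` uniform bins and
    blurring once per bin.  Background pixels (no depth) are treated as
    lying on the focal plane, so the uniform backdrop stays unblurred.

    Returns ``(frames, sharp, depth)`` where ``frames`` is a list of uint8
    images ordered like ``defocus_positions``.
    """
    positions = [float(p) for p in defocus_positions]
    if len(positions) < 2:
        raise ValueError("need >= 2 focus positions")
    sharp, matte, depth = render_view(scene, view)
    if blur_gain == 0:
        return [sharp.copy() for _ in positions], sharp, depth

    fg = np.isfinite(depth) & matte
    frames = []
    if fg.any():
        dmin, dmax = float(depth[fg].min()), float(depth[fg].max())
    else:
        dmin = dmax = positions[0]
    edges = np.linspace(dmin, dmax, depth_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    bin_of = np.clip(np.digitize(depth, edges) - 1, 0, depth_bins - 1)
    sharp_f = sharp.astype(float)
    for plane in positions:
        out = sharp_f.copy()
        for b in range(depth_bins):
            mask = fg & (bin_of == b)
            if not mask.any():
                continue
            sigma = blur_gain * abs(centres[b] - plane)
            if sigma < 0.05:
                continue
            blurred = gaussian_filter(sharp_f, sigma=(sigma, sigma, 0))
            out[mask] = blurred[mask]
        frames.append(np.clip(np.round(out), 0, 255).astype(np.uint8))
    return frames, sharp, depth


# ---------------------------------------------------------------------------
# Analytic oracle and stock scenes
# ---------------------------------------------------------------------------

def analytic_volume(scene: SyntheticScene) -> float:
    """Closed-form total volume (mm^3) of a scene of disjoint primitives.

    Disjointness is enforced conservatively through bounding boxes;
    overlapping boxes raise ``OverlappingPrimitivesError``.
    """
    prims = scene.primitives
    for i in range(len(prims)):
        lo_i, hi_i = prims[i].aabb()
        for j in range(i + 1, len(prims)):
            lo_j, hi_j = prims[j].aabb()
            if (lo_i < hi_j).all() and (lo_j < hi_i).all():
                raise OverlappingPrimitivesError(
                    f"primitives {i} and {j} have overlapping bounds")
    return float(sum(p.volume() for p in prims))


def synthetic_weevil(with_pin: bool = True,
                     pin_attached: bool = False) -> SyntheticScene:
    """Stock test specimen: a ~3 mm weevil-like body on a mounting pin.

    Ellipsoid abdomen, sphere head, six thin cylinder legs, and a 0.2 mm
    diameter vertical pin below the body — proportions of the smallest
    specimens this class of rig targets.  With ``pin_attached`` the pin
    penetrates the body (one fused hull component, so ``analytic_volume``
    refuses the scene); otherwise a small gap leaves the pin as a separate
    hull component and all primitives are disjoint.
    """
    body = Primitive("ellipsoid", (1.5, 0.9, 0.8), centre=(0, 0, 1.2),
                     colour=(140, 90, 40))
    head = Primitive("sphere", (0.5,), centre=(2.35, 0, 1.35),
                     colour=(110, 70, 35))
    legs = []
    tilt = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)  # z->y
    for i, x in enumerate((-1.0, 0.0, 1.0)):
        for sy in (-1.6, 1.6):
            legs.append(Primitive("cylinder", (0.09, 0.55),
                                  centre=(x, sy, 1.0),
                                  rotation=tilt, colour=(60, 40, 20)))
    prims = [body, head] + legs
    if with_pin:
        # body lower surface sits at z = 0.4
        pin_top = 0.7 if pin_attached else 0.15
        pin = Primitive("cylinder", (0.1, (pin_top + 2.6) / 2.0),
                        centre=(0, 0, (pin_top - 2.6) / 2.0),
                        colour=(180, 180, 185))
        prims.append(pin)
    return SyntheticScene(tuple(prims))
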