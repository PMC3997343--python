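"""Shared fixtures: small calibrated synthetic scenes with ground truth."""

import pytest

from insecthull.camera import (
    CameraIntrinsics,
    CameraView,
    TurntableState,
    pose_from_turntable,
)
from insecthull.render import Primitive, SyntheticScene, render_view
from insecthull.silhouette import SilhouetteMask


@pytest.fixture(scope="session")
def intrinsics_240():
    # 4800 px focal at 300 mm keeps a 10 mm specimen well inside frame
    return CameraIntrinsics(4800.0, (120.0, 120.0), (240, 240))


def ring_views(intr, pan_steps, tilts, distance=300.0):
    """Turntable view set: pan_steps uniform pans at each tilt."""
    views = []
    i = 0
    for tilt in tilts:
        for k in range(pan_steps):
            st = TurntableState(360.0 * k / pan_steps, tilt, distance)
            views.append(CameraView(i, intr, pose_from_turntable(st)))
            i += 1
    return views


def render_mattes(scene, views):
    """Exact silhouettes and images for a view set."""
    masks, images = [], []
    for v in views:
        img, matte, _ = render_view(scene, v)
        masks.append(SilhouetteMask(matte, view_id=v.view_id))
        images.append(img)
    return masks, images


@pytest.fixture(scope="session")
def sphere_scene():
    return SyntheticScene((Primitive("sphere", (5.0,)),))


@pytest.fixture(scope="session")
def two_tone_sphere_scene():
    sph = Primitive("sphere", (5.0,), colour=(220, 40, 40),
                    colour2=(40, 40, 220), split_axis=(0.0, 0.0, 1.0))
    return SyntheticScene((sph,))


@pytest.fixture(scope="session")
def sphere_views_18(intrinsics_240, sphere_scene):
    """18 views (6 pan x 3 tilt) of the plain sphere, with exact mattes."""
    views = ring_views(intrinsics_240, 6, (-40.0, 0.0, 40.0))
    masks, images = render_mattes(sphere_scene, views)
    return views, masks, images
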