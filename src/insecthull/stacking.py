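"""Extended depth of field: collapse a multi-focus stack into one image.

Macro lenses have sub-millimetre depth of focus, so each view of a small
specimen is captured as an ordered stack of partially focused frames (the
camera stepped along the optical axis).  Per pixel we score sharpness as
the local variance of the Laplacian of luminance, pick the sharpest frame
(argmax, ties to the lower index), median-smooth the index map, and
hard-select colours from the winning frames — a simple, colour-conserving
alternative to commercial stacking software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FocusStack", "DepthIndexMap", "sharpness_map", "select_depth",
           "composite"]

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FocusStack:
    """Ordered partially-focused frames of one view.

    ``frames``: equal-size uint8 RGB rasters; ``focus_mm``: strictly
    increasing focus distances, one per frame.
    """

    frames: tuple
    focus_mm: tuple

    def __post_init__(self):
        frames = tuple(np.asarray(f) for f in self.frames)
        if len(frames) != len(self.focus_mm) or not frames:
            raise ValueError("need one focus distance per frame, >= 1 frame")
        shape = frames[0].shape
        if any(f.shape != shape for f in frames):
            raise ValueError("all frames must share dimensions")
        if len(self.focus_mm) > 1 and not (np.diff(self.focus_mm) > 0).all():
            raise ValueError("focus distances must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "focus_mm",
                           tuple(float(x) for x in self.focus_mm))

    def __len__(self):
        return len(self.frames)


@dataclass(frozen=True)
class DepthIndexMap:
    """Per-pixel winning frame index plus its sharpness score."""

    index: np.ndarray
    confidence: np.ndarray

    def __post_init__(self):
        if self.index.shape != self.confidence.shape:
            raise ValueError("index and confidence must share shape")


def _luminance(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    return img[..., :3] @ _LUMA


def sharpness_map(image: np.ndarray, window: int = 9) -> np.ndarray:
    """Local variance of the Laplacian of luminance.

    High where fine detail is resolved, ~0 in defocused or textureless
    regions; always non-negative.  ``window`` is the odd box size (px) of
    the local variance.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    lap = ndimage.laplace(_luminance(image), mode="nearest")
    mean = ndimage.uniform_filter(lap, size=window, mode="nearest")
    mean_sq = ndimage.uniform_filter(lap * lap, size=window, mode="nearest")
    return np.clip(mean_sq - mean * mean, 0.0, None)


def select_depth(stack: FocusStack, window: int = 9,
                 smoothing_radius: int = 5) -> DepthIndexMap:
    """Choose the sharpest frame per pixel.

    Argmax of sharpness across the stack (ties to the lower index),
    median-filtered with the given radius so isolated misselections in
    low-texture areas inherit their neighbourhood's index.
    """
    if len(stack) < 2:
        raise ValueError("need >= 2 frames to select depth")
    sharp = np.stack([sharpness_map(f, window) for f in stack.frames])
    idx = np.argmax(sharp, axis=0)          # ties break to the lower index
    conf = np.take_along_axis(sharp, idx[None], axis=0)[0]
    if smoothing_radius > 0:
        idx = ndimage.median_filter(idx, size=2 * smoothing_radius + 1,
                                    mode="nearest")
    return DepthIndexMap(idx.astype(np.int32), conf)


def composite(stack: FocusStack, depth: DepthIndexMap) -> np.ndarray:
    """All-in-focus image by hard per-pixel selection from the stack."""
    frames = np.stack(stack.frames)
    if depth.index.shape != frames.shape[1:3]:
        raise ValueError("depth map dimensions do not match the frames")
    idx = depth.index
    if frames.ndim == 4:
        return np.take_along_axis(
            frames, idx[None, :, :, None], axis=0)[0]
    return np.take_along_axis(frames, idx[None], axis=0)[0]


def stack_view(frames, focus_mm, window: int = 9,
               smoothing_radius: int = 5):
    """Convenience: build the stack, select depth, composite.

    A single-frame stack is already all-in-focus and is returned as-is.
    Returns ``(image, DepthIndexMap | None)``.
    """
    stack = FocusStack(tuple(frames), tuple(focus_mm))
    if len(stack) == 1:
        return stack.frames[0], None
    depth = select_depth(stack, window=window,
                         smoothing_radius=smoothing_radius)
    return composite(stack, depth), depth
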