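"""Per-view foreground silhouette extraction.

Segmentation is chroma-key style: pixels whose normalized RGB distance
from the background model (a uniform key colour, or a per-pixel reference
background image of the empty rig) exceeds a threshold are foreground.
A morphological close bridges thin gaps, specks below a size floor are
dropped, and the largest connected component (with anything the close
merged into it) is kept.  Pin/adhesive artifacts can be excluded in 2D by
polygon masking before reconstruction — the quick pin-removal route,
which trades a clean hull for possible texture contamination where the
pin crossed the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.morphology import closing, dilation, disk

from insecthull.errors import EmptySilhouetteError

__all__ = ["SilhouetteMask", "extract_silhouette", "apply_exclusions"]


@dataclass(frozen=True)
class SilhouetteMask:
    """Binary foreground mask for one view.

    ``exclusions`` records the 2D polygons (lists of (x, y) pixel
    vertices) forced to background after extraction.
    """

    mask: np.ndarray
    view_id: int = -1
    exclusions: tuple = field(default_factory=tuple)

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.dtype != bool:
            if not np.isin(np.unique(m), (0, 1)).all():
                raise ValueError("mask values must be 0/1")
            m = m.astype(bool)
        object.__setattr__(self, "mask", m)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def extract_silhouette(image: np.ndarray,
                       background=(0, 140, 0),
                       threshold: float = 0.12,
                       min_blob_px: int = 16,
                       close_px: int = 3,
                       dilate_px: int = 0,
                       keep_components: str = "largest",
                       view_id: int = -1) -> SilhouetteMask:
    """Segment the specimen from a chroma or reference background.

    ``background`` is either an RGB triple (uniform key colour) or an
    image of the empty scene with the same shape as ``image``; distances
    are Euclidean in RGB normalized to [0, 1] and compared against
    ``threshold``.  ``dilate_px`` optionally grows the final mask — used
    before carving so silhouette errors inflate rather than truncate the
    hull.  ``keep_components``: "largest" retains the biggest connected
    blob (with whatever the morphological close merged into it);
    "all" retains every blob above the size floor — needed when distinct
    specimen parts (head, legs, pin) project as separate 2D regions,
    since a view whose mask omits a part would carve that part away.

    Raises ``EmptySilhouetteError`` when no foreground survives.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    img = np.asarray(image, dtype=float) / 255.0
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 1:
        bg = bg[None, None, :]
    bg = bg / 255.0
    dist = np.sqrt(((img[..., :3] - bg[..., :3]) ** 2).sum(-1))
    fg = dist > threshold
    if close_px > 0:
        fg = closing(fg, disk(close_px))
    labels, n = ndimage.label(fg)
    if n == 0:
        raise EmptySilhouetteError("no foreground pixels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_blob_px) + 1
    if keep.size == 0:
        raise EmptySilhouetteError(
            f"all components smaller than {min_blob_px} px")
    if keep_components == "all":
        mask = np.isin(labels, keep)
    elif keep_components == "largest":
        largest = keep[np.argmax(sizes[keep - 1])]
        mask = labels == largest
    else:
        raise ValueError("keep_components must be 'largest' or 'all'")
    if dilate_px > 0:
        mask = dilation(mask, disk(dilate_px))
    return SilhouetteMask(mask, view_id=view_id)


def apply_exclusions(sil: SilhouetteMask, polygons) -> SilhouetteMask:
    """Force polygon interiors to background.

    ``polygons``: iterable of (N, 2) arrays of (x, y) pixel vertices.
    The excluded regions are recorded on the returned mask.
    """
    polys = [np.asarray(p, dtype=float).reshape(-1, 2) for p in polygons]
    if not polys:
        return sil
    mask = sil.mask.copy()
    h, w = mask.shape
    for poly in polys:
        if (poly[:, 0] < 0).any() or (poly[:, 0] > w).any() or \
           (poly[:, 1] < 0).any() or (poly[:, 1] > h).any():
            raise ValueError("exclusion polygon outside image bounds")
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=mask.shape)
        mask[rr, cc] = False
    return SilhouetteMask(mask, view_id=sil.view_id,
                          exclusions=sil.exclusions + tuple(
                              tuple(map(tuple, p)) for p in polys))
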