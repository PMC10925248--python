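"""Corneal-reflection (glint) detection and the pupil-CR vector.

Glints are small bright blobs; their sub-pixel centers are intensity-
weighted centroids.  The pupil-minus-glint vector cancels translations of
camera or head, leaving the rotational gaze signal.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from vogkit.core.types import Glint, Point

_STRUCT8 = np.ones((3, 3), dtype=bool)


def detect_glints(
    image: np.ndarray,
    glint_threshold: int,
    min_size_px2: int = 1,
    max_size_px2: int = 500,
    search_roi: Optional[Tuple[int, int, int, int]] = None,
    max_glints: Optional[int] = None,
    exclude_mask: Optional[np.ndarray] = None,
) -> List[Glint]:
    """Bright 8-connected blobs with peak >= threshold and area in range.

    ``search_roi`` is a half-open (x0, y0, x1, y1) window; ``exclude_mask``
    pixels (e.g. the pupil component) are removed before labeling so glints
    touching the pupil boundary are not merged with it.  Result is sorted by
    descending peak intensity, then descending area, then position.

    Sub-pixel centers are centroids weighted by the intensity *excess* over
    the threshold, which suppresses the quantization bias of the dimmest
    member pixels.
    """
    image = np.asarray(image)
    offset = (0.0, 0.0)
    sub = image
    sub_exclude = exclude_mask
    if search_roi is not None:
        x0, y0, x1, y1 = search_roi
        h, w = image.shape
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
        if x1 <= x0 or y1 <= y0:
            return []
        sub = image[y0:y1, x0:x1]
        if exclude_mask is not None:
            sub_exclude = exclude_mask[y0:y1, x0:x1]
        offset = (float(x0), float(y0))

    mask = sub >= glint_threshold
    if sub_exclude is not None:
        mask &= ~sub_exclude
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return []

    glints: List[Glint] = []
    intensities = sub.astype(float)
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if not (min_size_px2 <= area <= max_size_px2):
            continue
        ys, xs = np.nonzero(comp)
        weights = intensities[ys, xs] - glint_threshold + 1.0
        total = weights.sum()
        cx = float((xs * weights).sum() / total) + offset[0]
        cy = float((ys * weights).sum() / total) + offset[1]
        peak = float(intensities[ys, xs].max())
        glints.append(Glint(Point(cx, cy), area, peak))

    glints.sort(key=lambda g: (-g.peak_intensity, -g.area_px2, g.center.x, g.center.y))
    if max_glints is not None:
        glints = glints[:max_glints]
    return glints


def pupil_cr_vector(
    pupil_center: Optional[Point], glint_center: Optional[Point]
) -> Optional[Point]:
    """Pupil minus glint, in pixels; None if either is absent."""
    if pupil_center is None or glint_center is None:
        return None
    return Point(pupil_center.x - glint_center.x, pupil_center.y - glint_center.y)
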