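"""Digital dual-Purkinje tracking.

P1 (corneal, bright) and P4 (posterior lens surface, much dimmer) are both
small specular spots; their difference vector isolates eye rotation from
translation.  P1 and P4 are disambiguated purely by intensity ordering plus
proximity: frames with two near-equal bright spots (within 10% intensity)
are flagged as ambiguous rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from vogkit.core.types import Glint, Point
from vogkit.glints import detect_glints

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class PurkinjePair:
    p1: Optional[Glint]
    p4: Optional[Glint]
    ambiguous: bool = False

    @property
    def dpi_vector(self) -> Optional[Point]:
        if self.p1 is None or self.p4 is None:
            return None
        return Point(self.p1.center.x - self.p4.center.x,
                     self.p1.center.y - self.p4.center.y)


def detect_purkinje(
    image: np.ndarray,
    p1_threshold: int,
    p4_threshold: int,
    p4_search_radius: float,
    min_size_px2: int = 1,
    max_size_px2: int = 500,
) -> PurkinjePair:
    """Find P1 (brightest qualifying spot) and P4 near it.

    P4 is the brightest spot whose peak lies in [p4_threshold, p1_threshold)
    within ``p4_search_radius`` of P1, excluding P1's own pixels.
    """
    if not p1_threshold > p4_threshold:
        raise ValueError("p1_threshold must exceed p4_threshold")
    image = np.asarray(image)

    p1_candidates = detect_glints(
        image, p1_threshold, min_size_px2, max_size_px2
    )
    if not p1_candidates:
        return PurkinjePair(None, None)
    p1 = p1_candidates[0]
    if (
        len(p1_candidates) > 1
        and p1_candidates[1].peak_intensity >= 0.9 * p1.peak_intensity
    ):
        return PurkinjePair(p1, None, ambiguous=True)

    # Exclude P1's entire skirt down to the P4 threshold: the component of
    # (image >= p4_threshold) containing P1's center.  Otherwise the ring of
    # mid-bright pixels around P1's core shows up as a spurious P4.
    skirt_mask = image >= p4_threshold
    labels, n = ndimage.label(skirt_mask, structure=_STRUCT8)
    exclude = np.zeros_like(skirt_mask)
    if n:
        iy, ix = int(round(p1.center.y)), int(round(p1.center.x))
        iy = min(max(iy, 0), image.shape[0] - 1)
        ix = min(max(ix, 0), image.shape[1] - 1)
        lab = labels[iy, ix]
        if lab:
            exclude = labels == lab

    p4_candidates = detect_glints(
        image, p4_threshold, min_size_px2, max_size_px2, exclude_mask=exclude
    )
    p4 = None
    for cand in p4_candidates:
        if cand.peak_intensity >= p1_threshold:
            continue
        dist = np.hypot(cand.center.x - p1.center.x, cand.center.y - p1.center.y)
        if dist <= p4_search_radius:
            p4 = cand
            break
    return PurkinjePair(p1, p4)


def dpi_signal(pair: PurkinjePair) -> Optional[Point]:
    """(P1 - P4) in pixels; None if either member is absent."""
    return pair.dpi_vector
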