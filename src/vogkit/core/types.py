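"""Domain types shared by every pipeline.

Coordinate conventions
----------------------
Images are 2-D 8-bit grayscale rasters, row-major, origin at the top-left
corner, x rightward (columns), y downward (rows).  Pixel (row i, col j) has
coordinates (x=j, y=i) exactly; sub-pixel results are real valued.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np


class Point(NamedTuple):
    """A sub-pixel image location (x rightward, y downward)."""

    x: float
    y: float

    def __add__(self, other):  # type: ignore[override]
        return Point(self.x + other[0], self.y + other[1])

    def __sub__(self, other):
        return Point(self.x - other[0], self.y - other[1])


class Eye(enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"


class Quality(enum.Enum):
    """Per-row quality flag in the output data file."""

    OK = "ok"
    PUPIL_NOT_FOUND = "pupil_not_found"
    TORSION_LOW_CORRELATION = "torsion_low_correlation"
    DROPPED = "dropped"
    ERROR = "error"


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in image coordinates.

    ``major_axis`` and ``minor_axis`` are full axis lengths (diameters) in
    pixels with ``major_axis >= minor_axis > 0``.  ``angle_deg`` is the angle
    of the major axis measured from +x toward +y, normalized to [0, 180).
    """

    center: Point
    major_axis: float
    minor_axis: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.major_axis > 0 and self.minor_axis > 0):
            raise ValueError("ellipse axes must be positive")
        if self.major_axis < self.minor_axis:
            raise ValueError("major_axis must be >= minor_axis")
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValueError("angle_deg must be normalized to [0, 180)")

    @classmethod
    def from_params(
        cls, cx: float, cy: float, ax1: float, ax2: float, angle_deg: float
    ) -> "Ellipse":
        """Build an ellipse from unordered axes, normalizing the convention."""
        if ax2 > ax1:
            ax1, ax2 = ax2, ax1
            angle_deg += 90.0
        angle_deg = angle_deg % 180.0
        if math.isclose(angle_deg, 180.0, abs_tol=1e-12):
            angle_deg = 0.0
        return cls(
            Point(float(cx), float(cy)), float(ax1), float(ax2), float(angle_deg)
        )

    @property
    def area(self) -> float:
        return math.pi * self.major_axis * self.minor_axis / 4.0


@dataclass
class Frame:
    """One grabbed image plus identity/time metadata."""

    frame_number: int
    timestamp: float
    eye: Eye
    image: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_number < 0:
            raise ValueError("frame_number must be non-negative")
        img = np.asarray(self.image)
        if img.ndim != 2 or img.dtype != np.uint8:
            raise ValueError("image must be a 2-D uint8 array")
        self.image = img


@dataclass
class Glint:
    """A detected corneal reflection."""

    center: Point
    area_px2: int
    peak_intensity: float


@dataclass
class EyeDatum:
    """Per-frame, per-eye tracking result.

    Dropped rows carry no measurements; torsion is present only when a pupil
    was found.  ``h_deg``/``v_deg`` are filled by the calibration stage.
    """

    frame_number: int
    timestamp: float
    eye: Eye
    pupil: Optional[Ellipse] = None
    glints: list = field(default_factory=list)
    torsion_deg: Optional[float] = None
    torsion_peak: Optional[float] = None
    p1: Optional[Point] = None
    p4: Optional[Point] = None
    quality: Quality = Quality.OK
    h_deg: Optional[float] = None
    v_deg: Optional[float] = None

    @property
    def pupil_cr_vector(self) -> Optional[Point]:
        """Pupil minus first glint, or None if either is absent."""
        if self.pupil is None or not self.glints:
            return None
        g = self.glints[0].center
        c = self.pupil.center
        return Point(c.x - g.x, c.y - g.y)

    @property
    def dpi_vector(self) -> Optional[Point]:
        """P1 minus P4, or None if either Purkinje image is absent."""
        if self.p1 is None or self.p4 is None:
            return None
        return Point(self.p1.x - self.p4.x, self.p1.y - self.p4.y)


def dropped_datum(frame_number: int, timestamp: float, eye: Eye) -> EyeDatum:
    return EyeDatum(frame_number, timestamp, eye, quality=Quality.DROPPED)
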