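"""Foot progression angle from contour geometry, and upright rotation.

The foot progression angle (FPA, θ) is the angle between the foot's long
axis and the line of progression.  Here the long axis is approximated from
the enclosing rectangle of the foot contour by two points on its medial
side: t1 at the top edge of the rectangle and t2 = t3 at the bottom-medial
corner.  The line of progression p2 is taken vertical, through
t4 = (t2.x, 0).  With m1 the slope of the axis line p1 and p2 vertical
(its slope m2 is infinite), the two-line angle formula

    tan θ = (m2 − m1) / (1 + m2·m1)

degenerates to the analytic limit tan θ = 1/m1, i.e. the signed angle
between p1 and the vertical axis.  The crop is then rotated by θ about its
center so the axis becomes vertical.

Two constructions of t1's x-coordinate ship:

* ``midpoint`` (default): x1avg = (minxd + maxxd) / 2, the horizontal
  center of the rectangle's top edge — the geometry drawn in the method's
  axis figure.
* ``literal``: x1avg = (medial_x − maxyd) / 2, the formula exactly as
  printed in the source method, kept for fidelity even though it mixes an
  x-extent with a y-extent and can land outside the image.

``minxd`` is the medial side of a RIGHT footprint; for a LEFT foot the
x-relations are mirrored (``maxxd`` is medial), which also mirrors the
angle sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateAxisError
from .foot_segmentation import BoundingBox, FootCrop, FootSide
from .pressuremap_io import PixelClass

__all__ = ["AxisPoints", "Angle", "axis_points", "progression_angle", "rotate_foot"]

AxisMode = Literal["midpoint", "literal"]


@dataclass(frozen=True)
class AxisPoints:
    """The four construction points of the axis lines p1 and p2.

    p1 runs through t1 and t2; p2 through t3 = t2 and t4 = (t2.x, 0),
    hence p2 is vertical.  ``x1avg`` is t1's x-coordinate.
    """

    t1: tuple[float, float]
    t2: tuple[float, float]
    t3: tuple[float, float]
    t4: tuple[float, float]
    x1avg: float


@dataclass(frozen=True)
class Angle:
    """Signed progression angle with the slopes it was derived from.

    ``slope_m2`` is infinite because p2 is vertical by construction.
    Degrees are radians · 180/π; |degrees| < 90 always holds since the
    angle is an arctangent.
    """

    radians: float
    slope_m1: float
    slope_m2: float = math.inf

    @property
    def degrees(self) -> float:
        return math.degrees(self.radians)


def axis_points(
    box: BoundingBox,
    mode: AxisMode = "midpoint",
    side: FootSide = FootSide.RIGHT,
) -> AxisPoints:
    """Construct t1–t4 from the foot's enclosing rectangle.

    The medial x is ``minxd`` for a right foot, ``maxxd`` for a left foot.
    """
    if mode not in ("midpoint", "literal"):
        raise ConfigError(f"unknown axis mode: {mode!r}")
    med_x = float(box.minxd if side is FootSide.RIGHT else box.maxxd)
    if mode == "midpoint":
        x1avg = (box.minxd + box.maxxd) / 2.0
    else:
        x1avg = (med_x - box.maxyd) / 2.0
    t1 = (x1avg, float(box.minyd))
    t2 = (med_x, float(box.maxyd))
    return AxisPoints(t1=t1, t2=t2, t3=t2, t4=(med_x, 0.0), x1avg=x1avg)


def progression_angle(pts: AxisPoints) -> Angle:
    """Signed angle of the axis line p1 against the vertical line p2.

    m1 = (t2.y − t1.y) / (t2.x − t1.x).  Since p2 is vertical, the
    two-line formula reduces to tan θ = 1/m1; a vertical p1 (infinite m1)
    gives θ = 0.  Sign convention: θ > 0 when the bottom point t2 is
    displaced toward +x relative to the top point t1.
    """
    dx = pts.t2[0] - pts.t1[0]
    dy = pts.t2[1] - pts.t1[1]
    if dx == 0.0 and dy == 0.0:
        raise DegenerateAxisError("axis points t1 and t2 coincide")
    if dx == 0.0:
        return Angle(radians=0.0, slope_m1=math.inf)
    m1 = dy / dx  # slope in raster coordinates: Δy/Δx along p1
    theta = math.atan2(dx, dy)  # limit of atan((m2−m1)/(1+m2·m1)) as m2→∞
    return Angle(radians=theta, slope_m1=m1)


def _rotation_grids(shape: tuple[int, int], theta: float):
    """Output shape, index matrix and offset mapping a rotation by θ.

    The transform maps the p1 direction (sin θ, cos θ) onto the vertical
    and expands the canvas so no input pixel is clipped.
    """
    h, w = shape
    c, s = math.cos(theta), math.sin(theta)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # forward map: x' = c·(x−cx) − s·(y−cy), y' = s·(x−cx) + c·(y−cy)
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    rel = corners - [cx, cy]
    fx = c * rel[:, 0] - s * rel[:, 1]
    fy = s * rel[:, 0] + c * rel[:, 1]
    eps = 1e-9  # guard against ceil() inflating exact quarter turns
    out_w = int(math.ceil(fx.max() - fx.min() - eps)) + 1
    out_h = int(math.ceil(fy.max() - fy.min() - eps)) + 1
    cx2, cy2 = (out_w - 1) / 2.0, (out_h - 1) / 2.0
    # inverse map for ndimage: input (y, x) from output (y', x')
    matrix = np.array([[c, -s], [s, c]])  # rows: y, x coefficients on (y', x')
    offset = np.array(
        [cy - c * cy2 + s * cx2, cx - s * cy2 - c * cx2]
    )
    return (out_h, out_w), matrix, offset


def rotate_foot(crop: FootCrop, angle: Angle) -> FootCrop:
    """Rotate the crop by θ about its center so the axis becomes vertical.

    The color image is resampled bilinearly with the background color as
    fill; the class map uses nearest-neighbor so labels never blend.  The
    canvas is expanded to hold every rotated pixel.  θ = 0 returns the
    input unchanged.
    """
    theta = angle.radians
    if theta == 0.0:
        return FootCrop(
            image=crop.image.copy(),
            class_map=crop.class_map.copy(),
            offset=crop.offset,
            side=crop.side,
        )
    shape = crop.class_map.shape
    out_shape, matrix, offset = _rotation_grids(shape, theta)
    channels = [
        ndimage.affine_transform(
            crop.image[..., k].astype(float),
            matrix,
            offset=offset,
            output_shape=out_shape,
            order=1,
            mode="constant",
            cval=255.0,
        )
        for k in range(3)
    ]
    image = np.clip(np.stack(channels, axis=-1), 0, 255).astype(np.uint8)
    class_map = ndimage.affine_transform(
        crop.class_map,
        matrix,
        offset=offset,
        output_shape=out_shape,
        order=0,
        mode="constant",
        cval=int(PixelClass.BACKGROUND),
    )
    # Rotation breaks the link to the parent frame; offset restarts at 0.
    return FootCrop(image=image, class_map=class_map, offset=(0, 0), side=crop.side)
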