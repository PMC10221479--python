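"""Foot isolation: foreground mask, contour detection, rectangles, crops.

A static acquisition images both feet at once; contour detection on the
color-segmented foreground finds the two largest connected components,
their enclosing rectangles separate the feet, and each foot is cropped to
its rectangle (plus a small margin) for the downstream per-foot stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours

from .errors import BoundsError, SegmentationError
from .pressuremap_io import PixelClass

__all__ = [
    "FootSide",
    "ContourPolygon",
    "BoundingBox",
    "FootCrop",
    "foreground_mask",
    "detect_feet",
    "bounding_box",
    "crop_foot",
    "assign_sides",
]

#: 8-connectivity for component labeling.
_CONN8 = np.ones((3, 3), dtype=bool)


class FootSide(Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class ContourPolygon:
    """Closed external boundary of one connected foreground component.

    ``vertices`` is an ``(N, 2)`` float array of (x, y) points tracing the
    component boundary (first and last point coincide); ``area`` is the
    filled pixel count of the component.
    """

    vertices: np.ndarray
    area: int

    def __post_init__(self) -> None:
        v = self.vertices
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise SegmentationError("contour needs at least 3 (x, y) vertices")
        if self.area <= 0:
            raise SegmentationError("contour encloses no area")


@dataclass(frozen=True)
class BoundingBox:
    """Tight axis-aligned enclosing rectangle in pixel coordinates."""

    minxd: int
    maxxd: int
    minyd: int
    maxyd: int

    def __post_init__(self) -> None:
        if not (self.minxd < self.maxxd and self.minyd < self.maxyd):
            raise SegmentationError(
                f"degenerate bounding box "
                f"[{self.minxd},{self.maxxd}]x[{self.minyd},{self.maxyd}]"
            )

    @property
    def width(self) -> int:
        """Pixel count spanned along x (inclusive extremes)."""
        return self.maxxd - self.minxd + 1

    @property
    def height(self) -> int:
        """Pixel count spanned along y (inclusive extremes)."""
        return self.maxyd - self.minyd + 1


@dataclass
class FootCrop:
    """One foot cut out of the parent frame.

    ``offset`` is the (x, y) of the crop origin in the parent frame so
    every crop coordinate can be mapped back.
    """

    image: np.ndarray
    class_map: np.ndarray
    offset: tuple[int, int]
    side: FootSide


def foreground_mask(class_map: np.ndarray) -> np.ndarray:
    """Boolean mask of foot pixels: perimeter plus every pressure level."""
    return np.asarray(class_map) != int(PixelClass.BACKGROUND)


def _trace_contour(component: np.ndarray) -> np.ndarray:
    """Longest iso-0.5 boundary of a component mask as (x, y) vertices."""
    padded = np.pad(component.astype(float), 1)
    # 'high' keeps diagonally linked foreground in one loop, matching the
    # 8-connected component labeling
    loops = find_contours(padded, 0.5, fully_connected="high")
    # the outer boundary is the loop with the widest bounding box (hole
    # loops lie strictly inside it)
    loop = max(loops, key=lambda lp: np.ptp(lp[:, 0]) + np.ptp(lp[:, 1]))
    # find_contours yields (row, col); shift for padding and flip to (x, y).
    return np.stack([loop[:, 1] - 1.0, loop[:, 0] - 1.0], axis=1)


def detect_feet(
    mask: np.ndarray,
    min_area_frac: float = 0.001,
    n_required: int | None = None,
) -> list[ContourPolygon]:
    """External contours of connected components, largest area first.

    Components smaller than ``min_area_frac`` of the image area are treated
    as compression-noise specks and dropped before ranking.  Area ties are
    broken by smaller min-y, then smaller min-x, so the ordering is
    deterministic.  In pair mode the caller takes the first two contours
    as the feet.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask: no foreground to segment")
    labels, n = ndimage.label(mask, structure=_CONN8)
    min_area = min_area_frac * mask.size
    objects = ndimage.find_objects(labels)
    entries = []
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        comp = labels[sl] == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        verts = _trace_contour(comp)
        verts[:, 0] += sl[1].start
        verts[:, 1] += sl[0].start
        entries.append((area, sl[0].start, sl[1].start, ContourPolygon(verts, area)))
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    contours = [e[3] for e in entries]
    if not contours:
        raise SegmentationError("all components fall below the minimum-area filter")
    if n_required is not None and len(contours) < n_required:
        raise SegmentationError(
            f"found {len(contours)} contour(s), {n_required} required"
        )
    return contours


def bounding_box(contour: ContourPolygon) -> BoundingBox:
    """Enclosing rectangle of a contour, in whole-pixel coordinates.

    Boundary vertices traced at the 0.5 iso-level sit half a pixel outside
    the pixel centers, so the extrema are rounded inward; the resulting box
    equals the min/max over the component's foreground pixel coordinates.
    """
    v = contour.vertices
    return BoundingBox(
        minxd=math.ceil(v[:, 0].min()),
        maxxd=math.floor(v[:, 0].max()),
        minyd=math.ceil(v[:, 1].min()),
        maxyd=math.floor(v[:, 1].max()),
    )


def contour_centroid_x(contour: ContourPolygon) -> float:
    return float(contour.vertices[:, 0].mean())


def assign_sides(contours: list[ContourPolygon]) -> dict[FootSide, ContourPolygon]:
    """Label a pair of contours LEFT/RIGHT by centroid x in the parent frame."""
    if len(contours) < 2:
        raise SegmentationError("side assignment requires two contours")
    a, b = contours[0], contours[1]
    if contour_centroid_x(a) <= contour_centroid_x(b):
        return {FootSide.LEFT: a, FootSide.RIGHT: b}
    return {FootSide.LEFT: b, FootSide.RIGHT: a}


def crop_foot(
    img: np.ndarray,
    class_map: np.ndarray,
    box: BoundingBox,
    side: FootSide,
    margin: int = 2,
) -> FootCrop:
    """Cut the sub-image and sub-map inside ``box`` plus a margin.

    The margin is clamped to the parent frame; the crop origin is recorded
    so coordinates can be mapped back to the parent.
    """
    h, w = np.asarray(class_map).shape[:2]
    if box.minxd < 0 or box.minyd < 0 or box.maxxd >= w or box.maxyd >= h:
        raise BoundsError(f"bounding box {box} outside {w}x{h} image")
    x0 = max(0, box.minxd - margin)
    y0 = max(0, box.minyd - margin)
    x1 = min(w, box.maxxd + 1 + margin)
    y1 = min(h, box.maxyd + 1 + margin)
    return FootCrop(
        image=np.ascontiguousarray(img[y0:y1, x0:x1]),
        class_map=np.ascontiguousarray(class_map[y0:y1, x0:x1]),
        offset=(x0, y0),
        side=side,
    )
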