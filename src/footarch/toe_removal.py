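"""Toeprint removal, heel-artifact repair, and morphological cleanup.

Toeprints carry a negligible share of body weight and are highly variable,
so they are excluded before the arch index is measured.  Removal is a
circle criterion: every pixel farther than a radius R from the footprint
centroid is discarded.  R is the Euclidean distance between the centroid
(Cx, Cy) and an anchor derived from the highest-pressure forefoot region,

    R = sqrt((ax − Cx)² + (ay − Cy)²),

with the anchor at (0, minyg) in the crop frame, where minyg is the top
row of that region ("literal" mode), or at the actual contour point that
attains minyg ("contour" mode).  Because the circle can also clip the
heel, the lower half of the pre-removal image is concatenated back under
the upper half of the toe-free image.  Finally the blue perimeter trace is
dropped and a morphological opening (one erosion, one dilation) yields the
clean black-and-white footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import EmptyFootprintError, FootArchError, PeakNotFoundError
from .foot_segmentation import FootCrop
from .pressuremap_io import PixelClass

__all__ = [
    "Centroid",
    "PeakRegion",
    "BinaryFootprint",
    "centroid",
    "forefoot_peak",
    "toe_radius",
    "circular_crop",
    "repair_heel",
    "binarize_morph",
]

AnchorMode = Literal["literal", "contour"]

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Centroid:
    """Arithmetic mean of the foreground pixel coordinates (raster moments
    M10/M00 and M01/M00)."""

    cx: float
    cy: float


@dataclass(frozen=True)
class PeakRegion:
    """The highest-pressure connected region of the forefoot.

    ``minyg`` is the smallest y of the region; ``anchor`` is the point the
    radius is measured to: (0, minyg) in literal mode, or the region pixel
    attaining minyg in contour mode.
    """

    minyg: int
    anchor: tuple[float, float]
    pressure_class: PixelClass
    pixel_count: int


@dataclass
class BinaryFootprint:
    """Toe-free, artifact-repaired, morphologically opened footprint."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def centroid(mask: np.ndarray) -> Centroid:
    """Centroid of a binary mask via its zeroth and first raster moments."""
    mask = np.asarray(mask, dtype=bool)
    m00 = mask.sum()
    if m00 == 0:
        raise EmptyFootprintError("cannot take the centroid of an empty mask")
    ys, xs = np.nonzero(mask)
    return Centroid(cx=float(xs.mean()), cy=float(ys.mean()))


def forefoot_peak(
    class_map: np.ndarray, anchor_mode: AnchorMode = "literal"
) -> PeakRegion:
    """Find the forefoot region of maximum pressure.

    Among the connected regions of the highest pressure class present,
    the one nearest the top of the image is the forefoot one (toes point
    up in the working orientation); the heel often carries an equally
    high peak and must not be selected.
    """
    cm = np.asarray(class_map)
    peak_class = int(cm.max())
    if peak_class < int(PixelClass.P1):
        raise PeakNotFoundError("no pressure-class pixels present")
    labels, n = ndimage.label(cm == peak_class, structure=_CONN8)
    best = None
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        key = (int(ys.min()), int(xs[ys == ys.min()].min()))
        if best is None or key < best[0]:
            best = (key, len(ys))
    (minyg, min_x_at_top), count = best
    if anchor_mode == "contour":
        anchor = (float(min_x_at_top), float(minyg))
    else:
        anchor = (0.0, float(minyg))
    return PeakRegion(
        minyg=minyg,
        anchor=anchor,
        pressure_class=PixelClass(peak_class),
        pixel_count=count,
    )


def toe_radius(c: Centroid, peak: PeakRegion) -> float:
    """Euclidean distance from the centroid to the peak anchor."""
    ax, ay = peak.anchor
    return math.hypot(ax - c.cx, ay - c.cy)


def circular_crop(crop: FootCrop, c: Centroid, radius: float) -> FootCrop:
    """Blank every pixel farther than ``radius`` from the centroid.

    Pixels at distance ≤ R are untouched; the rest become background in
    both the color image and the class map.  Dimensions are preserved.
    """
    if radius < 0:
        raise FootArchError("radius must be non-negative")
    h, w = crop.class_map.shape
    ys, xs = np.ogrid[:h, :w]
    outside = (xs - c.cx) ** 2 + (ys - c.cy) ** 2 > radius**2
    image = crop.image.copy()
    image[outside] = (255, 255, 255)
    class_map = crop.class_map.copy()
    class_map[outside] = int(PixelClass.BACKGROUND)
    return FootCrop(image=image, class_map=class_map, offset=crop.offset, side=crop.side)


def repair_heel(cropped: FootCrop, original: FootCrop) -> FootCrop:
    """Concatenate the toe-free upper half with the pre-removal lower half.

    The toe-removal circle can clip the heel; gluing rows [0, H/2) of the
    toe-free image onto rows [H/2, H) of the pre-removal image restores it.
    Both crops must live in the same frame (circular_crop preserves it).
    """
    if cropped.class_map.shape != original.class_map.shape:
        raise FootArchError("repair_heel operands have mismatched dimensions")
    split = cropped.class_map.shape[0] // 2
    image = np.vstack([cropped.image[:split], original.image[split:]])
    class_map = np.vstack([cropped.class_map[:split], original.class_map[split:]])
    return FootCrop(
        image=image, class_map=class_map, offset=cropped.offset, side=cropped.side
    )


def binarize_morph(
    crop: FootCrop,
    structure: np.ndarray | None = None,
    erosion_passes: int = 1,
    dilation_passes: int = 1,
) -> BinaryFootprint:
    """Binary footprint: pressure pixels only, then erosion and dilation.

    The blue perimeter trace is excluded (it outlines the foot but is not
    loaded area); the opening removes stray specks left by segmentation
    while preserving the footprint body.
    """
    structure = _CONN8 if structure is None else np.asarray(structure, dtype=bool)
    cm = crop.class_map
    fg = (cm >= int(PixelClass.P1)) & (cm <= int(PixelClass.P5))
    if erosion_passes:
        fg = ndimage.binary_erosion(fg, structure=structure, iterations=erosion_passes)
    if dilation_passes:
        fg = ndimage.binary_dilation(fg, structure=structure, iterations=dilation_passes)
    if not fg.any():
        raise EmptyFootprintError("footprint vanished under binarization/opening")
    return BinaryFootprint(
        mask=fg,
        provenance={
            "morphed": True,
            "erosion_passes": erosion_passes,
            "dilation_passes": dilation_passes,
        },
    )
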