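"""Reading pressure-map images and decoding the isochromatic palette.

Baropodometric platforms render the plantar pressure field as an
isochromatic map: warm colors (red) mark the areas of highest pressure,
cooler colors down to dark green mark progressively lower pressure, and a
blue outline traces the foot perimeter.  This module decodes such an RGB
raster into per-pixel semantic classes and writes the analysis report.

Conventions used throughout the package: raster frame, origin at the
top-left corner, x to the right (columns), y downward (rows).  Images are
``numpy`` arrays of shape ``(height, width, 3)`` with dtype ``uint8``;
class maps are ``(height, width)`` arrays of ``uint8`` holding
:class:`PixelClass` values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.color import rgb2hsv

from .errors import ConfigError, FormatError, InputError, OutputError

__all__ = [
    "PixelClass",
    "HueRange",
    "PaletteConfig",
    "DEFAULT_PALETTE",
    "load_image",
    "save_image",
    "classify_pixels",
    "render_class_map",
    "write_report",
    "read_report",
]


class PixelClass(IntEnum):
    """Semantic pixel classes, ordered by pressure level.

    ``P1`` is the lowest pressure level (dark green), ``P5`` the highest
    (red); ``PERIMETER`` is the blue foot outline.
    """

    BACKGROUND = 0
    PERIMETER = 1
    P1 = 2
    P2 = 3
    P3 = 4
    P4 = 5
    P5 = 6


#: Classes that count as pressure (exclude background and perimeter).
PRESSURE_CLASSES = (
    PixelClass.P1,
    PixelClass.P2,
    PixelClass.P3,
    PixelClass.P4,
    PixelClass.P5,
)


@dataclass(frozen=True)
class HueRange:
    """Closed hue interval in degrees; ``lo > hi`` wraps through 0/360."""

    lo: float
    hi: float

    def contains(self, hue_deg: np.ndarray) -> np.ndarray:
        if self.lo <= self.hi:
            return (hue_deg >= self.lo) & (hue_deg <= self.hi)
        return (hue_deg >= self.lo) | (hue_deg <= self.hi)

    def overlaps(self, other: "HueRange") -> bool:
        # Sample-free interval test on the circle: split wrapped ranges.
        def segments(r: "HueRange"):
            if r.lo <= r.hi:
                return [(r.lo, r.hi)]
            return [(r.lo, 360.0), (0.0, r.hi)]

        for a0, a1 in segments(self):
            for b0, b1 in segments(other):
                if a0 <= b1 and b0 <= a1:
                    return True
        return False


@dataclass
class PaletteConfig:
    """Color ranges that map RGB pixels to semantic classes.

    The platform software renders five discrete pressure levels along a
    red-to-green ramp plus a blue perimeter outline; the numeric hue
    intervals here reconstruct that ramp.  Saturation and value floors
    keep compression artifacts (washed-out ring pixels around saturated
    regions) in the background class rather than in a wrong level.
    """

    hue_ranges: dict[PixelClass, HueRange]
    sat_min: float = 0.30
    val_min: float = 0.20
    render_colors: dict[PixelClass, tuple[int, int, int]] = field(default_factory=dict)
    background_color: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        classes = list(self.hue_ranges)
        if not classes:
            raise ConfigError("palette defines no classes")
        for c in classes:
            if c is PixelClass.BACKGROUND:
                raise ConfigError("BACKGROUND must not have a hue range")
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                if self.hue_ranges[a].overlaps(self.hue_ranges[b]):
                    raise ConfigError(
                        f"palette hue ranges overlap: {a.name} and {b.name}"
                    )
        if not 0.0 <= self.sat_min <= 1.0 or not 0.0 <= self.val_min <= 1.0:
            raise ConfigError("saturation/value floors must lie in [0, 1]")

    def color_of(self, cls: PixelClass) -> tuple[int, int, int]:
        if cls is PixelClass.BACKGROUND:
            return self.background_color
        return self.render_colors[cls]

    # -- plain-text (JSON) persistence ------------------------------------

    def to_file(self, path: str | Path) -> None:
        doc = {
            "hue_ranges": {c.name: [r.lo, r.hi] for c, r in self.hue_ranges.items()},
            "sat_min": self.sat_min,
            "val_min": self.val_min,
            "render_colors": {
                c.name: list(v) for c, v in self.render_colors.items()
            },
            "background_color": list(self.background_color),
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "PaletteConfig":
        p = Path(path)
        if not p.exists():
            raise InputError(f"palette file not found: {p}")
        try:
            doc = json.loads(p.read_text())
            return cls(
                hue_ranges={
                    PixelClass[k]: HueRange(*v) for k, v in doc["hue_ranges"].items()
                },
                sat_min=float(doc.get("sat_min", 0.30)),
                val_min=float(doc.get("val_min", 0.20)),
                render_colors={
                    PixelClass[k]: tuple(v)
                    for k, v in doc.get("render_colors", {}).items()
                },
                background_color=tuple(doc.get("background_color", (255, 255, 255))),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"invalid palette file {p}: {exc}") from exc


def default_palette() -> PaletteConfig:
    """Five pressure levels on a red→yellow→green hue ramp plus blue outline."""
    return PaletteConfig(
        hue_ranges={
            PixelClass.P5: HueRange(345.0, 15.0),   # red
            PixelClass.P4: HueRange(16.0, 45.0),    # orange
            PixelClass.P3: HueRange(46.0, 75.0),    # yellow
            PixelClass.P2: HueRange(76.0, 105.0),   # light green
            PixelClass.P1: HueRange(106.0, 165.0),  # dark green
            PixelClass.PERIMETER: HueRange(195.0, 265.0),  # blue
        },
        render_colors={
            PixelClass.P5: (255, 0, 0),
            PixelClass.P4: (255, 128, 0),
            PixelClass.P3: (255, 255, 0),
            PixelClass.P2: (128, 255, 0),
            PixelClass.P1: (0, 153, 51),
            PixelClass.PERIMETER: (0, 0, 255),
        },
    )


DEFAULT_PALETTE = default_palette()


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG into an ``(H, W, 3)`` uint8 RGB array.

    An alpha channel, palette, or grayscale encoding is converted to RGB;
    everything else about the pixel grid is preserved.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"image not found: {p}")
    try:
        with Image.open(p) as im:
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode image: {p}") from exc
    except OSError as exc:
        raise FormatError(f"cannot read image {p}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise FormatError(f"unexpected image shape {arr.shape} for {p}")
    return arr


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB array as PNG (lossless) or JPEG, by extension."""
    try:
        Image.fromarray(np.asarray(img, dtype=np.uint8)).save(Path(path))
    except OSError as exc:
        raise OutputError(f"cannot write image {path}: {exc}") from exc


def classify_pixels(img: np.ndarray, palette: PaletteConfig | None = None) -> np.ndarray:
    """Decode an RGB pressure map into a per-pixel class map.

    Each pixel receives exactly one :class:`PixelClass`; pixels whose hue
    falls in no configured range, or whose saturation/value are below the
    palette floors, become ``BACKGROUND``.
    """
    palette = palette or DEFAULT_PALETTE
    palette.validate()
    arr = np.asarray(img, dtype=np.uint8)
    hsv = rgb2hsv(arr)
    hue = hsv[..., 0] * 360.0
    chromatic = (hsv[..., 1] >= palette.sat_min) & (hsv[..., 2] >= palette.val_min)
    out = np.zeros(arr.shape[:2], dtype=np.uint8)
    for cls, rng in palette.hue_ranges.items():
        out[chromatic & rng.contains(hue)] = int(cls)
    return out


def render_class_map(class_map: np.ndarray, palette: PaletteConfig | None = None) -> np.ndarray:
    """Render a class map back to canonical class colors (inverse of
    :func:`classify_pixels` up to palette quantization)."""
    palette = palette or DEFAULT_PALETTE
    cm = np.asarray(class_map)
    out = np.empty(cm.shape + (3,), dtype=np.uint8)
    out[:] = palette.background_color
    for cls in list(PRESSURE_CLASSES) + [PixelClass.PERIMETER]:
        out[cm == int(cls)] = palette.color_of(cls)
    return out


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an analysis report (or a recorded failure) to JSON."""
    try:
        Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
    except OSError as exc:
        raise OutputError(f"cannot write report {path}: {exc}") from exc


def read_report(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise InputError(f"report not found: {p}")
    return json.loads(p.read_text())
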