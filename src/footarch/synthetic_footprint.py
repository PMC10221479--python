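"""Synthetic baropodometric footprints with known ground truth.

No public dataset of isochromatic pressure maps accompanies this package,
so every pipeline stage is validated against generated footprints whose
geometry is known exactly.  A foot is modeled as the union of simple
shapes in an upright template frame — a forefoot ellipse, a heel ellipse,
a connecting midfoot band whose width fraction ``w`` of the forefoot
width controls the expected arch index monotonically, and detached toe
circles — rotated by a pose angle and rasterized directly (membership
testing per pixel, no resampling).  Regions are painted with the palette's
canonical class colors and a 1-pixel blue perimeter ring is drawn around
the convex hull of the print, emulating the foot outline the platform
software draws around the whole sole (which is also what connects the
detached toeprints to the foot in contour detection).

Ground truth bundled with each image:

* ``theta_true_deg`` — the foot progression angle as the enclosing-
  rectangle construction defines it, computed in closed form from the
  exact (continuous) extents of the rotated shapes: the progression angle
  here is a contour-geometry quantity, so its ground truth is the same
  construction evaluated on exact geometry rather than on pixels.
* per-region painted pixel counts and the total foreground count;
* ``oracle_ai`` — the arch index of the toe-free, unrotated foot,
  rasterized independently at 4x resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .errors import SpecError
from .foot_segmentation import FootSide
from .pressuremap_io import PixelClass, render_class_map

__all__ = [
    "FootSpec",
    "GroundTruth",
    "default_spec",
    "rectangle_spec",
    "generate",
    "generate_pair",
    "oracle_ai",
    "parse_footspec",
    "format_footspec",
]

_CONN8 = np.ones((3, 3), dtype=bool)

#: Default pressure class per anatomical region: both the forefoot and the
#: heel carry the highest loads, the midfoot the lowest, toes in between.
DEFAULT_LEVELS = {
    "forefoot": PixelClass.P5,
    "heel": PixelClass.P5,
    "midfoot": PixelClass.P2,
    "toes": PixelClass.P3,
}


@dataclass
class FootSpec:
    """Geometric recipe for one synthetic footprint.

    All shape coordinates are given in the canvas frame for a pose
    rotation of zero; ``rotation_deg`` rotates the whole foot about the
    midpoint between the forefoot and heel centers (positive = the top of
    the foot swings toward +x).  ``midfoot_frac`` is the band half-width
    as a fraction of the forefoot half-width and is the main driver of
    the arch index.
    """

    canvas: tuple[int, int]  # (width, height) in pixels
    fore_center: tuple[float, float]
    fore_axes: tuple[float, float]  # (x half-axis, y half-axis)
    heel_center: tuple[float, float]
    heel_axes: tuple[float, float]
    midfoot_frac: float
    band_center_x: float | None = None
    toes: tuple[tuple[float, float, float], ...] = ()  # (cx, cy, radius)
    rotation_deg: float = 0.0
    side: FootSide = FootSide.RIGHT
    levels: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    noise: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    theta_true_deg: float
    region_counts: dict
    foreground_count: int
    oracle_ai: float
    oracle_category: str
    seed: int


def default_spec(
    side: FootSide = FootSide.RIGHT,
    midfoot_frac: float = 0.45,
    rotation_deg: float = 0.0,
    seed: int = 0,
    noise: float = 0.0,
    width_scale: float = 1.0,
) -> FootSpec:
    """A realistic adult footprint on a 170x310 canvas.

    The template is a right foot (medial side toward smaller x: big toe
    medial, midfoot band shifted laterally as the arch is medial); a left
    foot is its mirror image.  ``width_scale`` widens or narrows the foot
    without changing its length.
    """
    x0 = 85.0

    def mx(x: float) -> float:  # mirror x for a left foot
        return x if side is FootSide.RIGHT else 2 * x0 - x

    s = width_scale
    return FootSpec(
        canvas=(170, 310),
        fore_center=(mx(x0), 75.0),
        fore_axes=(34.0 * s, 30.0),
        heel_center=(mx(x0), 230.0),
        heel_axes=(26.0 * s, 34.0),
        midfoot_frac=midfoot_frac,
        band_center_x=mx(x0 + 6.0 * s),
        toes=(
            (mx(x0 - 22.0 * s), 19.0, 7.0),  # big toe, medial
            (mx(x0 - 6.0 * s), 22.0, 5.0),
            (mx(x0 + 8.0 * s), 25.0, 5.0),
            (mx(x0 + 20.0 * s), 28.0, 4.0),
            (mx(x0 + 30.0 * s), 31.0, 4.0),
        ),
        rotation_deg=rotation_deg,
        side=side,
        noise=noise,
        seed=seed,
    )


def shift_spec(spec: FootSpec, dx: float, dy: float = 0.0, canvas: tuple[int, int] | None = None) -> FootSpec:
    """Translate every shape of a spec (used to place feet on a pair canvas)."""
    return replace(
        spec,
        canvas=canvas or spec.canvas,
        fore_center=(spec.fore_center[0] + dx, spec.fore_center[1] + dy),
        heel_center=(spec.heel_center[0] + dx, spec.heel_center[1] + dy),
        band_center_x=(
            None if spec.band_center_x is None else spec.band_center_x + dx
        ),
        toes=tuple((tx + dx, ty + dy, r) for tx, ty, r in spec.toes),
    )


def rectangle_spec(width: int = 48, height: int = 240, seed: int = 0) -> FootSpec:
    """A degenerate footprint whose pressure area is an exact rectangle.

    Both ellipses are collapsed to zero area and the midfoot band spans
    the full height, so the painted foreground is a ``width`` x ``height``
    axis-aligned rectangle — the shape whose arch index is exactly 1/3
    when the height is divisible by 3.
    """
    # half-integer center: pixel membership |x - cx| <= width/2 then spans
    # exactly `width` integer columns
    cx, cy0, cy1 = 85.5, 35.0, 35.0 + height - 1
    return FootSpec(
        canvas=(170, height + 70),
        fore_center=(cx, cy0),
        fore_axes=(width / 2.0, 0.0),
        heel_center=(cx, cy1),
        heel_axes=(width / 2.0, 0.0),
        midfoot_frac=1.0,
        band_center_x=cx,
        toes=(),
        levels={**DEFAULT_LEVELS, "midfoot": PixelClass.P5},
        seed=seed,
    )


# ----------------------------------------------------------------------
# geometry helpers


def _pose(spec: FootSpec):
    """Rotation center and angle (radians) of the pose transform."""
    rc = (
        (spec.fore_center[0] + spec.heel_center[0]) / 2.0,
        (spec.fore_center[1] + spec.heel_center[1]) / 2.0,
    )
    return rc, math.radians(spec.rotation_deg)


def _band_geometry(spec: FootSpec):
    half_width = spec.midfoot_frac * spec.fore_axes[0]
    cx = spec.band_center_x if spec.band_center_x is not None else spec.fore_center[0]
    return cx, half_width, spec.fore_center[1], spec.heel_center[1]


def _rotated_point(p, rc, beta):
    c, s = math.cos(beta), math.sin(beta)
    dx, dy = p[0] - rc[0], p[1] - rc[1]
    return (rc[0] + c * dx - s * dy, rc[1] + s * dx + c * dy)


def _analytic_extents(spec: FootSpec) -> tuple[float, float, float, float]:
    """Exact (minx, maxx, miny, maxy) of the rotated print plus its
    1-pixel perimeter ring."""
    rc, beta = _pose(spec)
    c, s = math.cos(beta), math.sin(beta)
    xs: list[float] = []
    ys: list[float] = []
    for center, (a, b) in (
        (spec.fore_center, spec.fore_axes),
        (spec.heel_center, spec.heel_axes),
    ):
        if a <= 0 and b <= 0:
            continue
        ex = math.hypot(a * c, b * s)  # AABB half-extents of a rotated ellipse
        ey = math.hypot(a * s, b * c)
        cx, cy = _rotated_point(center, rc, beta)
        xs += [cx - ex, cx + ex]
        ys += [cy - ey, cy + ey]
    bx, hw, y0, y1 = _band_geometry(spec)
    if hw > 0 and y1 > y0:
        for corner in ((bx - hw, y0), (bx + hw, y0), (bx - hw, y1), (bx + hw, y1)):
            px, py = _rotated_point(corner, rc, beta)
            xs.append(px)
            ys.append(py)
    for tx, ty, r in spec.toes:
        if r <= 0:
            continue
        px, py = _rotated_point((tx, ty), rc, beta)
        xs += [px - r, px + r]
        ys += [py - r, py + r]
    if not xs:
        raise SpecError("footprint spec paints no shapes")
    ring = 1.0
    return min(xs) - ring, max(xs) + ring, min(ys) - ring, max(ys) + ring


def theta_true_deg(spec: FootSpec) -> float:
    """Closed-form progression angle of the rotated print.

    Evaluates the enclosing-rectangle axis construction (midpoint mode)
    on the exact continuous extents: |tan θ| = W / (2 H), negative for a
    right foot (t2 sits at the medial = min-x corner), positive for a
    left foot.
    """
    minx, maxx, miny, maxy = _analytic_extents(spec)
    w, h = maxx - minx, maxy - miny
    sign = -1.0 if spec.side is FootSide.RIGHT else 1.0
    return sign * math.degrees(math.atan2(w / 2.0, h))


# ----------------------------------------------------------------------
# rasterization


def _region_masks(spec: FootSpec, xs: np.ndarray, ys: np.ndarray, posed: bool):
    """Membership masks per region at the given sample coordinates.

    ``xs``/``ys`` broadcast to the sample grid; with ``posed`` the sample
    points are pulled back through the inverse pose rotation first.
    """
    if posed:
        rc, beta = _pose(spec)
        c, s = math.cos(beta), math.sin(beta)
        u = rc[0] + c * (xs - rc[0]) + s * (ys - rc[1])
        v = rc[1] - s * (xs - rc[0]) + c * (ys - rc[1])
    else:
        u, v = xs, ys

    def ellipse(center, axes):
        a, b = axes
        if a <= 0 or b <= 0:
            return np.zeros(np.broadcast_shapes(u.shape, v.shape), dtype=bool)
        return ((u - center[0]) / a) ** 2 + ((v - center[1]) / b) ** 2 <= 1.0

    bx, hw, y0, y1 = _band_geometry(spec)
    band = (np.abs(u - bx) <= hw) & (v >= y0) & (v <= y1) if hw > 0 else np.zeros(
        np.broadcast_shapes(u.shape, v.shape), dtype=bool
    )
    toes = np.zeros(np.broadcast_shapes(u.shape, v.shape), dtype=bool)
    for tx, ty, r in spec.toes:
        toes |= (u - tx) ** 2 + (v - ty) ** 2 <= r**2
    return {
        "forefoot": ellipse(spec.fore_center, spec.fore_axes),
        "heel": ellipse(spec.heel_center, spec.heel_axes),
        "midfoot": band,
        "toes": toes,
    }


#: Paint priority when regions overlap (later wins).
_PRIORITY = ("midfoot", "heel", "forefoot", "toes")


def _label_map(spec: FootSpec) -> tuple[np.ndarray, dict]:
    """Class-label raster of one foot plus exclusive per-region counts."""
    w, h = spec.canvas
    minx, maxx, miny, maxy = _analytic_extents(spec)
    if minx < 0 or miny < 0 or maxx > w - 1 or maxy > h - 1:
        raise SpecError(
            f"rotated footprint extent [{minx:.1f},{maxx:.1f}]x[{miny:.1f},{maxy:.1f}] "
            f"exceeds {w}x{h} canvas"
        )
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    masks = _region_masks(spec, xs, ys, posed=True)

    labels = np.zeros((h, w), dtype=np.uint8)
    owner = np.full((h, w), "", dtype="U8")
    for region in _PRIORITY:
        m = masks[region]
        labels[m] = int(spec.levels[region])
        owner[m] = region

    pressure = labels >= int(PixelClass.P1)
    hull = convex_hull_image(pressure)
    ring = ndimage.binary_dilation(hull, structure=_CONN8) & ~hull
    labels[ring] = int(PixelClass.PERIMETER)

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        border = pressure & ~ndimage.binary_erosion(pressure, structure=_CONN8)
        jitter = border & (rng.random(labels.shape) < spec.noise)
        delta = rng.integers(0, 2, size=labels.shape) * 2 - 1
        noisy = np.clip(
            labels.astype(int) + delta, int(PixelClass.P1), int(PixelClass.P5)
        ).astype(np.uint8)
        labels[jitter] = noisy[jitter]

    counts = {r: int((owner == r).sum()) for r in _PRIORITY}
    counts["perimeter"] = int(ring.sum())
    return labels, counts


def oracle_ai(spec: FootSpec, factor: int = 4) -> float:
    """Arch index of the toe-free, unrotated foot at ``factor``x resolution.

    An implementation-independent expected value: the foot body (forefoot,
    heel, midfoot band — no toes, no pose rotation, no perimeter) is
    rasterized on a supersampled grid, its tight height is split into
    thirds with round-half-up boundaries, and B/(A+B+C) is computed
    directly from the sample counts.
    """
    upright = replace(spec, rotation_deg=0.0, toes=())
    minx, maxx, miny, maxy = _analytic_extents(upright)
    step = 1.0 / factor
    xs = np.arange(minx, maxx + step, step)
    ys = np.arange(miny, maxy + step, step)
    masks = _region_masks(upright, xs[None, :], ys[:, None], posed=False)
    body = masks["forefoot"] | masks["heel"] | masks["midfoot"]
    rows = np.nonzero(body.any(axis=1))[0]
    if rows.size == 0:
        raise SpecError("toe-free footprint is empty")
    body = body[rows.min() : rows.max() + 1]
    n = body.shape[0]
    b1 = int(math.floor(n / 3.0 + 0.5))
    b2 = int(math.floor(2.0 * n / 3.0 + 0.5))
    a = int(body[:b1].sum())
    b = int(body[b1:b2].sum())
    c = int(body[b2:].sum())
    return b / (a + b + c)


def _oracle_category(ai: float) -> str:
    if ai < 0.17:
        return "pes_cavus"
    if ai > 0.28:
        return "pes_planus"
    return "healthy"


def _ground_truth(spec: FootSpec, counts: dict) -> GroundTruth:
    ai = oracle_ai(spec)
    return GroundTruth(
        theta_true_deg=theta_true_deg(spec),
        region_counts=counts,
        foreground_count=sum(counts.values()),
        oracle_ai=ai,
        oracle_category=_oracle_category(ai),
        seed=spec.seed,
    )


def generate(spec: FootSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one footprint image and its ground truth.

    Deterministic for a fixed spec (including its seed).
    """
    labels, counts = _label_map(spec)
    return render_class_map(labels), _ground_truth(spec, counts)


def generate_pair(
    left: FootSpec, right: FootSpec
) -> tuple[np.ndarray, dict[FootSide, GroundTruth]]:
    """Render two disjoint feet on one shared canvas.

    The left foot must lie at smaller x; any overlap of the prints
    (including their perimeter rings) is a spec error.
    """
    if left.canvas != right.canvas:
        raise SpecError("pair members must share one canvas size")
    if left.side is not FootSide.LEFT or right.side is not FootSide.RIGHT:
        raise SpecError("pair members must be a LEFT and a RIGHT spec, in that order")
    labels_l, counts_l = _label_map(left)
    labels_r, counts_r = _label_map(right)
    if ((labels_l > 0) & (labels_r > 0)).any():
        raise SpecError("feet overlap on the shared canvas")
    lx = _analytic_extents(left)
    rx = _analytic_extents(right)
    if lx[0] >= rx[0]:
        raise SpecError("LEFT spec does not lie at smaller x than RIGHT spec")
    labels = np.where(labels_r > 0, labels_r, labels_l)
    truths = {
        FootSide.LEFT: _ground_truth(left, counts_l),
        FootSide.RIGHT: _ground_truth(right, counts_r),
    }
    return render_class_map(labels), truths


# ----------------------------------------------------------------------
# plain-text spec files


def format_footspec(spec: FootSpec) -> str:
    """Serialize a spec as `key = value` lines (toe lines repeat)."""
    lines = [
        f"canvas = {spec.canvas[0]} {spec.canvas[1]}",
        f"side = {spec.side.value}",
        f"rotation_deg = {spec.rotation_deg}",
        f"fore_center = {spec.fore_center[0]} {spec.fore_center[1]}",
        f"fore_axes = {spec.fore_axes[0]} {spec.fore_axes[1]}",
        f"heel_center = {spec.heel_center[0]} {spec.heel_center[1]}",
        f"heel_axes = {spec.heel_axes[0]} {spec.heel_axes[1]}",
        f"midfoot_frac = {spec.midfoot_frac}",
    ]
    if spec.band_center_x is not None:
        lines.append(f"band_center_x = {spec.band_center_x}")
    for tx, ty, r in spec.toes:
        lines.append(f"toe = {tx} {ty} {r}")
    lines.append(
        "levels = " + " ".join(f"{k}:{PixelClass(v).name}" for k, v in spec.levels.items())
    )
    lines.append(f"noise = {spec.noise}")
    lines.append(f"seed = {spec.seed}")
    return "\n".join(lines) + "\n"


def parse_footspec(text: str) -> FootSpec:
    """Parse the plain-text key-value spec format of :func:`format_footspec`."""
    fields: dict = {"toes": []}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SpecError(f"malformed spec line: {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "toe":
            fields["toes"].append(tuple(float(t) for t in val.split()))
        elif key == "levels":
            fields["levels"] = {
                part.split(":")[0]: PixelClass[part.split(":")[1]]
                for part in val.split()
            }
        else:
            fields[key] = val
    try:
        return FootSpec(
            canvas=tuple(int(t) for t in fields["canvas"].split()),
            fore_center=tuple(float(t) for t in fields["fore_center"].split()),
            fore_axes=tuple(float(t) for t in fields["fore_axes"].split()),
            heel_center=tuple(float(t) for t in fields["heel_center"].split()),
            heel_axes=tuple(float(t) for t in fields["heel_axes"].split()),
            midfoot_frac=float(fields["midfoot_frac"]),
            band_center_x=(
                float(fields["band_center_x"]) if "band_center_x" in fields else None
            ),
            toes=tuple(fields["toes"]),
            rotation_deg=float(fields.get("rotation_deg", 0.0)),
            side=FootSide(fields.get("side", "right")),
            levels=fields.get("levels", dict(DEFAULT_LEVELS)),
            noise=float(fields.get("noise", 0.0)),
            seed=int(fields.get("seed", 0)),
        )
    except (KeyError, ValueError) as exc:
        raise SpecError(f"invalid footprint spec: {exc}") from exc
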