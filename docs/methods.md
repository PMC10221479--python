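# Methods

## Pipeline

The package labels a static plantar-pressure image in a fixed stage
order: palette decoding → foreground mask → contour detection and
enclosing rectangles → per-foot crop → foot progression angle → upright
rotation → contour re-detection and re-crop → centroid, forefoot peak and
toe-removal circle → heel repair → binarization with morphological
opening → thirds split → arch index → classification. Every stage is a
pure function on explicit data types, so each is testable in isolation;
the orchestration lives in `footarch.cli.analyze_image`.

Working assumptions: inputs are static (not gait) prints rendered as
isochromatic maps; the toes point toward the top of the image; the raster
frame has its origin at the top-left with x rightward and y downward.

## Palette decoding

The platform software renders five discrete pressure levels from red
(highest) through orange, yellow and light green to dark green (lowest),
plus a blue perimeter outline; published figures state the ramp only
qualitatively, so the numeric reconstruction lives in a plain-text
`PaletteConfig` (JSON) and is fully overridable. Defaults: hue intervals
centered on the five ramp colors (P5 red 345°–15°, …, P1 dark green
106°–165°, perimeter blue 195°–265°), with saturation ≥ 0.30 and value
≥ 0.20 floors so washed-out compression artifacts around saturated
regions fall to background instead of a wrong level. Classification is
total (every pixel gets exactly one class) and idempotent under
re-rendering with the canonical class colors. Overlapping hue intervals
are rejected at configuration time.

## Progression angle

The axis line p1 is built from the enclosing rectangle of the foot
contour: t1 = (x1avg, minyd) on the top edge and t2 = t3 = (minxd, maxyd)
at the bottom-medial corner; p2 runs vertically through t4 = (t2.x, 0).
Two points needed resolution:

* The printed construction of x1avg mixes an x-extent with a y-extent
  ((minxd − maxyd)/2), which can place t1 outside the image. The default
  `midpoint` mode uses x1avg = (minxd + maxxd)/2, matching the axis as
  drawn; the printed formula ships unchanged behind `axis_mode="literal"`
  for fidelity.
* The slope of p2 as printed divides by zero (minxd − minxd). p2 is
  simply vertical, so the two-line angle formula
  tan θ = (m2 − m1)/(1 + m2·m1) is evaluated analytically in the limit
  m2 → ∞: tan θ = 1/m1, the signed angle between p1 and the vertical.

`minxd` is the medial side of a right footprint; for a left foot the
x-relations mirror (`maxxd` substitutes for `minxd`), which also mirrors
the angle sign — θ is antisymmetric under reflection, and this holds to
1e−9 in the property tests.

A consequence worth stating plainly: in midpoint mode
tan θ = −W/(2H) for a right foot, where W×H is the rectangle — the
estimate depends only on the rectangle's aspect ratio. The rotation
therefore makes p1 vertical (the contract of `rotate_foot`, verified by a
bar fixture) but leaves the anatomical long axis with a residual tilt of
roughly atan(W/2H) ≈ 8° for realistic proportions, and a re-estimate on
the rotated print does not converge to 0°. This is intrinsic to the
rectangle construction; the arch index downstream is only mildly
sensitive to it (see the recovery numbers below). The ground-truth angle
the synthetic generator reports is accordingly *the same construction
evaluated on exact continuous geometry* (closed-form extents of rotated
ellipses, rectangles and circles), which is what a progression-angle
estimate from pixels can and should be compared against.

Rotation resamples the color image bilinearly (background fill) and the
class map with nearest-neighbor so labels never blend; the canvas is
expanded so nothing is clipped, with a 1e−9 guard before `ceil` so exact
quarter turns do not inflate it. Foreground count is conserved within 2%
(exactly, for multiples of 90°).

## Toe removal and heel repair

The removal circle is centered on the centroid of the foreground (the
arithmetic mean of all foreground pixel coordinates — the filled-region
moments, since the print is "all the pixels that make up that shape") with
radius equal to the Euclidean distance to the anchor of the
highest-pressure forefoot region. Among connected regions of the maximum
pressure class present, the forefoot one is the region with smallest
minimum row (the heel usually carries an equally high peak). The printed
distance formula subtracts the squared terms, which would be imaginary;
the text's own "Euclidean distance" fixes the sign. The anchor default is
the printed (0, minyg) — note this makes R depend on the crop margin and
on which side of the crop the centroid sits; the actual contour point
attaining minyg is available via `anchor_mode="contour"`.

The circle clips the heel, so rows [H/2, H) of the pre-removal rotated
crop are concatenated under rows [0, H/2) of the toe-free image
(split row = floor(H/2)); both operands share one frame because the
circular crop preserves dimensions, and the lower half is restored
pixel-exactly.

Binarization keeps only pressure classes (the perimeter outline is not
loaded area), then applies one erosion and one dilation with a 3×3 square
— the operations are named in the source method but not the kernel or
pass counts, so all three are configurable. Opening is idempotent
pixel-exactly, and the circular crop is monotone in R; both are asserted
on random fixtures.

## Arch index

Thirds are measured over the tight bounding-box height of the cleaned
binary footprint (not the padded crop), so empty margins cannot dilute
band heights. Band boundaries use round-half-up at H/3 and 2H/3; leftover
rows go to the middle band, never dropped. AI = B/(A+B+C) ∈ [0, 1];
AI < 0.17 → pes cavus, AI > 0.28 → pes planus, boundaries inclusive as
healthy. The thresholds are literature conventions and sit in `RunConfig`.

## Synthetic footprints

A foot is the union of a forefoot ellipse, a heel ellipse, a midfoot band
of half-width w × (forefoot half-width), and detached toe circles,
rotated by a pose angle and rasterized by per-pixel membership testing
(no resampling, so the rendered geometry is exact). Regions get the
palette's canonical class colors — both the forefoot and heel carry the
top pressure class, which exercises the forefoot-vs-heel peak selection —
and a one-pixel blue ring around the convex hull of the print emulates
the whole-sole outline the platform draws, which is also what joins the
detached toeprints into a single contour. The default template
(170×310 canvas, foot ≈ 70×250 px) has the big toe on the medial side and
the midfoot band shifted slightly lateral (the arch is medial); toe
circles sit clearly beyond the toe-removal radius, as in the method's own
demonstration where the circle removes the toeprints completely.
Optional border noise flips pressure classes of boundary pixels with a
given probability (seeded); the default is 0, matching the clean platform
renders.

The band-width fraction w is the main driver of the arch index: w = 0
gives a disconnected cavus print (AI → 0), a full rectangle is the
AI = 1/3 limit, and only a midfoot bulging wider than the forefoot pushes
AI above that, flattening out near 0.40 — the anatomical ceiling of this
shape family. The recovery test family therefore sweeps w from 0.05 to
1.2, spanning oracle AI ≈ 0.04–0.38, comfortably crossing both decision
thresholds.

`oracle_ai` is implementation-independent: it rasterizes the toe-free,
unrotated foot body at 4× resolution and applies the thirds ratio
directly to the sample counts.

What the generator does **not** emulate: continuous pressure gradients
within a region, sensor quantization, JPEG compression artifacts (beyond
the optional border jitter), anatomical outlines beyond
ellipse-band-circle geometry, and partial or smeared prints. Passing
tests demonstrate the pipeline's correctness on clean, well-formed maps;
robustness on degraded real captures is untested by construction.

## Measured behavior at the default sizes

With the default template and the problem sizes used throughout the test
suite (20 feet per recovery family, 100 random oracle masks, 25 random
morphology fixtures):

* progression angle within 0.16° of the closed-form oracle (tolerance 1°);
* arch index within 0.007 of the 4× oracle (tolerance 0.02), categories
  agreeing whenever the oracle is ≥ 0.01 from a threshold;
* rectangle footprint: AI exactly 1/3 at the binary stage, 0.339 through
  the full pipeline (the residual-tilt effect described above);
* centroid, bounding box, per-third areas and radius match per-pixel
  brute force exactly.

## Known limitations

* The rectangle-based angle construction has a shape-dependent offset and
  is sign-fixed per side; it normalizes orientation only approximately.
* The literal (0, minyg) radius anchor ties R to the crop frame: margins
  and side asymmetries change how aggressively toes are removed.
* Thirds-over-height assumes the print is upright after rotation; gross
  rotation failures would corrupt the band split.
* Single-foot mode trusts the caller's `--side`; anatomy is not checked.
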