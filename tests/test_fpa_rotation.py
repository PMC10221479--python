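"""Progression-angle geometry and upright rotation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import footarch as fa
from conftest import crop_from_labels

P = fa.PixelClass
BOX = fa.BoundingBox(minxd=0, maxxd=20, minyd=0, maxyd=100)


def test_axis_points_midpoint_mode():
    pts = fa.axis_points(BOX, mode="midpoint")
    assert pts.t1 == (10.0, 0.0)
    assert pts.t2 == pts.t3 == (0.0, 100.0)
    assert pts.t4 == (0.0, 0.0)


def test_axis_points_literal_mode_uses_printed_formula():
    pts = fa.axis_points(BOX, mode="literal")
    assert pts.x1avg == (0 - 100) / 2  # mixes x- and y-extents, as printed
    assert pts.t1 == (-50.0, 0.0)


def test_axis_points_t4_always_on_zero_row():
    for minxd in (5, 17, 60):
        box = fa.BoundingBox(minxd=minxd, maxxd=minxd + 30, minyd=12, maxyd=200)
        assert fa.axis_points(box).t4 == (float(minxd), 0.0)


def test_axis_points_left_foot_uses_lateral_mirror():
    pts = fa.axis_points(BOX, side=fa.FootSide.LEFT)
    assert pts.t2 == (20.0, 100.0)
    assert pts.t4 == (20.0, 0.0)


def test_vertical_axis_has_zero_angle():
    pts = fa.AxisPoints(t1=(0, 0), t2=(0, 100), t3=(0, 100), t4=(0, 0), x1avg=0)
    angle = fa.progression_angle(pts)
    assert angle.radians == 0.0
    assert math.isinf(angle.slope_m1)


def test_known_angle_against_arctangent_oracle():
    pts = fa.AxisPoints(t1=(10, 0), t2=(0, 100), t3=(0, 100), t4=(0, 0), x1avg=10)
    angle = fa.progression_angle(pts)
    assert angle.slope_m1 == pytest.approx(-10.0)
    # independent oracle: signed angle between the p1 and p2 direction
    # vectors via the 2D cross/dot construction (raster frame, y down:
    # positive = p1 leaning toward +x)
    d1 = (0 - 10, 100 - 0)
    d2 = (0.0, 1.0)
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    dot = d1[0] * d2[0] + d1[1] * d2[1]
    oracle = math.atan2(cross, dot)
    assert angle.radians == pytest.approx(oracle, abs=1e-12)
    assert angle.degrees == pytest.approx(-5.7106, abs=1e-4)


def test_radian_degree_conversion():
    assert fa.Angle(radians=math.pi / 4, slope_m1=1.0).degrees == pytest.approx(45.0)


def test_coincident_axis_points_raise():
    pts = fa.AxisPoints(t1=(5, 5), t2=(5, 5), t3=(5, 5), t4=(5, 0), x1avg=5)
    with pytest.raises(fa.DegenerateAxisError):
        fa.progression_angle(pts)


@given(
    minxd=st.integers(0, 50),
    width=st.integers(1, 80),
    minyd=st.integers(0, 50),
    height=st.integers(1, 300),
)
def test_mirroring_negates_the_angle(minxd, width, minyd, height):
    """Reflecting the contour about a vertical axis (and swapping the foot
    side, since the medial side mirrors too) negates θ."""
    box = fa.BoundingBox(
        minxd=minxd, maxxd=minxd + width, minyd=minyd, maxyd=minyd + height
    )
    canvas_w = 200
    mirrored = fa.BoundingBox(
        minxd=canvas_w - (minxd + width),
        maxxd=canvas_w - minxd,
        minyd=minyd,
        maxyd=minyd + height,
    )
    theta_r = fa.progression_angle(fa.axis_points(box, side=fa.FootSide.RIGHT))
    theta_l = fa.progression_angle(fa.axis_points(mirrored, side=fa.FootSide.LEFT))
    assert theta_l.radians == pytest.approx(-theta_r.radians, abs=1e-9)


def test_zero_rotation_is_identity():
    labels = np.zeros((40, 30), dtype=np.uint8)
    labels[5:30, 10:20] = int(P.P2)
    crop = crop_from_labels(labels)
    out = fa.rotate_foot(crop, fa.Angle(radians=0.0, slope_m1=math.inf))
    assert np.array_equal(out.image, crop.image)
    assert np.array_equal(out.class_map, crop.class_map)


def test_quarter_turn_is_exact():
    labels = np.zeros((20, 12), dtype=np.uint8)
    labels[2:16, 3] = int(P.P3)  # vertical bar of an L
    labels[15, 3:9] = int(P.P3)  # horizontal bar
    crop = crop_from_labels(labels)
    out = fa.rotate_foot(crop, fa.Angle(radians=math.pi / 2, slope_m1=0.0))
    assert out.class_map.shape == (12, 20)
    before = fa.foreground_mask(crop.class_map)
    after = fa.foreground_mask(out.class_map)
    assert after.sum() == before.sum()
    # analytic quarter-turn of the foreground coordinate set
    ys, xs = np.nonzero(before)
    h = crop.class_map.shape[0]
    expected = {(int(h - 1 - y), int(x)) for y, x in zip(ys, xs)}
    got = {(int(x), int(y)) for y, x in zip(*np.nonzero(after))}
    assert got == expected


def test_rotation_turns_a_slanted_bar_vertical():
    # a 2-px-wide bar from (10, 5) to (30, 95): direction angle atan2(20, 90)
    labels = np.zeros((110, 50), dtype=np.uint8)
    for t in np.linspace(0.0, 1.0, 400):
        x, y = 10 + 20 * t, 5 + 90 * t
        labels[int(round(y)), int(round(x))] = int(P.P4)
        labels[int(round(y)), int(round(x)) + 1] = int(P.P4)
    crop = crop_from_labels(labels)
    theta = math.atan2(20.0, 90.0)
    out = fa.rotate_foot(crop, fa.Angle(radians=theta, slope_m1=90.0 / 20.0))
    xs = np.nonzero(fa.foreground_mask(out.class_map))[1]
    assert xs.max() - xs.min() <= 3  # bar is now (nearly) vertical


def test_rotation_conserves_foreground_within_tolerance():
    image, _ = fa.generate(fa.default_spec(seed=4, rotation_deg=9.0))
    cm = fa.classify_pixels(image)
    contour = fa.detect_feet(fa.foreground_mask(cm))[0]
    box = fa.bounding_box(contour)
    crop = fa.crop_foot(image, cm, box, fa.FootSide.RIGHT)
    angle = fa.progression_angle(fa.axis_points(box))
    out = fa.rotate_foot(crop, angle)
    n0 = fa.foreground_mask(crop.class_map).sum()
    n1 = fa.foreground_mask(out.class_map).sum()
    assert abs(n1 - n0) <= 0.02 * n0
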