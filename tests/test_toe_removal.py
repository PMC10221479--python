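"""Centroid, peak region, toe-removal circle, heel repair, binarization."""

import numpy as np
import pytest

import footarch as fa
from conftest import crop_from_labels, random_blob

P = fa.PixelClass


# ---------------------------------------------------------------- centroid


def test_centroid_of_square_is_its_center():
    mask = np.zeros((20, 20), dtype=bool)
    mask[0:10, 0:10] = True
    c = fa.centroid(mask)
    assert (c.cx, c.cy) == (4.5, 4.5)


def test_centroid_of_single_pixel():
    mask = np.zeros((10, 10), dtype=bool)
    mask[7, 3] = True
    c = fa.centroid(mask)
    assert (c.cx, c.cy) == (3.0, 7.0)


def test_centroid_equals_bruteforce_mean(rng):
    for _ in range(10):
        mask = random_blob(rng)
        c = fa.centroid(mask)
        pts = np.argwhere(mask)  # (y, x)
        assert c.cy == pts[:, 0].mean()
        assert c.cx == pts[:, 1].mean()


def test_centroid_of_empty_mask_raises():
    with pytest.raises(fa.EmptyFootprintError):
        fa.centroid(np.zeros((5, 5), dtype=bool))


# ----------------------------------------------------------- forefoot peak


def test_peak_minyg_is_top_row_of_red_blob():
    cm = np.zeros((100, 50), dtype=np.uint8)
    cm[10:21, 10:30] = int(P.P5)
    peak = fa.forefoot_peak(cm)
    assert peak.minyg == 10
    assert peak.anchor == (0.0, 10.0)
    assert peak.pressure_class == P.P5


def test_peak_prefers_topmost_of_two_blobs():
    cm = np.zeros((100, 50), dtype=np.uint8)
    cm[80:96, 10:30] = int(P.P5)  # heel peak
    cm[10:21, 15:35] = int(P.P5)  # forefoot peak
    peak = fa.forefoot_peak(cm)
    assert peak.minyg == 10  # brute-force region scan: topmost region wins
    assert peak.pixel_count == 11 * 20


def test_peak_uses_highest_class_present():
    cm = np.zeros((60, 40), dtype=np.uint8)
    cm[40:50, 5:15] = int(P.P4)
    cm[5:12, 5:15] = int(P.P2)
    peak = fa.forefoot_peak(cm)
    assert peak.pressure_class == P.P4
    assert peak.minyg == 40


def test_peak_contour_anchor_mode():
    cm = np.zeros((60, 40), dtype=np.uint8)
    cm[10:20, 25:35] = int(P.P5)
    peak = fa.forefoot_peak(cm, anchor_mode="contour")
    assert peak.anchor == (25.0, 10.0)


def test_no_pressure_pixels_raise():
    cm = np.zeros((30, 30), dtype=np.uint8)
    cm[3, 3] = int(P.PERIMETER)
    with pytest.raises(fa.PeakNotFoundError):
        fa.forefoot_peak(cm)


# -------------------------------------------------------------- toe radius


def test_radius_of_3_4_5_triangle():
    c = fa.Centroid(cx=3.0, cy=4.0)
    peak = fa.PeakRegion(minyg=0, anchor=(0.0, 0.0), pressure_class=P.P5, pixel_count=1)
    assert fa.toe_radius(c, peak) == 5.0


def test_radius_zero_when_anchor_equals_centroid():
    c = fa.Centroid(cx=2.5, cy=9.0)
    peak = fa.PeakRegion(minyg=9, anchor=(2.5, 9.0), pressure_class=P.P5, pixel_count=1)
    assert fa.toe_radius(c, peak) == 0.0


def test_radius_matches_hypot_oracle(rng):
    for _ in range(50):
        cx, cy, ax, ay = rng.uniform(-50, 50, size=4)
        c = fa.Centroid(cx=cx, cy=cy)
        peak = fa.PeakRegion(
            minyg=0, anchor=(ax, ay), pressure_class=P.P5, pixel_count=1
        )
        assert fa.toe_radius(c, peak) == pytest.approx(
            np.hypot(ax - cx, ay - cy), abs=1e-12
        )


# ----------------------------------------------------------- circular crop


def _random_crop(rng, shape=(50, 40)):
    labels = np.where(random_blob(rng, shape=shape), int(P.P3), 0).astype(np.uint8)
    return crop_from_labels(labels)


def test_huge_radius_is_identity(rng):
    crop = _random_crop(rng)
    c = fa.Centroid(cx=20.0, cy=25.0)
    out = fa.circular_crop(crop, c, radius=1000.0)
    assert np.array_equal(out.class_map, crop.class_map)
    assert np.array_equal(out.image, crop.image)


def test_zero_radius_blanks_everything(rng):
    crop = _random_crop(rng)
    out = fa.circular_crop(crop, fa.Centroid(cx=5.0, cy=5.0), radius=0.0)
    assert not fa.foreground_mask(out.class_map).any()


def test_circular_crop_monotone_in_radius(rng):
    crop = _random_crop(rng)
    c = fa.Centroid(cx=18.0, cy=22.0)
    previous = None
    for radius in (3.0, 7.0, 12.0, 20.0, 35.0):
        fg = fa.foreground_mask(fa.circular_crop(crop, c, radius).class_map)
        if previous is not None:
            assert (previous & ~fg).sum() == 0  # foreground only ever grows
        previous = fg


def test_circular_crop_matches_perpixel_distance_oracle(rng):
    crop = _random_crop(rng)
    c = fa.Centroid(cx=13.7, cy=29.2)
    radius = 11.4
    out = fa.circular_crop(crop, c, radius)
    ys, xs = np.mgrid[0 : crop.class_map.shape[0], 0 : crop.class_map.shape[1]]
    keep = (xs - c.cx) ** 2 + (ys - c.cy) ** 2 <= radius**2
    expected = np.where(keep, crop.class_map, 0)
    assert np.array_equal(out.class_map, expected)


# -------------------------------------------------------------- heel repair


def test_repair_identity_when_nothing_removed(rng):
    crop = _random_crop(rng)
    out = fa.repair_heel(crop, crop)
    assert np.array_equal(out.class_map, crop.class_map)


def test_repair_restores_lower_half_exactly(rng):
    crop = _random_crop(rng)
    cut = fa.circular_crop(crop, fa.Centroid(cx=20.0, cy=10.0), radius=15.0)
    out = fa.repair_heel(cut, crop)
    split = crop.class_map.shape[0] // 2
    assert np.array_equal(out.class_map[split:], crop.class_map[split:])
    assert np.array_equal(out.class_map[:split], cut.class_map[:split])
    assert out.class_map.shape == crop.class_map.shape


def test_repair_rejects_mismatched_dimensions(rng):
    a = _random_crop(rng)
    b = crop_from_labels(np.zeros((10, 10), dtype=np.uint8))
    with pytest.raises(fa.FootArchError):
        fa.repair_heel(a, b)


# ------------------------------------------------------------ binarization


def test_opening_preserves_solid_square():
    labels = np.zeros((30, 30), dtype=np.uint8)
    labels[5:25, 5:25] = int(P.P2)
    fp = fa.binarize_morph(crop_from_labels(labels))
    assert np.array_equal(fp.mask, labels > 0)


def test_opening_removes_isolated_pixel():
    labels = np.zeros((30, 30), dtype=np.uint8)
    labels[5:25, 5:25] = int(P.P2)
    labels[2, 28] = int(P.P4)  # lone speck
    fp = fa.binarize_morph(crop_from_labels(labels))
    assert not fp.mask[2, 28]
    assert fp.mask.sum() == 400


def test_perimeter_pixels_are_excluded():
    labels = np.zeros((30, 30), dtype=np.uint8)
    labels[5:25, 5:25] = int(P.PERIMETER)
    with pytest.raises(fa.EmptyFootprintError):
        fa.binarize_morph(crop_from_labels(labels))


def test_opening_is_idempotent(rng):
    for _ in range(10):
        crop = _random_crop(rng, shape=(60, 45))
        once = fa.binarize_morph(crop)
        relabeled = crop_from_labels(
            np.where(once.mask, int(P.P3), 0).astype(np.uint8)
        )
        twice = fa.binarize_morph(relabeled)
        assert np.array_equal(once.mask, twice.mask)
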