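"""Gray conversion, thresholding, particle extraction and morphometry."""

import numpy as np
import pytest

from marbliq.imaging import (
    CalibratedImage,
    anchored_threshold,
    extract_marbling,
    measure_morphometry,
    otsu_threshold,
    rle_decode,
    rle_encode,
    to_gray8,
)


def _gray(pixels, mm=0.1):
    return CalibratedImage(np.asarray(pixels, dtype=np.uint8), mm)


# ---------------------------------------------------------------------------
# gray conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rgb,expected",
    [((255, 255, 255), 255), ((0, 0, 0), 0), ((255, 0, 0), 76), ((0, 255, 0), 150)],
)
def test_to_gray8_luma_weights(rgb, expected):
    img = CalibratedImage(np.full((2, 2, 3), rgb, dtype=np.uint8), 0.1)
    gray = to_gray8(img)
    assert gray.is_gray
    assert gray.mm_per_px == img.mm_per_px
    assert np.all(gray.pixels == expected)


def test_to_gray8_identity_on_gray_input():
    img = _gray(np.arange(16).reshape(4, 4))
    assert to_gray8(img) is img


def test_calibrated_image_rejects_bad_input():
    with pytest.raises(ValueError):
        CalibratedImage(np.zeros((2, 2, 4), dtype=np.uint8), 0.1)
    with pytest.raises(ValueError):
        CalibratedImage(np.zeros((2, 2), dtype=np.uint8), 0.0)
    with pytest.raises(ValueError):
        CalibratedImage(np.zeros((0, 2), dtype=np.uint8), 0.1)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_anchored_threshold_min_rule():
    px = np.full((5, 5), 100, dtype=np.uint8)
    px[1, 1], px[2, 2], px[3, 3] = 200, 210, 190
    img = _gray(px)
    roi = np.ones((5, 5), dtype=bool)
    anchors = [(1, 1), (2, 2), (3, 3)]
    assert anchored_threshold(img, roi, anchors) == 190
    assert anchored_threshold(img, roi, anchors, margin=5) == 185


def test_anchored_threshold_rejects_bad_anchors():
    img = _gray(np.zeros((5, 5)))
    roi = np.zeros((5, 5), dtype=bool)
    roi[1:4, 1:4] = True
    with pytest.raises(ValueError):
        anchored_threshold(img, roi, [(0, 0)])
    with pytest.raises(ValueError):
        anchored_threshold(img, roi, [])


def _brute_force_otsu(values):
    """Maximize between-class variance over all 256 candidate thresholds
    with the >= binarization convention."""
    values = np.asarray(values, dtype=float)
    best_t, best_var = None, -1.0
    for t in range(256):
        lo, hi = values[values < t], values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / values.size, hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def test_otsu_matches_brute_force_oracle(rng):
    for _ in range(20):
        px = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        roi = rng.random((12, 12)) < 0.7
        if roi.sum() < 4 or np.unique(px[roi]).size < 2:
            continue
        img = _gray(px)
        t = otsu_threshold(img, roi)
        vals = px[roi]
        brute = _brute_force_otsu(vals)
        # accept any threshold achieving the maximal between-class variance
        def var_of(t):
            lo, hi = vals[vals < t], vals[vals >= t]
            if lo.size == 0 or hi.size == 0:
                return -1.0
            return lo.size * hi.size / vals.size**2 * (lo.mean() - hi.mean()) ** 2
        assert var_of(t) == pytest.approx(var_of(brute), rel=1e-12)


def test_otsu_separates_two_modes():
    px = np.where(np.arange(100).reshape(10, 10) < 50, 50, 200).astype(np.uint8)
    t = otsu_threshold(_gray(px), np.ones((10, 10), dtype=bool))
    assert 50 < t <= 200


def test_otsu_recovers_planted_flecks(clean_cutlet):
    image, truth = clean_cutlet
    t = otsu_threshold(image, truth.roi_mask)
    assert np.all(image.pixels[truth.fleck_mask] >= t)


def test_otsu_uniform_roi_errors():
    with pytest.raises(ValueError):
        otsu_threshold(_gray(np.full((5, 5), 7)), np.ones((5, 5), dtype=bool))


# ---------------------------------------------------------------------------
# particle extraction
# ---------------------------------------------------------------------------

def test_min_particle_filter_is_inclusive_at_10():
    px = np.zeros((30, 30), dtype=np.uint8)
    px[1, 1:10] = 255          # 9 px  -> removed
    px[5, 1:11] = 255          # 10 px -> kept
    px[10:13, 1:6] = 255       # 15 px -> kept
    res = extract_marbling(_gray(px), np.ones((30, 30), dtype=bool), threshold=128)
    assert res.n_particles == 2
    assert sorted(res.particle_areas_px) == [10, 15]


def test_all_below_threshold_gives_empty_result():
    px = np.full((10, 10), 40, dtype=np.uint8)
    res = extract_marbling(_gray(px), np.ones((10, 10), dtype=bool), threshold=100)
    assert res.n_particles == 0
    assert res.marb_area_pct == 0.0
    assert res.marb_area_mm2 == 0.0


def _flood_fill_components(binary, connectivity=8):
    """Independent component oracle: iterative stack-based flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    areas = []
    H, W = binary.shape
    for r0 in range(H):
        for c0 in range(W):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            stack, area = [(r0, c0)], 0
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                area += 1
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W and binary[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            areas.append(area)
    return sorted(areas)


@pytest.mark.parametrize("connectivity", [4, 8])
def test_labeling_agrees_with_flood_fill_oracle(rng, connectivity):
    for _ in range(100):
        mask = rng.random((20, 20)) < 0.35
        px = np.where(mask, 255, 0).astype(np.uint8)
        res = extract_marbling(
            _gray(px), np.ones((20, 20), dtype=bool),
            threshold=128, min_particle_px=1, connectivity=connectivity,
        )
        assert sorted(res.particle_areas_px) == _flood_fill_components(mask, connectivity)


def test_raising_threshold_never_increases_marbling(clean_cutlet):
    image, truth = clean_cutlet
    pcts = [
        extract_marbling(image, truth.roi_mask, t).marb_area_pct
        for t in range(0, 256, 16)
    ]
    assert all(a >= b for a, b in zip(pcts, pcts[1:]))


def test_extract_marbling_invariants(clean_cutlet):
    image, truth = clean_cutlet
    res = extract_marbling(image, truth.roi_mask, 150)
    assert res.n_particles == len(res.particle_areas_px)
    total = sum(res.particle_areas_px)
    assert res.marb_area_mm2 == pytest.approx(total * image.mm_per_px**2)
    assert res.marb_area_pct == pytest.approx(100 * total / truth.roi_mask.sum())


def test_extract_marbling_errors(clean_cutlet):
    image, truth = clean_cutlet
    with pytest.raises(ValueError):
        extract_marbling(image, np.zeros_like(truth.roi_mask), 100)
    with pytest.raises(ValueError):
        extract_marbling(image, truth.roi_mask, 300)


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

def test_morphometry_closed_form_rectangle():
    roi = np.zeros((80, 120), dtype=bool)
    roi[10:60, 5:105] = True  # 50 rows x 100 cols
    m = measure_morphometry(roi, None, mm_per_px=0.1)
    assert m.width_cm == pytest.approx(1.0)
    assert m.height_cm == pytest.approx(0.5)
    assert m.rea_cm2 == pytest.approx(0.5)
    assert m.bft_cm == 0.0


def test_bft_from_uniform_band():
    roi = np.zeros((60, 40), dtype=bool)
    roi[40:55, 5:35] = True
    band = np.zeros((60, 40), dtype=bool)
    band[5:35, 10:30] = True  # 30 px vertical run
    m = measure_morphometry(roi, band, mm_per_px=0.1)
    assert m.bft_cm == pytest.approx(0.3)


def test_morphometry_matches_generator_truth(clean_cutlet):
    _, truth = clean_cutlet
    m = measure_morphometry(truth.roi_mask, truth.fat_band_mask, truth.mm_per_px)
    assert m.rea_cm2 == pytest.approx(truth.roi_mask.sum() * truth.mm_per_px**2 / 100)
    assert m.rea_cm2 <= m.width_cm * m.height_cm


def test_scale_equivariance(clean_cutlet):
    image, truth = clean_cutlet
    doubled = CalibratedImage(image.pixels, 2 * image.mm_per_px)
    r1 = extract_marbling(image, truth.roi_mask, 150)
    r2 = extract_marbling(doubled, truth.roi_mask, 150)
    assert r2.marb_area_mm2 == pytest.approx(4 * r1.marb_area_mm2)
    assert r2.marb_area_pct == pytest.approx(r1.marb_area_pct)
    m1 = measure_morphometry(truth.roi_mask, truth.fat_band_mask, truth.mm_per_px)
    m2 = measure_morphometry(truth.roi_mask, truth.fat_band_mask, 2 * truth.mm_per_px)
    assert m2.rea_cm2 == pytest.approx(4 * m1.rea_cm2)


def test_morphometry_empty_roi_errors():
    with pytest.raises(ValueError):
        measure_morphometry(np.zeros((5, 5), dtype=bool), None, 0.1)


def test_rle_roundtrip(rng):
    for _ in range(10):
        mask = rng.random((17, 23)) < rng.uniform(0.1, 0.9)
        assert np.array_equal(rle_decode(rle_encode(mask)), mask)
    empty = np.zeros((4, 4), dtype=bool)
    assert np.array_equal(rle_decode(rle_encode(empty)), empty)
    full = np.ones((4, 4), dtype=bool)
    assert np.array_equal(rle_decode(rle_encode(full)), full)
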