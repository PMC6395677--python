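"""BM extraction stages: thresholding, reconstruction, thinning, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from octchoroid.bm import (
    binarize,
    connectivity_number,
    fit_bm_curve,
    reconstruct,
    segment_bm,
    select_rows,
    skeleton_to_points,
    thin,
)
from octchoroid.datatypes import (
    BScanImage,
    ParameterError,
    SegmentationError,
)
from octchoroid.phantom import PhantomParams, generate_scan


def image_of(arr):
    return BScanImage(pixels=np.asarray(arr, dtype=np.uint8))


# ---- binarize ---------------------------------------------------------------


def test_binarize_all_zero_image_gives_empty_mask():
    img = image_of(np.zeros((64, 64)))
    assert binarize(img, 190).sum() == 0


def test_binarize_threshold_value_is_foreground_and_255_included():
    px = np.zeros((64, 64))
    px[0, 0] = 190
    px[0, 1] = 189
    px[0, 2] = 255
    mask = binarize(image_of(px), 190)
    assert mask[0, 0] == 1 and mask[0, 1] == 0 and mask[0, 2] == 1


def test_binarize_foreground_count_monotone_in_threshold():
    rng = np.random.default_rng(0)
    img = image_of(rng.integers(0, 256, (64, 64)))
    counts = [binarize(img, t).sum() for t in range(1, 255)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


@pytest.mark.parametrize("t", [0, 255, -3, 400])
def test_binarize_rejects_out_of_range_threshold(t):
    with pytest.raises(ParameterError):
        binarize(image_of(np.zeros((64, 64))), t)


# ---- reconstruct ------------------------------------------------------------


def test_reconstruct_removes_isolated_pixel():
    px = np.zeros((64, 64))
    px[30, 30] = 250
    img = image_of(px)
    mask = binarize(img, 190)
    assert reconstruct(mask, img).sum() == 0


def test_reconstruct_drops_components_on_constant_image():
    """On a constant image the local background criterion equals the
    image (erosion = dilation = c), so no component is brighter than its
    background and everything is discarded."""
    img = image_of(np.full((64, 64), 200))
    mask = np.zeros((64, 64), dtype=np.uint8)
    mask[10:20, 10:40] = 1
    assert reconstruct(mask, img).sum() == 0


def test_reconstruct_keeps_bm_band_and_removes_speckle(easy_scan):
    img = easy_scan.image
    mask = binarize(img, 190)
    cleaned = reconstruct(mask, img)
    centre = np.rint(easy_scan.bm_truth.rows).astype(int)
    cols = np.arange(img.cols)
    # the band core survives
    assert cleaned[centre, cols].mean() > 0.9
    # speckle foreground (anything > 5 px away from the band) mostly removed
    rows = np.arange(img.rows)[:, None]
    off_band = np.abs(rows - easy_scan.bm_truth.rows[None, :]) > 5
    before = int((mask & off_band).sum())
    after = int((cleaned & off_band).sum())
    assert before > 0
    assert after <= 0.1 * before


def test_reconstruct_rejects_dim_mismatch(easy_scan):
    with pytest.raises(ParameterError):
        reconstruct(np.zeros((10, 10), dtype=np.uint8), easy_scan.image)


# ---- select_rows ------------------------------------------------------------


def test_select_rows_keeps_contained_band_and_drops_stray():
    mask = np.zeros((200, 50), dtype=np.uint8)
    mask[140:161] = 1
    assert np.array_equal(select_rows(mask), mask)
    stray = mask.copy()
    stray[190, 10] = 1
    out = select_rows(stray)
    assert out[190, 10] == 0
    assert np.array_equal(out, mask)


def test_select_rows_empty_mask_raises():
    with pytest.raises(SegmentationError):
        select_rows(np.zeros((10, 10), dtype=np.uint8))


# ---- connectivity number ----------------------------------------------------


def oracle_connectivity(block):
    """Independent literal transcription of the cyclic arc-count formula:
    C_n = sum over k in {1,3,5,7} of N_k - N_k*N_{k+1}*N_{k+2}, neighbours
    numbered counter-clockwise from the right, N_9 = N_1."""
    offs = {1: (0, 1), 2: (-1, 1), 3: (-1, 0), 4: (-1, -1),
            5: (0, -1), 6: (1, -1), 7: (1, 0), 8: (1, 1)}

    def N(k):
        w = ((k - 1) % 8) + 1
        dr, dc = offs[w]
        return int(block[1 + dr][1 + dc])

    total = 0
    for k in (1, 3, 5, 7):
        total += N(k) - N(k) * N(k + 1) * N(k + 2)
    return total


def test_connectivity_number_simple_cases():
    empty = np.zeros((3, 3), dtype=int)
    empty[1, 1] = 1
    assert connectivity_number(empty) == 0
    one = empty.copy()
    one[1, 2] = 1  # single neighbour at N1
    assert connectivity_number(one) == 1


def test_connectivity_number_matches_oracle_exhaustively():
    for code in range(256):
        block = np.zeros((3, 3), dtype=int)
        block[1, 1] = 1
        offs = [(0, 1), (-1, 1), (-1, 0), (-1, -1),
                (0, -1), (1, -1), (1, 0), (1, 1)]
        for bit, (dr, dc) in enumerate(offs):
            block[1 + dr, 1 + dc] = (code >> bit) & 1
        assert connectivity_number(block) == oracle_connectivity(block)
        assert 0 <= connectivity_number(block) <= 4


def test_connectivity_number_rejects_bad_blocks():
    with pytest.raises(ParameterError):
        connectivity_number(np.zeros((4, 3), dtype=int))
    with pytest.raises(ParameterError):
        connectivity_number(np.full((3, 3), 2))


# ---- thinning ---------------------------------------------------------------


def test_thick_bar_thins_to_single_row_spanning_all_columns():
    bar = np.zeros((20, 100), dtype=np.uint8)
    bar[8:13] = 1
    out = thin(bar)
    assert np.array_equal(out.sum(axis=0), np.ones(100, dtype=np.uint8))


def test_thin_is_idempotent_on_lines_and_random_masks():
    line = np.zeros((10, 30), dtype=np.uint8)
    line[5] = 1
    assert np.array_equal(thin(line), line)
    rng = np.random.default_rng(1)
    for _ in range(10):
        m = (rng.random((10, 14)) < 0.4).astype(np.uint8)
        t = thin(m)
        assert np.array_equal(thin(t), t)


def test_thin_preserves_component_count():
    s8 = np.ones((3, 3), dtype=int)
    rng = np.random.default_rng(2)
    for _ in range(30):
        m = (rng.random((12, 16)) < 0.45).astype(np.uint8)
        t = thin(m)
        assert ndimage.label(m, s8)[1] == ndimage.label(t, s8)[1]


def test_thin_empty_mask_passes_through():
    z = np.zeros((5, 5), dtype=np.uint8)
    assert np.array_equal(thin(z), z)


# ---- skeleton to knots ------------------------------------------------------


def test_skeleton_points_single_row_and_median_ties():
    skel = np.zeros((200, 30), dtype=np.uint8)
    skel[150, :] = 1
    knots = skeleton_to_points(skel)
    assert knots == [(c, 150.0) for c in range(30)]
    skel[149, 4] = 1
    skel[151, 4] = 1
    knots = dict(skeleton_to_points(skel))
    assert knots[4] == 150.0  # median of {149, 150, 151}
    two = np.zeros((200, 30), dtype=np.uint8)
    two[149, :] = 1
    two[151, :] = 1
    assert dict(skeleton_to_points(two))[0] == 150.0


def test_skeleton_points_needs_four_columns():
    skel = np.zeros((10, 10), dtype=np.uint8)
    skel[5, :3] = 1
    with pytest.raises(SegmentationError):
        skeleton_to_points(skel)


# ---- spline fitting ---------------------------------------------------------


def test_spline_reproduces_constant_and_linear_knots():
    knots = [(c, 150.0) for c in range(0, 100, 2)]
    curve = fit_bm_curve(knots, 100)
    assert np.abs(curve.rows - 150.0).max() < 1e-6
    knots = [(c, 100.0 + 0.05 * c) for c in range(0, 100, 2)]
    curve = fit_bm_curve(knots, 100)
    expected = 100.0 + 0.05 * np.arange(100)
    assert np.abs(curve.rows - expected).max() < 1e-6


def test_spline_interpolates_retained_knots():
    rng = np.random.default_rng(3)
    cols = np.arange(0, 300, 3)
    rows = 150 + 5 * np.sin(cols / 40.0) + rng.normal(0, 0.2, cols.size)
    knots = list(zip(cols.tolist(), rows.tolist()))
    curve = fit_bm_curve(knots, 300, knot_stride=10)
    retained = knots[::10] + [knots[-1]]
    for c, r in retained:
        assert abs(curve.rows[c] - r) < 1e-6


def test_spline_requires_four_knots():
    with pytest.raises(SegmentationError):
        fit_bm_curve([(0, 1.0), (1, 1.0), (2, 1.0)], 10)


# ---- full pipeline ----------------------------------------------------------


def test_segment_bm_recovers_truth_on_easy_phantom(easy_scan):
    curve = segment_bm(easy_scan.image)
    mae = np.abs(curve.rows - easy_scan.bm_truth.rows).mean()
    assert mae <= 2.0


def test_segment_bm_recovers_truth_on_hard_phantom():
    scan = generate_scan(PhantomParams(seed=21, contrast="hard"), 0)
    curve = segment_bm(scan.image)
    assert np.abs(curve.rows - scan.bm_truth.rows).mean() <= 5.0


def test_segment_bm_dark_image_raises_bm_not_found():
    img = BScanImage(pixels=np.full((100, 100), 120, dtype=np.uint8))
    with pytest.raises(SegmentationError, match="BM"):
        segment_bm(img)


def test_segment_bm_is_deterministic(easy_scan):
    a = segment_bm(easy_scan.image)
    b = segment_bm(easy_scan.image)
    assert np.array_equal(a.rows, b.rows)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(t=st.integers(min_value=1, max_value=254))
def test_binarize_partitions_pixels_exactly_at_threshold(t):
    rng = np.random.default_rng(17)
    px = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    mask = binarize(image_of(px), t)
    assert np.array_equal(mask == 1, px >= t)
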