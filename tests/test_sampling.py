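"""Patch enumeration, masking, labeling and class balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octchoroid.config import PipelineConfig
from octchoroid.datatypes import BScanImage, BoundaryCurve, ParameterError
from octchoroid.phantom import generate_volume
from octchoroid.sampling import (
    LabeledPatch,
    balance,
    black_fraction_filter,
    enumerate_patches,
    grid_count,
    label_patch,
    mask_above_bm,
    sample_dataset,
)


def image_of(arr):
    return BScanImage(pixels=np.asarray(arr, dtype=np.uint8))


# ---- masking ----------------------------------------------------------------


def test_mask_with_zero_curve_leaves_image_unchanged():
    rng = np.random.default_rng(0)
    img = image_of(rng.integers(1, 256, (80, 90)))
    out = mask_above_bm(img, BoundaryCurve(np.zeros(90)))
    assert np.array_equal(out.pixels, img.pixels)


def test_mask_with_bottom_curve_blacks_everything():
    img = image_of(np.full((80, 90), 200))
    out = mask_above_bm(img, BoundaryCurve(np.full(90, 80.0)))
    assert out.pixels.sum() == 0


def test_masked_columns_start_at_ceil_of_curve(small_scan):
    out = mask_above_bm(small_scan.image, small_scan.bm_truth)
    first_nonzero = np.argmax(out.pixels > 0, axis=0)
    assert np.all(first_nonzero >= np.ceil(small_scan.bm_truth.rows) - 1e-9)


def test_mask_rejects_width_mismatch(small_scan):
    with pytest.raises(ParameterError):
        mask_above_bm(small_scan.image, BoundaryCurve(np.zeros(10)))


# ---- enumeration ------------------------------------------------------------


def test_grid_matches_expected_counts_on_nominal_scan():
    img = image_of(np.zeros((456, 760)))
    origins = enumerate_patches(img, 32, 5)
    assert len(origins) == 12410
    assert grid_count(760, 32, 5) == 146
    assert grid_count(456, 32, 5) == 85


def test_single_origin_when_patch_equals_image():
    img = image_of(np.zeros((64, 64)))
    assert enumerate_patches(img, 64, 5) == [(0, 0)]


def test_origins_are_row_major_and_increasing():
    img = image_of(np.zeros((70, 70)))
    origins = enumerate_patches(img, 32, 5)
    assert origins == sorted(origins)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    rows=st.integers(64, 200),
    cols=st.integers(64, 200),
    patch=st.integers(8, 64),
    stride=st.integers(1, 11),
)
def test_grid_count_closed_form_matches_brute_force(rows, cols, patch, stride):
    brute_r = len([t for t in range(0, rows, 1) if t % stride == 0 and t + patch <= rows])
    brute_c = len([t for t in range(0, cols, 1) if t % stride == 0 and t + patch <= cols])
    assert grid_count(rows, patch, stride) == brute_r
    assert grid_count(cols, patch, stride) == brute_c


# ---- black fraction filter --------------------------------------------------


def test_black_fraction_boundary_at_342_of_1024():
    patch = np.ones((32, 32), dtype=np.uint8)
    flat = patch.reshape(-1)
    flat[:341] = 0
    assert black_fraction_filter(patch)          # 341 zeros: keep
    flat[341] = 0
    assert not black_fraction_filter(patch)      # 342 zeros: discard
    assert not black_fraction_filter(np.zeros((32, 32)))
    assert black_fraction_filter(np.ones((32, 32)))


# ---- labeling ---------------------------------------------------------------


def test_label_from_flat_truth_curve():
    truth = BoundaryCurve(np.full(100, 260.0), "choroid")
    assert label_patch((240, 0), 32, truth) == 1     # rows [240, 272) contain 260
    assert label_patch((0, 0), 32, truth) == 0
    assert label_patch((261, 0), 32, truth) == 0     # window starts below the line


def test_label_1_origins_form_contiguous_vertical_runs():
    cols = np.arange(200)
    truth = BoundaryCurve(60.0 + 0.3 * cols, "choroid")
    for left in range(0, 169, 8):
        labels = [label_patch((top, left), 32, truth) for top in range(0, 120)]
        ones = [i for i, v in enumerate(labels) if v == 1]
        assert ones, "monotone curve must intersect some window"
        assert ones == list(range(ones[0], ones[-1] + 1))


# ---- balancing --------------------------------------------------------------


def make_patches(n1, n0):
    rng = np.random.default_rng(0)
    mk = lambda lab: LabeledPatch(
        pixels=rng.integers(0, 256, (32, 32)).astype(np.uint8), label=lab
    )
    return [mk(1) for _ in range(n1)] + [mk(0) for _ in range(n0)]


def test_balance_equalizes_classes():
    out = balance(make_patches(10, 50), seed=1)
    assert len(out) == 20
    assert sum(p.label for p in out) == 10
    out = balance(make_patches(10, 10), seed=1)
    assert len(out) == 20


def test_balance_is_seeded():
    patches = make_patches(20, 200)
    a = balance(patches, seed=3)
    b = balance(patches, seed=3)
    assert [id(p) for p in a] == [id(p) for p in b]
    c = balance(patches, seed=4)
    assert [id(p) for p in a] != [id(p) for p in c]


def test_balance_without_positives_raises():
    with pytest.raises(ParameterError, match="on-line"):
        balance(make_patches(0, 5) or make_patches(0, 5), seed=0)


# ---- dataset sampling -------------------------------------------------------


def test_sample_dataset_yields_balanced_filtered_patches(small_params, config):
    vol = generate_volume(small_params, "s")
    patches, yields = sample_dataset([vol], config, seed=0)
    assert len(yields) == small_params.n_scans
    n1 = sum(p.label for p in patches)
    assert n1 * 2 == len(patches)
    # every emitted patch re-passes the black-fraction rule
    assert all(black_fraction_filter(p.pixels, config.black_fraction)
               for p in patches)


def test_sample_dataset_per_scan_yield_is_thousands_on_full_phantom(config):
    from octchoroid.phantom import PhantomParams

    vol = generate_volume(
        PhantomParams(seed=77, n_scans=1), "one"
    )
    patches, yields = sample_dataset([vol], config, seed=0)
    # order-of-magnitude check: one scan yields on the order of 10^3
    # balanced patches
    assert 300 <= len(patches) <= 30_000
    assert yields[0]["kept"] <= 12_410


def test_sample_dataset_empty_volume_list_raises(config):
    with pytest.raises(ParameterError):
        sample_dataset([], config, seed=0)


def test_sample_dataset_is_seeded(small_params, config):
    vol = generate_volume(small_params, "s")
    a, _ = sample_dataset([vol], config, seed=5, max_patches=100)
    b, _ = sample_dataset([vol], config, seed=5, max_patches=100)
    assert all(
        np.array_equal(x.pixels, y.pixels) and x.label == y.label
        for x, y in zip(a, b)
    )
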