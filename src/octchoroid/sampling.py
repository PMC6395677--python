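"""Patch sampling for classifier training.

Scans are first masked to black above the BM reference curve, then 32x32
windows are enumerated on a stride-5 grid in row-major order.  Windows
dominated by black pixels (more than a third) are discarded; the rest are
labeled 1 ("on-line") when they contain a pixel of the lower choroid
boundary and 0 otherwise, and the two classes are balanced by seeded
subsampling of the majority label-0 class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    AnnotatedScan,
    BScanImage,
    BoundaryCurve,
    OCTVolume,
    ParameterError,
)

logger = logging.getLogger("octchoroid.sampling")


@dataclass
class LabeledPatch:
    """A 32x32 pixel block with its on-line/off-line label and provenance."""

    pixels: np.ndarray          # (patch, patch) uint8
    label: int                  # 1 = contains the choroid boundary
    origin: tuple = (0, 0)      # (top row, left column) in the source scan
    source: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ParameterError("patch pixels must be 2-D")
        if self.label not in (0, 1):
            raise ParameterError(f"patch label must be 0 or 1, got {self.label}")


def mask_above_bm(image: BScanImage, bm: BoundaryCurve) -> BScanImage:
    """Zero all pixels strictly above the BM curve in every column."""
    if bm.width != image.cols:
        raise ParameterError("BM curve width does not match image width")
    rows = np.arange(image.rows)[:, None]
    out = np.where(rows < bm.rows[None, :], 0, image.pixels).astype(np.uint8)
    return BScanImage(
        pixels=out,
        scan_index=image.scan_index,
        lateral_scale=image.lateral_scale,
        axial_scale=image.axial_scale,
    )


def grid_count(length: int, patch: int, stride: int) -> int:
    """Closed-form number of window positions along one axis."""
    if patch > length:
        return 0
    return (length - patch) // stride + 1


def enumerate_patches(image: BScanImage, patch: int = 32, stride: int = 5):
    """All window origins on the stride grid, row-major (top-to-bottom,
    left-to-right), each window fully inside the image."""
    if patch > min(image.rows, image.cols):
        raise ParameterError("patch size exceeds image dimensions")
    tops = np.arange(0, image.rows - patch + 1, stride)
    lefts = np.arange(0, image.cols - patch + 1, stride)
    return [(int(t), int(l)) for t in tops for l in lefts]


def black_fraction_filter(pixels: np.ndarray, fraction: float = 1.0 / 3.0) -> bool:
    """True (keep) unless more than ``fraction`` of the pixels are black.

    Black means intensity exactly 0, as written by the BM mask.  For a
    32x32 window and fraction 1/3 the discard point is 342 zeros
    (341/1024 is kept, 342/1024 is discarded).
    """
    pixels = np.asarray(pixels)
    return np.count_nonzero(pixels == 0) <= fraction * pixels.size


def label_patch(origin, patch: int, choroid_truth: BoundaryCurve) -> int:
    """1 iff the rounded boundary row passes through the window."""
    top, left = origin
    cols = np.arange(left, left + patch)
    if cols[-1] >= choroid_truth.width:
        raise ParameterError("patch columns exceed truth-curve width")
    rounded = np.rint(choroid_truth.rows[cols])
    return int(np.any((rounded >= top) & (rounded < top + patch)))


def _scan_patches(scan: AnnotatedScan, config, use_truth_bm: bool = True):
    """Enumerate, filter and label every patch of one annotated scan.

    Vectorized: the black-pixel count per window comes from a 2-D summed
    table, and the label test from the rounded truth curve, so no window
    pixels are materialized here.
    """
    p, s = config.patch_size, config.stride
    masked = mask_above_bm(scan.image, scan.bm_truth)
    img = masked.pixels
    tops = np.arange(0, img.shape[0] - p + 1, s)
    lefts = np.arange(0, img.shape[1] - p + 1, s)

    # summed-area table of the black-pixel indicator
    black = (img == 0).astype(np.int32)
    sat = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(black, axis=0), axis=1, out=sat[1:, 1:])
    t, l = np.meshgrid(tops, lefts, indexing="ij")
    zeros = sat[t + p, l + p] - sat[t + p, l] - sat[t, l + p] + sat[t, l]
    keep = zeros <= config.black_fraction * (p * p)

    # label: does the rounded truth curve enter the window anywhere?
    rounded = np.rint(scan.choroid_truth.rows)
    # per column-stripe, min and max of the rounded curve over the 32 columns
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(rounded, p)[lefts]          # (n_lefts, p)
    in_window = (win[None, :, :] >= t[:, :, None]) & (
        win[None, :, :] < (t + p)[:, :, None]
    )
    labels = in_window.any(axis=2).astype(np.int8)

    return masked, t, l, keep, labels


def balance(patches, seed: int = 0):
    """Equalize class counts: keep all label-1 patches, subsample label-0
    without replacement to the same count, shuffle; all seeded."""
    ones = [p for p in patches if p.label == 1]
    zeros = [p for p in patches if p.label == 0]
    if not ones:
        raise ParameterError("no on-line patches to balance against")
    if not zeros:
        raise ParameterError("no off-line patches to balance against")
    rng = np.random.default_rng(seed)
    if len(zeros) > len(ones):
        idx = rng.choice(len(zeros), size=len(ones), replace=False)
        zeros = [zeros[i] for i in sorted(idx)]
    elif len(ones) > len(zeros):
        # off-line patches are normally the majority; when a scan yields
        # more on-line patches the same equalization applies in reverse
        idx = rng.choice(len(ones), size=len(zeros), replace=False)
        ones = [ones[i] for i in sorted(idx)]
    out = ones + zeros
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def sample_dataset(volumes, config, seed: int = 0, max_patches: int | None = None):
    """Sample, label and balance training patches from annotated volumes.

    Per scan: mask above the ground-truth BM, enumerate the stride grid,
    drop overly black windows, label from the ground-truth choroid curve.
    Classes are then balanced globally; if ``max_patches`` is given the
    balanced set is further subsampled (seeded, classes kept equal).
    Returns (patches, per-scan yield log).
    """
    if not volumes:
        raise ParameterError("no volumes to sample from")
    records = []  # (scan_ref, top, left, label)
    yields = []
    for vol in volumes:
        for scan in vol.scans:
            if not isinstance(scan, AnnotatedScan):
                raise ParameterError("sample_dataset needs annotated scans")
            masked, t, l, keep, labels = _scan_patches(scan, config)
            kept = int(keep.sum())
            pos = int((labels[keep] == 1).sum())
            name = f"{vol.subject_id}/scan_{scan.image.scan_index:02d}"
            yields.append(
                {"scan": name, "kept": kept, "on_line": pos, "off_line": kept - pos}
            )
            tt, ll = t[keep], l[keep]
            lab = labels[keep]
            records.append((masked, name, tt, ll, lab))
    logger.info(
        "sampled %d scans, %d patches kept",
        len(yields),
        sum(y["kept"] for y in yields),
    )

    # global balancing on (scan, origin, label) triples before extracting
    # pixel blocks, so memory stays proportional to the final set
    flat = []
    for masked, name, tt, ll, lab in records:
        for k in range(tt.size):
            flat.append((masked, name, int(tt[k]), int(ll[k]), int(lab[k])))
    ones = [f for f in flat if f[4] == 1]
    zeros = [f for f in flat if f[4] == 0]
    if not ones:
        raise ParameterError("no on-line patches in the dataset")
    rng = np.random.default_rng(seed)
    if len(zeros) > len(ones):
        idx = rng.choice(len(zeros), size=len(ones), replace=False)
        zeros = [zeros[i] for i in sorted(idx)]
    elif len(ones) > len(zeros):
        idx = rng.choice(len(ones), size=len(zeros), replace=False)
        ones = [ones[i] for i in sorted(idx)]
    if max_patches is not None and len(ones) + len(zeros) > max_patches:
        per_class = max_patches // 2
        keep1 = rng.choice(len(ones), size=per_class, replace=False)
        keep0 = rng.choice(len(zeros), size=per_class, replace=False)
        ones = [ones[i] for i in sorted(keep1)]
        zeros = [zeros[i] for i in sorted(keep0)]
    sel = ones + zeros
    order = rng.permutation(len(sel))
    p = config.patch_size
    patches = []
    for i in order:
        masked, name, top, left, lab = sel[i]
        block = masked.pixels[top : top + p, left : left + p]
        patches.append(
            LabeledPatch(pixels=block, label=lab, origin=(top, left), source=name)
        )
    logger.info(
        "balanced dataset: %d patches (%d per class)", len(patches), len(ones)
    )
    return patches, yields
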