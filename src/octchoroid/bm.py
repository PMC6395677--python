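"""Bruch's-membrane extraction by morphological operations.

The BM band is the brightest, most homogeneous structure in a macular
B-scan, so it can be isolated without learned statistics: binarize at a
fixed intensity threshold, clean the mask by a morphological
reconstruction step (3x3 opening plus a local-background component
filter), keep the dominant row band, thin the band to a one-pixel
skeleton using connectivity numbers, and fit a natural cubic spline
through the skeleton to obtain a full-width boundary curve.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .datatypes import (
    BScanImage,
    BoundaryCurve,
    ParameterError,
    SegmentationError,
)

#: 3x3 structuring element considering all eight neighbours of a pixel
STRUCTURING_ELEMENT = np.ones((3, 3), dtype=bool)

#: offsets of the eight neighbours N1..N8, counter-clockwise starting at
#: the pixel to the right (N1), in (row, col) with row 0 at the top
NEIGHBOR_OFFSETS = [
    (0, 1),    # N1 right
    (-1, 1),   # N2 upper-right
    (-1, 0),   # N3 up
    (-1, -1),  # N4 upper-left
    (0, -1),   # N5 left
    (1, -1),   # N6 lower-left
    (1, 0),    # N7 down
    (1, 1),    # N8 lower-right
]


def binarize(image: BScanImage, t_b: int = 190) -> np.ndarray:
    """Threshold a scan into a {0,1} foreground mask.

    A pixel is foreground iff ``t_b <= P(i,j) <= 255``.  Saturated pixels
    are kept: a bright-band detector must not discard them.
    """
    if not 0 < t_b < 255:
        raise ParameterError(f"threshold must lie in (0, 255), got {t_b}")
    return (image.pixels >= t_b).astype(np.uint8)


def reconstruct(mask: np.ndarray, image: BScanImage) -> np.ndarray:
    """Remove noise components from a thresholded mask.

    Two stages: (i) morphological opening with the 3x3 structuring
    element, which deletes speckle specks thinner than the element;
    (ii) for each surviving connected component, compare its mean
    grayscale intensity with the mean of the local background criterion
    R(x) = (erosion(f)(x) + dilation(f)(x)) / 2 over the component, and
    drop components not brighter than their local background.  The BM
    band itself survives both stages unchanged in shape.
    """
    mask = np.asarray(mask)
    if mask.shape != image.pixels.shape:
        raise ParameterError("mask and image dimensions differ")
    opened = ndimage.binary_opening(mask.astype(bool), structure=STRUCTURING_ELEMENT)
    if not opened.any():
        return opened.astype(np.uint8)

    f = image.pixels.astype(float)
    r_crit = (
        ndimage.grey_erosion(f, footprint=STRUCTURING_ELEMENT)
        + ndimage.grey_dilation(f, footprint=STRUCTURING_ELEMENT)
    ) / 2.0

    labels, n = ndimage.label(opened, structure=STRUCTURING_ELEMENT)
    idx = np.arange(1, n + 1)
    mean_f = ndimage.mean(f, labels, idx)
    mean_r = ndimage.mean(r_crit, labels, idx)
    keep = idx[mean_f > mean_r]
    out = np.isin(labels, keep) if keep.size else np.zeros_like(opened)
    return out.astype(np.uint8)


def select_rows(mask: np.ndarray, band_fraction: float = 0.10) -> np.ndarray:
    """Keep only the dominant contiguous row band of the mask.

    The per-row foreground histogram is peaked at the BM band; the band is
    grown contiguously around the peak while the per-row count stays at or
    above ``band_fraction`` of the peak count.  Everything outside the
    band is zeroed.
    """
    mask = np.asarray(mask).astype(np.uint8)
    counts = mask.sum(axis=1)
    if counts.sum() == 0:
        raise SegmentationError("BM not found: mask is empty")
    peak = int(np.argmax(counts))
    floor = band_fraction * counts[peak]
    top = peak
    while top > 0 and counts[top - 1] >= floor:
        top -= 1
    bottom = peak
    while bottom < mask.shape[0] - 1 and counts[bottom + 1] >= floor:
        bottom += 1
    out = np.zeros_like(mask)
    out[top : bottom + 1] = mask[top : bottom + 1]
    return out


def connectivity_number(neighborhood: np.ndarray) -> int:
    """Connectivity number C_n of the centre pixel of a 3x3 binary block.

    C_n = sum over k in {1,3,5,7} of N_k - N_k*N_{k+1}*N_{k+2}, with the
    neighbours numbered counter-clockwise from the right-hand pixel (N1)
    and indices wrapping (N9 = N1).  C_n counts the distinct foreground
    arcs touching the centre; deleting a pixel with C_n = 1 cannot split
    its neighbourhood.
    """
    block = np.asarray(neighborhood)
    if block.shape != (3, 3):
        raise ParameterError("neighborhood must be a 3x3 block")
    if not np.isin(block, (0, 1)).all():
        raise ParameterError("neighborhood must be binary")
    n = [int(block[1 + dr, 1 + dc]) for dr, dc in NEIGHBOR_OFFSETS]

    def at(k: int) -> int:  # 1-based with wrap-around
        return n[(k - 1) % 8]

    return sum(at(k) - at(k) * at(k + 1) * at(k + 2) for k in (1, 3, 5, 7))


def _neighbor_arrays(mask: np.ndarray):
    """Stacked neighbour planes N1..N8 for every pixel (zero-padded)."""
    padded = np.pad(mask, 1)
    planes = []
    for dr, dc in NEIGHBOR_OFFSETS:
        planes.append(padded[1 + dr : 1 + dr + mask.shape[0],
                             1 + dc : 1 + dc + mask.shape[1]])
    return np.stack(planes)  # (8, rows, cols)


def _arc_count(block: np.ndarray) -> int:
    """Number of distinct 8-connected foreground arcs around the centre.

    This is the complement (background) form of the same cyclic
    arc-counting sum used by :func:`connectivity_number`; unlike the
    foreground form it also sees arcs made of a single diagonal
    neighbour, which is what makes it a safe deletion criterion.
    """
    n = [int(block[1 + dr, 1 + dc]) for dr, dc in NEIGHBOR_OFFSETS]

    def bg(k: int) -> int:
        return 1 - n[(k - 1) % 8]

    return sum(bg(k) - bg(k) * bg(k + 1) * bg(k + 2) for k in (1, 3, 5, 7))


def thin(mask: np.ndarray) -> np.ndarray:
    """Thin a mask to a one-pixel skeleton without breaking or shortening it.

    Iterative two-subiteration boundary peel tailored to near-horizontal
    bands like BM: the first subiteration deletes north-border pixels,
    the second south-border pixels, so the band collapses onto its
    centreline without ever losing column coverage.  A pixel is deleted
    only when it lies on exactly one 8-connected foreground arc (removal
    cannot split the neighbourhood) and its foreground-neighbour count is
    in [2, 6] (isolated pixels and line endpoints are protected).
    Deletions inside a subiteration are sequential in raster order, so a
    two-pixel-thick line cannot vanish from both sides at once.  Passes
    repeat until a full pass deletes nothing.
    """
    work = (np.asarray(mask) > 0).astype(np.uint8)
    if not work.any():
        return work
    rows, cols = work.shape

    def pass_once(border_offset) -> int:
        # candidates computed from the current mask, then re-validated
        # sequentially as earlier deletions change the neighbourhood
        n = _neighbor_arrays(work)
        count = n.sum(axis=0)
        k = NEIGHBOR_OFFSETS.index(border_offset)
        cand = (work == 1) & (n[k] == 0) & (count >= 2) & (count <= 6)
        deleted = 0
        for rr, cc in zip(*np.nonzero(cand)):
            block = np.zeros((3, 3), dtype=np.uint8)
            r0, r1 = max(rr - 1, 0), min(rr + 2, rows)
            c0, c1 = max(cc - 1, 0), min(cc + 2, cols)
            block[r0 - rr + 1 : r1 - rr + 1, c0 - cc + 1 : c1 - cc + 1] = (
                work[r0:r1, c0:c1]
            )
            nb = block.sum() - block[1, 1]
            if nb < 2 or nb > 6:
                continue
            if _arc_count(block) != 1:
                continue
            work[rr, cc] = 0
            deleted += 1
        return deleted

    north, south = (-1, 0), (1, 0)
    while True:
        removed = pass_once(north)
        removed += pass_once(south)
        if removed == 0:
            return work


def skeleton_to_points(skeleton: np.ndarray):
    """Collapse a skeleton to one (column, row) knot per occupied column.

    The knot row is the median of the column's skeleton rows; columns with
    no skeleton pixel are omitted.  At least four knot columns are needed
    downstream for the cubic spline.
    """
    skeleton = np.asarray(skeleton)
    cols = np.nonzero(skeleton.any(axis=0))[0]
    if cols.size < 4:
        raise SegmentationError(
            f"BM skeleton covers only {cols.size} columns; need at least 4"
        )
    knots = []
    for c in cols:
        rows_c = np.nonzero(skeleton[:, c])[0]
        knots.append((int(c), float(np.median(rows_c))))
    return knots


def fit_bm_curve(knots, width: int, knot_stride: int = 10) -> BoundaryCurve:
    """Natural cubic spline through subsampled skeleton knots.

    Knots are subsampled every ``knot_stride`` columns (first and last
    always kept) so the spline does not chase speckle; the spline is
    evaluated at every column of the image, with linear extrapolation
    beyond the outermost knots.
    """
    if len(knots) < 4:
        raise SegmentationError("need at least 4 knots to fit the BM spline")
    knots = sorted(knots)
    xs = np.array([k[0] for k in knots], dtype=float)
    ys = np.array([k[1] for k in knots], dtype=float)
    if np.unique(xs).size != xs.size:
        raise ParameterError("knot columns must be distinct")
    keep = list(range(0, len(knots), max(knot_stride, 1)))
    if keep[-1] != len(knots) - 1:
        keep.append(len(knots) - 1)
    xs, ys = xs[keep], ys[keep]
    if xs.size < 4:  # fall back to all knots when subsampling leaves too few
        xs = np.array([k[0] for k in knots], dtype=float)
        ys = np.array([k[1] for k in knots], dtype=float)
    spline = CubicSpline(xs, ys, bc_type="natural")
    cols = np.arange(width, dtype=float)
    rows = spline(cols)
    # linear extrapolation beyond the outermost knots
    left = cols < xs[0]
    right = cols > xs[-1]
    rows[left] = ys[0] + spline(xs[0], 1) * (cols[left] - xs[0])
    rows[right] = ys[-1] + spline(xs[-1], 1) * (cols[right] - xs[-1])
    return BoundaryCurve(rows, layer_tag="bm")


def segment_bm(image: BScanImage, config=None) -> BoundaryCurve:
    """Full BM pipeline: threshold, reconstruct, erode, band-select, thin, fit.

    A final 3x3 erosion is applied after reconstruction so the band enters
    thinning as a slim core, then the skeleton is splined to a full-width
    curve.  The pipeline is fully deterministic.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    stage = "binarize"
    try:
        mask = binarize(image, cfg.threshold)
        stage = "reconstruct"
        mask = reconstruct(mask, image)
        stage = "erode"
        eroded = ndimage.binary_erosion(
            mask.astype(bool), structure=STRUCTURING_ELEMENT
        ).astype(np.uint8)
        if eroded.any():
            mask = eroded
        stage = "select_rows"
        mask = select_rows(mask, cfg.row_band_fraction)
        stage = "thin"
        skel = thin(mask)
        stage = "skeleton_to_points"
        knots = skeleton_to_points(skel)
        stage = "fit_bm_curve"
        curve = fit_bm_curve(knots, image.cols, cfg.knot_stride)
    except (SegmentationError, ParameterError) as exc:
        raise SegmentationError(f"BM segmentation failed at {stage}: {exc}") from exc
    rows = np.clip(curve.rows, 0, image.rows - 1e-6)
    return BoundaryCurve(rows, layer_tag="bm")
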