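"""Choroid boundary localization by sliding-window voting.

The trained patch classifier slides over the BM-masked scan on the same
stride-5 grid used for training; every patch predicted "on-line" casts a
+1 vote onto all pixels it covers in a counter matrix.  The per-column
argmax of the vote counts gives candidate boundary points, and a
least-squares cubic polynomial through those points yields the full-width
lower choroid boundary, clamped to lie strictly below BM.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    BScanImage,
    BoundaryCurve,
    ParameterError,
    SegmentationError,
)
from .sampling import mask_above_bm

logger = logging.getLogger("octchoroid.choroid")


def build_counter_matrix(image: BScanImage, bm: BoundaryCurve, model,
                         config=None) -> np.ndarray:
    """Accumulate votes from positively classified patches.

    The image is masked above BM; grid patches failing the black-fraction
    rule are discarded (they cast no vote), the rest are classified in
    batches, and each positive patch increments its 32x32 footprint in
    the counter matrix by one.  Increments use a difference array plus a
    2-D prefix sum, so the cost is independent of the patch area.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    if bm.width != image.cols:
        raise ParameterError("BM curve width does not match image width")
    p, s = cfg.patch_size, cfg.stride
    masked = mask_above_bm(image, bm)
    img = masked.pixels
    rows, cols = img.shape

    tops = np.arange(0, rows - p + 1, s)
    lefts = np.arange(0, cols - p + 1, s)
    t, l = np.meshgrid(tops, lefts, indexing="ij")
    t, l = t.ravel(), l.ravel()

    black = (img == 0).astype(np.int32)
    sat = np.zeros((rows + 1, cols + 1), dtype=np.int64)
    np.cumsum(np.cumsum(black, axis=0), axis=1, out=sat[1:, 1:])
    zeros = sat[t + p, l + p] - sat[t + p, l] - sat[t, l + p] + sat[t, l]
    keep = zeros <= cfg.black_fraction * (p * p)
    t, l = t[keep], l[keep]

    counter = np.zeros((rows, cols), dtype=np.int32)
    if t.size == 0:
        return counter

    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(img, (p, p))
    diff = np.zeros((rows + 1, cols + 1), dtype=np.int32)
    batch = 512
    n_pos = 0
    for i in range(0, t.size, batch):
        tb, lb = t[i : i + batch], l[i : i + batch]
        labels, _ = model.predict(windows[tb, lb], batch_size=64)
        pos = labels == 1
        n_pos += int(pos.sum())
        np.add.at(diff, (tb[pos], lb[pos]), 1)
        np.add.at(diff, (tb[pos] + p, lb[pos] + p), 1)
        np.add.at(diff, (tb[pos], lb[pos] + p), -1)
        np.add.at(diff, (tb[pos] + p, lb[pos]), -1)
    counter = diff.cumsum(axis=0).cumsum(axis=1)[:rows, :cols].astype(np.int32)
    logger.debug("counter matrix: %d/%d patches voted", n_pos, t.size)
    return counter


def extract_boundary_points(counter: np.ndarray):
    """Per-column argmax of the vote counts.

    Ties resolve to the smallest row (numpy argmax); columns whose
    maximum is zero carry no evidence and are omitted.
    """
    counter = np.asarray(counter)
    best = counter.argmax(axis=0)
    maxval = counter[best, np.arange(counter.shape[1])]
    cols = np.nonzero(maxval > 0)[0]
    if cols.size == 0:
        raise SegmentationError("no choroid evidence: counter matrix is empty")
    return [(int(c), int(best[c])) for c in cols]


def fit_choroid_curve(points, width: int, n_rows: int | None = None) -> BoundaryCurve:
    """Least-squares cubic polynomial through (column, row) vote peaks."""
    if len(points) < 4:
        raise SegmentationError(
            f"need at least 4 boundary points for the cubic fit, got {len(points)}"
        )
    xs = np.array([pt[0] for pt in points], dtype=float)
    ys = np.array([pt[1] for pt in points], dtype=float)
    if np.unique(xs).size < 4:
        raise SegmentationError("need at least 4 distinct columns for the cubic fit")
    # centre/scale the abscissa for conditioning; the fit is still an
    # ordinary degree-3 least squares in the original variable
    x0, xs_scale = xs.mean(), max(xs.std(), 1.0)
    coeffs = np.polyfit((xs - x0) / xs_scale, ys, deg=3)
    cols = np.arange(width, dtype=float)
    rows = np.polyval(coeffs, (cols - x0) / xs_scale)
    if n_rows is not None:
        rows = np.clip(rows, 0, n_rows - 1e-6)
    return BoundaryCurve(rows, layer_tag="choroid")


def segment_choroid(image: BScanImage, bm: BoundaryCurve, model,
                    config=None) -> BoundaryCurve:
    """Full choroid stage: vote, take column maxima, fit the cubic, and
    clamp the result to at least one pixel below BM."""
    counter = build_counter_matrix(image, bm, model, config)
    points = extract_boundary_points(counter)
    curve = fit_choroid_curve(points, image.cols, image.rows)
    floor = np.clip(bm.rows + 1, 0, image.rows - 1e-6)
    clamped = np.maximum(curve.rows, floor)
    n_clamped = int((curve.rows < floor).sum())
    if n_clamped:
        logger.info("choroid curve clamped below BM at %d columns", n_clamped)
    return BoundaryCurve(clamped, layer_tag="choroid")
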