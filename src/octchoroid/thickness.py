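"""Choroidal thickness maps.

Per scan, thickness is the per-column vertical distance between the
lower choroid boundary and BM (the curves are functions of column, so
vertical distance is the natural surface distance).  Stacking the 25
per-scan thickness rows gives a 25 x width en-face matrix; the physical
rendering scales pixels to microns with 200 um per 76 axial px, 200 um
per 25 lateral px and a 240 um slow-axis scan spacing, so the nominal
25 x 760 matrix spans 5760 um x 6080 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    AXIAL_UM_PER_PX,
    LATERAL_UM_PER_PX,
    SCAN_SPACING_UM,
    BoundaryCurve,
    ParameterError,
)

#: fixed colormap for rendered maps, so runs stay visually comparable
COLORMAP = "viridis"


def column_thickness(bm: BoundaryCurve, choroid: BoundaryCurve) -> np.ndarray:
    """Per-column thickness choroid(c) - bm(c), in pixels."""
    if bm.width != choroid.width:
        raise ParameterError("curve widths differ")
    t = choroid.rows - bm.rows
    neg = np.nonzero(t < 0)[0]
    if neg.size:
        raise ParameterError(
            f"choroid boundary above BM at column {int(neg[0])}"
        )
    return t


@dataclass
class ThicknessMap:
    """Per-subject en-face thickness matrix with physical scaling."""

    pixel_units: np.ndarray            # (n_scans, width), px
    axial_um_per_px: float = AXIAL_UM_PER_PX
    lateral_um_per_px: float = LATERAL_UM_PER_PX
    scan_spacing_um: float = SCAN_SPACING_UM
    subject_id: str = ""

    def __post_init__(self):
        self.pixel_units = np.asarray(self.pixel_units, dtype=float)
        if self.pixel_units.ndim != 2:
            raise ParameterError("thickness matrix must be 2-D")
        if (self.pixel_units < 0).any():
            raise ParameterError("thickness values must be non-negative")

    @property
    def micron_units(self) -> np.ndarray:
        return self.pixel_units * self.axial_um_per_px

    @property
    def slow_axis_extent_um(self) -> float:
        """(n_scans - 1) * spacing."""
        return (self.pixel_units.shape[0] - 1) * self.scan_spacing_um

    @property
    def fast_axis_extent_um(self) -> float:
        """width * lateral scale."""
        return self.pixel_units.shape[1] * self.lateral_um_per_px


def build_map(curve_pairs, config=None, subject_id: str = "") -> ThicknessMap:
    """Assemble a thickness map from per-scan (bm, choroid) curve pairs.

    ``curve_pairs`` may be a list or a dict keyed by scan index; with a
    dict, missing indices in range(max+1) are reported.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    if isinstance(curve_pairs, dict):
        n = max(curve_pairs) + 1
        missing = [k for k in range(n) if k not in curve_pairs]
        if missing:
            raise ParameterError(f"missing scans at indices {missing}")
        pairs = [curve_pairs[k] for k in range(n)]
    else:
        pairs = list(curve_pairs)
    if not pairs:
        raise ParameterError("no curve pairs")
    widths = {bm.width for bm, _ in pairs}
    if len(widths) != 1:
        raise ParameterError("inconsistent curve widths across scans")
    matrix = np.stack([column_thickness(bm, ch) for bm, ch in pairs])
    return ThicknessMap(
        pixel_units=matrix,
        axial_um_per_px=cfg.axial_um_per_px,
        lateral_um_per_px=cfg.lateral_um_per_px,
        scan_spacing_um=cfg.scan_spacing_um,
        subject_id=subject_id,
    )


def render_map(tmap: ThicknessMap, out_prefix) -> dict:
    """Write ``<prefix>.thickness.csv`` (micron matrix) and
    ``<prefix>.thickness.png`` (colormapped raster resampled to the
    physical slow:fast aspect ratio).  Returns the written paths."""
    import io
    import os

    import matplotlib as mpl
    from PIL import Image

    from ._util import atomic_write_bytes, atomic_write_text

    out_prefix = os.fspath(out_prefix)
    csv_path = out_prefix + ".thickness.csv"
    png_path = out_prefix + ".thickness.png"

    micron = tmap.micron_units
    lines = "\n".join(",".join(f"{v:.6f}" for v in row) for row in micron)
    atomic_write_text(csv_path, lines + "\n")

    lo, hi = float(micron.min()), float(micron.max())
    norm = np.zeros_like(micron) if hi == lo else (micron - lo) / (hi - lo)
    rgba = (mpl.colormaps[COLORMAP](norm)[:, :, :3] * 255).astype(np.uint8)
    # resample to the physical aspect ratio (slow axis : fast axis)
    fast = max(int(round(tmap.fast_axis_extent_um / 10.0)), 1)
    slow = max(int(round(tmap.slow_axis_extent_um / 10.0)), 1)
    img = Image.fromarray(rgba).resize((fast, slow), Image.BILINEAR)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    atomic_write_bytes(png_path, buf.getvalue())
    return {"csv": csv_path, "png": png_path}


def read_map_csv(path) -> np.ndarray:
    """Reload a rendered micron-unit matrix."""
    return np.loadtxt(path, delimiter=",", ndmin=2)
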