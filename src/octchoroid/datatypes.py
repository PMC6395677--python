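"""Core domain containers shared across the pipeline.

Coordinate convention (fixed project-wide): row 0 is the top of a B-scan,
column 0 the left edge; boundary curves are real-valued row coordinates
indexed by integer column; all geometry is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: physical scaling constants: an en-face map of 200 um corresponds to
#: 25 px laterally and 76 px axially; adjacent B-scans are 240 um apart.
LATERAL_UM_PER_PX = 200.0 / 25.0
AXIAL_UM_PER_PX = 200.0 / 76.0
SCAN_SPACING_UM = 240.0

#: minimum image side so a 32x32 patch window always fits
MIN_IMAGE_SIDE = 64


class OctError(Exception):
    """Base error for this package."""


class ParameterError(OctError, ValueError):
    """Invalid parameter or configuration value."""


class FormatError(OctError, ValueError):
    """Malformed file or record."""


class SegmentationError(OctError, RuntimeError):
    """A segmentation stage could not produce a boundary."""


@dataclass
class BScanImage:
    """One 2-D 8-bit grayscale OCT slice with pixel-size metadata."""

    pixels: np.ndarray
    scan_index: int = 0
    lateral_scale: float = LATERAL_UM_PER_PX
    axial_scale: float = AXIAL_UM_PER_PX

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError(
                f"B-scan must be a 2-D array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if np.issubdtype(self.pixels.dtype, np.integer) and (
                self.pixels.min() >= 0 and self.pixels.max() <= 255
            ):
                self.pixels = self.pixels.astype(np.uint8)
            else:
                raise ParameterError(
                    f"B-scan intensities must be 8-bit, got dtype {self.pixels.dtype}"
                )
        rows, cols = self.pixels.shape
        if rows < MIN_IMAGE_SIDE or cols < MIN_IMAGE_SIDE:
            raise ParameterError(
                f"B-scan must be at least {MIN_IMAGE_SIDE} px on each side, "
                f"got {rows}x{cols}"
            )
        if not (self.lateral_scale > 0 and self.axial_scale > 0):
            raise ParameterError("pixel scales must be strictly positive")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BoundaryCurve:
    """Per-column row coordinate of a layer boundary on one scan.

    ``rows[c]`` is the (real-valued) row of the boundary in column ``c``;
    length equals the image width.
    """

    rows: np.ndarray
    layer_tag: str = "bm"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 1 or self.rows.size == 0:
            raise ParameterError("boundary curve must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.rows)):
            raise ParameterError("boundary curve contains non-finite values")
        if self.layer_tag not in ("bm", "choroid"):
            raise ParameterError(f"unknown layer tag {self.layer_tag!r}")

    @property
    def width(self) -> int:
        return self.rows.size

    def __call__(self, column) -> np.ndarray:
        return self.rows[column]

    def __eq__(self, other) -> bool:  # value semantics, mostly for tests
        return (
            isinstance(other, BoundaryCurve)
            and self.layer_tag == other.layer_tag
            and np.array_equal(self.rows, other.rows)
        )


@dataclass
class AnnotatedScan:
    """A B-scan together with its ground-truth boundary curves."""

    image: BScanImage
    bm_truth: BoundaryCurve
    choroid_truth: BoundaryCurve

    def __post_init__(self) -> None:
        w = self.image.cols
        if self.bm_truth.width != w or self.choroid_truth.width != w:
            raise ParameterError("truth curves must cover every image column")
        bm, ch = self.bm_truth.rows, self.choroid_truth.rows
        if not (
            np.all(bm >= 0)
            and np.all(bm < ch)
            and np.all(ch < self.image.rows)
        ):
            raise ParameterError(
                "ground truth must satisfy 0 <= bm(c) < choroid(c) < rows"
            )


@dataclass
class OCTVolume:
    """An ordered stack of B-scans from one subject (25 by default)."""

    subject_id: str
    scans: list = field(default_factory=list)
    scan_spacing: float = SCAN_SPACING_UM

    def __post_init__(self) -> None:
        if not self.scans:
            raise ParameterError("volume must contain at least one scan")
        if self.scan_spacing <= 0:
            raise ParameterError("scan spacing must be positive")
        imgs = [self._image(s) for s in self.scans]
        idx = [im.scan_index for im in imgs]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ParameterError("scans must be sorted by unique scan_index")
        shape = imgs[0].pixels.shape
        if any(im.pixels.shape != shape for im in imgs):
            raise ParameterError("all scans in a volume must share dimensions")

    @staticmethod
    def _image(scan) -> BScanImage:
        return scan.image if isinstance(scan, AnnotatedScan) else scan

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def shape(self) -> tuple:
        return self._image(self.scans[0]).pixels.shape
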