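"""Readers and writers for scans, boundary CSVs and phantom volumes."""

from __future__ import annotations

import io
import logging
import os
import re

import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import (
    AnnotatedScan,
    BScanImage,
    BoundaryCurve,
    FormatError,
    OCTVolume,
)
from ._util import atomic_write_bytes, atomic_write_text

logger = logging.getLogger("octchoroid.io")


def read_scan(path, scan_index: int = 0) -> BScanImage:
    """Load an 8-bit grayscale scan from PNG/TIFF.

    Color inputs are converted to luminance; 16-bit inputs are rescaled
    to [0, 255] with a logged warning.
    """
    if not os.path.exists(path):
        raise FormatError(f"scan file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:
        raise FormatError(f"cannot read scan {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim != 2:
        raise FormatError(f"scan {path} is not a 2-D image")
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        top = info.max if info else max(float(arr.max()), 1.0)
        logger.warning("rescaling %s from %s to 8-bit", path, arr.dtype)
        arr = np.clip(np.rint(arr.astype(float) / top * 255.0), 0, 255).astype(
            np.uint8
        )
    return BScanImage(pixels=arr, scan_index=scan_index)


def write_scan(image: BScanImage, path) -> None:
    """Write a scan as 8-bit grayscale PNG (atomic, lossless)."""
    buf = io.BytesIO()
    Image.fromarray(image.pixels, mode="L").save(buf, format="PNG")
    atomic_write_bytes(path, buf.getvalue())


def read_boundary(path, layer_tag: str = "bm") -> BoundaryCurve:
    """Load a boundary CSV with header ``column,row``, one contiguous
    0-based column per line."""
    if not os.path.exists(path):
        raise FormatError(f"boundary file not found: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != ["column", "row"]:
        raise FormatError(f"{path}: expected header 'column,row'")
    cols = df["column"].to_numpy()
    if not np.array_equal(cols, np.arange(len(cols))):
        raise FormatError(f"{path}: columns must be contiguous from 0")
    return BoundaryCurve(df["row"].to_numpy(dtype=float), layer_tag=layer_tag)


def write_boundary(curve: BoundaryCurve, path) -> None:
    """Write a boundary curve CSV; values keep >= 6 significant decimals."""
    lines = ["column,row"]
    lines += [f"{c},{r:.9g}" for c, r in enumerate(curve.rows)]
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---- volume layout on disk --------------------------------------------------
# <subject>/scan_<k:02d>.png  (+ .bm.csv / .choroid.csv ground truth)

SCAN_RE = re.compile(r"^scan_(\d{2})\.png$")


def write_volume(volume: OCTVolume, out_dir) -> None:
    d = os.path.join(os.fspath(out_dir), volume.subject_id)
    os.makedirs(d, exist_ok=True)
    for scan in volume.scans:
        image = scan.image if isinstance(scan, AnnotatedScan) else scan
        stem = os.path.join(d, f"scan_{image.scan_index:02d}")
        write_scan(image, stem + ".png")
        if isinstance(scan, AnnotatedScan):
            write_boundary(scan.bm_truth, stem + ".bm.csv")
            write_boundary(scan.choroid_truth, stem + ".choroid.csv")


def read_volume(subject_dir, subject_id: str | None = None) -> OCTVolume:
    """Read a subject directory; attaches ground truth when present."""
    subject_dir = os.fspath(subject_dir)
    scans = []
    for name in sorted(os.listdir(subject_dir)):
        m = SCAN_RE.match(name)
        if not m:
            continue
        k = int(m.group(1))
        image = read_scan(os.path.join(subject_dir, name), scan_index=k)
        stem = os.path.join(subject_dir, f"scan_{k:02d}")
        if os.path.exists(stem + ".bm.csv") and os.path.exists(
            stem + ".choroid.csv"
        ):
            scans.append(
                AnnotatedScan(
                    image=image,
                    bm_truth=read_boundary(stem + ".bm.csv", "bm"),
                    choroid_truth=read_boundary(stem + ".choroid.csv", "choroid"),
                )
            )
        else:
            scans.append(image)
    if not scans:
        raise FormatError(f"no scans found under {subject_dir}")
    return OCTVolume(
        subject_id=subject_id or os.path.basename(subject_dir.rstrip("/")),
        scans=scans,
    )
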