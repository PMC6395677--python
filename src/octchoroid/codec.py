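"""CIFAR-10-style binary serialization of labeled patches.

Each record is exactly 3073 bytes: one label byte (0 or 1) followed by
3072 pixel bytes laid out as three 1024-byte planes (red, green, blue),
each plane row-major.  Grayscale patches are replicated into all three
planes on encode and read back from the red plane on decode.  Files are
plain concatenations of records with no header.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FormatError, ParameterError
from .sampling import LabeledPatch

PATCH_SIDE = 32
PLANE_BYTES = PATCH_SIDE * PATCH_SIDE           # 1024
RECORD_BYTES = 1 + 3 * PLANE_BYTES              # 3073


def encode_record(patch: LabeledPatch) -> bytes:
    """Serialize one 32x32 grayscale patch to a 3073-byte record."""
    px = np.asarray(patch.pixels, dtype=np.uint8)
    if px.shape != (PATCH_SIDE, PATCH_SIDE):
        raise ParameterError(
            f"patch must be {PATCH_SIDE}x{PATCH_SIDE}, got {px.shape}"
        )
    plane = px.reshape(-1)  # row-major: 32 bytes per row, top row first
    return bytes([patch.label]) + plane.tobytes() * 3


def decode_record(record: bytes) -> LabeledPatch:
    """Parse one 3073-byte record back into a labeled grayscale patch."""
    if len(record) != RECORD_BYTES:
        raise FormatError(
            f"record must be {RECORD_BYTES} bytes, got {len(record)}"
        )
    label = record[0]
    if label > 1:
        raise FormatError(f"invalid label byte {label} at offset 0")
    red = np.frombuffer(record, dtype=np.uint8, count=PLANE_BYTES, offset=1)
    return LabeledPatch(
        pixels=red.reshape(PATCH_SIDE, PATCH_SIDE).copy(), label=int(label)
    )


def write_records(patches, path) -> None:
    """Write patches as a flat record file (atomically)."""
    from ._util import atomic_write_bytes

    atomic_write_bytes(path, b"".join(encode_record(p) for p in patches))


def stream_records(path):
    """Yield decoded records from a flat record file, in file order."""
    import os

    size = os.path.getsize(path)
    if size % RECORD_BYTES != 0:
        raise FormatError(
            f"file size {size} is not a multiple of {RECORD_BYTES} "
            f"(residue {size % RECORD_BYTES})"
        )
    with open(path, "rb") as fh:
        while True:
            chunk = fh.read(RECORD_BYTES)
            if not chunk:
                return
            yield decode_record(chunk)


def load_arrays(path):
    """Load a record file into (pixels (N,32,32) uint8, labels (N,))."""
    xs, ys = [], []
    for patch in stream_records(path):
        xs.append(patch.pixels)
        ys.append(patch.label)
    if not xs:
        return np.zeros((0, PATCH_SIDE, PATCH_SIDE), np.uint8), np.zeros(0, np.int64)
    return np.stack(xs), np.asarray(ys, dtype=np.int64)
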