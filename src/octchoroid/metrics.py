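"""Segmentation evaluation metrics.

* err1: Euclidean norm of the difference between predicted and reference
  per-column thickness vectors, divided by h*w.
* err2: absolute difference of the two thickness means, divided by h.
* Dice: region overlap 2|A&B|/(|A|+|B|) of the rasterized choroidal
  regions (rows strictly below BM down to and including the choroid
  boundary, curves rounded per column).
* Signed / unsigned boundary positioning errors: per-column row
  deviation mean +- std, in pixels; positive signed error means the
  predicted boundary sits deeper (larger row) than the truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .datatypes import BoundaryCurve, ParameterError


def err1(pred_thickness, ref_thickness, h: int, w: int) -> float:
    """||A - B||_2 / (h * w)."""
    a = np.asarray(pred_thickness, dtype=float)
    b = np.asarray(ref_thickness, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("thickness vectors must be 1-D and equally long")
    if h <= 0 or w <= 0:
        raise ParameterError("image dimensions must be positive")
    return float(np.linalg.norm(a - b) / (h * w))


def err2(pred_thickness, ref_thickness, h: int) -> float:
    """|mean(A) - mean(B)| / h."""
    a = np.asarray(pred_thickness, dtype=float)
    b = np.asarray(ref_thickness, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("thickness vectors must be 1-D and equally long")
    if h <= 0:
        raise ParameterError("height must be positive")
    return float(abs(a.mean() - b.mean()) / h)


def rasterize_region(bm: BoundaryCurve, choroid: BoundaryCurve, n_rows: int):
    """Boolean mask of the choroidal region {(r,c): bm(c) < r <= choroid(c)}
    with rounded curve values."""
    if bm.width != choroid.width:
        raise ParameterError("curve widths differ")
    rows = np.arange(n_rows)[:, None]
    top = np.rint(bm.rows)[None, :]
    bottom = np.rint(choroid.rows)[None, :]
    return (rows > top) & (rows <= bottom)


def dice(pred_region, ref_region) -> float:
    """2|A&B| / (|A|+|B|); defined as 1 when both regions are empty."""
    a = np.asarray(pred_region, dtype=bool)
    b = np.asarray(ref_region, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError("regions must lie on the same grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def boundary_errors(pred: BoundaryCurve, truth: BoundaryCurve) -> dict:
    """Signed and unsigned per-column positioning errors, mean +- std (px)."""
    if pred.width != truth.width:
        raise ParameterError("curve widths differ")
    d = pred.rows - truth.rows
    return {
        "signed_mean": float(d.mean()),
        "signed_std": float(d.std()),
        "unsigned_mean": float(np.abs(d).mean()),
        "unsigned_std": float(np.abs(d).std()),
    }


@dataclass
class EvalReport:
    """Volume-level aggregate metrics plus the per-scan breakdown."""

    err1: float
    err2: float
    dice: float
    bm_errors: dict
    choroid_errors: dict
    n_scans: int
    per_scan: list

    def to_json(self, path) -> None:
        from ._util import atomic_write_text

        atomic_write_text(path, json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def evaluate_scan(pred_bm, pred_choroid, true_bm, true_choroid, n_rows: int) -> dict:
    pred_t = pred_choroid.rows - pred_bm.rows
    true_t = true_choroid.rows - true_bm.rows
    w = pred_bm.width
    return {
        "err1": err1(pred_t, true_t, n_rows, w),
        "err2": err2(pred_t, true_t, n_rows),
        "dice": dice(
            rasterize_region(pred_bm, pred_choroid, n_rows),
            rasterize_region(true_bm, true_choroid, n_rows),
        ),
        "bm": boundary_errors(pred_bm, true_bm),
        "choroid": boundary_errors(pred_choroid, true_choroid),
    }


def evaluate_run(pred_dir, truth_dir, n_rows: int = 456,
                 report_path=None) -> EvalReport:
    """Compare per-scan predicted and reference boundary CSV pairs.

    Both directories must hold ``scan_<k>.bm.csv`` / ``scan_<k>.choroid.csv``
    files; unmatched scans are reported.  Per-scan metrics are averaged
    into the volume-level report.
    """
    from .imgio import read_boundary

    def index(d):
        out = {}
        for name in sorted(os.listdir(d)):
            if name.endswith(".bm.csv"):
                out.setdefault(name[: -len(".bm.csv")], {})["bm"] = name
            elif name.endswith(".choroid.csv"):
                out.setdefault(name[: -len(".choroid.csv")], {})["choroid"] = name
        return {k: v for k, v in out.items() if set(v) == {"bm", "choroid"}}

    preds, truths = index(pred_dir), index(truth_dir)
    unmatched = sorted(set(preds) ^ set(truths))
    if unmatched:
        raise ParameterError(f"unmatched scans: {unmatched}")
    if not preds:
        raise ParameterError("no scan pairs found")

    per_scan = []
    for key in sorted(preds):
        pb = read_boundary(os.path.join(pred_dir, preds[key]["bm"]), "bm")
        pc = read_boundary(os.path.join(pred_dir, preds[key]["choroid"]), "choroid")
        tb = read_boundary(os.path.join(truth_dir, truths[key]["bm"]), "bm")
        tc = read_boundary(os.path.join(truth_dir, truths[key]["choroid"]), "choroid")
        m = evaluate_scan(pb, pc, tb, tc, n_rows)
        m["scan"] = key
        per_scan.append(m)

    def agg(path_fn):
        return float(np.mean([path_fn(m) for m in per_scan]))

    report = EvalReport(
        err1=agg(lambda m: m["err1"]),
        err2=agg(lambda m: m["err2"]),
        dice=agg(lambda m: m["dice"]),
        bm_errors={
            k: agg(lambda m, k=k: m["bm"][k])
            for k in ("signed_mean", "signed_std", "unsigned_mean", "unsigned_std")
        },
        choroid_errors={
            k: agg(lambda m, k=k: m["choroid"][k])
            for k in ("signed_mean", "signed_std", "unsigned_mean", "unsigned_std")
        },
        n_scans=len(per_scan),
        per_scan=per_scan,
    )
    if report_path is not None:
        report.to_json(report_path)
    return report
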