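"""Shared fixtures: small phantoms for unit tests and the session-scoped
end-to-end pipeline run reused by the acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

from octchoroid.config import PipelineConfig
from octchoroid.phantom import PhantomParams, generate_scan, generate_volume


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def easy_scan():
    """One default-geometry easy-mode phantom scan."""
    return generate_scan(PhantomParams(seed=11), 0)


@pytest.fixture(scope="session")
def small_params():
    """A small phantom for fast unit tests (96 x 128 px)."""
    return PhantomParams(
        rows=96,
        cols=128,
        n_scans=3,
        bm_center=30.0,
        retina_thickness=20.0,
        choroid_thickness=(28.0, 36.0),
        waviness_amplitude=3.0,
        drift=1.0,
        vessel_count=3,
        vessel_radius=(2.0, 4.0),
        seed=5,
    )


@pytest.fixture(scope="session")
def small_scan(small_params):
    return generate_scan(small_params, 0)


@pytest.fixture(scope="session")
def trained_pipeline():
    """Full scaled-down study: train on 3 phantom subjects, segment a
    held-out phantom volume, collect per-scan accuracy.

    This is the expensive session fixture behind the end-to-end checks;
    everything flows from fixed seeds so the run is reproducible.
    """
    from octchoroid import bm as bm_mod
    from octchoroid.choroid import segment_choroid
    from octchoroid.cnn import PatchClassifier, TrainConfig
    from octchoroid.cnn.train import train
    from octchoroid.metrics import dice, rasterize_region
    from octchoroid.sampling import sample_dataset

    cfg = PipelineConfig()
    train_vols = [
        generate_volume(PhantomParams(seed=100 + s), f"train{s}") for s in range(3)
    ]
    patches, yields = sample_dataset(train_vols, cfg, seed=7, max_patches=10_000)
    x = np.stack([p.pixels for p in patches])
    y = np.array([p.label for p in patches])
    model = PatchClassifier(seed=7)
    train(model, x, y, TrainConfig.reduced(seed=7))

    held = generate_volume(PhantomParams(seed=999), "held")
    per_scan = []
    for scan in held.scans:
        bm_curve = bm_mod.segment_bm(scan.image, cfg)
        ch_curve = segment_choroid(scan.image, bm_curve, model, cfg)
        per_scan.append(
            {
                "bm_mae": float(np.abs(bm_curve.rows - scan.bm_truth.rows).mean()),
                "choroid_mae": float(
                    np.abs(ch_curve.rows - scan.choroid_truth.rows).mean()
                ),
                "dice": dice(
                    rasterize_region(bm_curve, ch_curve, scan.image.rows),
                    rasterize_region(
                        scan.bm_truth, scan.choroid_truth, scan.image.rows
                    ),
                ),
            }
        )
    return {
        "model": model,
        "config": cfg,
        "patch_yields": yields,
        "n_patches": len(patches),
        "per_scan": per_scan,
    }
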