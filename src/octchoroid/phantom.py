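"""Synthetic OCT B-scan phantoms with known boundary ground truth.

The phantom emulates the image properties that make choroid segmentation
hard in real swept-source OCT: a thin bright Bruch's-membrane (BM) band
over a speckled, vessel-riddled choroid whose interface with the sclera is
low-contrast, all embedded in additive acquisition noise.  The layer stack,
top to bottom, is: dark vitreous, mildly textured retina band, a bright
3-px BM band, the choroid (multiplicative gamma speckle plus dark
elliptical vessel cross-sections) and a smooth sclera.

Boundary curves are a low-order polynomial plus one low-frequency sinusoid
per volume, with a bounded smooth drift across the 25 scans of a volume.
All randomness flows from one seed, so identical parameters give
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (
    SCAN_SPACING_UM,
    AnnotatedScan,
    BScanImage,
    BoundaryCurve,
    OCTVolume,
    ParameterError,
)

# base layer intensities (8-bit); BM is deliberately the only band above the
# 190 binarization threshold so thresholding isolates it up to speckle noise
VITREOUS_LEVEL = 20.0
RETINA_LEVEL = 100.0
BM_LEVEL = 220.0
CHOROID_LEVEL = 90.0
VESSEL_LEVEL = 50.0


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, texture and noise parameters of the phantom generator.

    Defaults reproduce the nominal scan geometry (456 rows x 760 columns,
    25 scans at 240 um) and an "easy" contrast regime; ``contrast='hard'``
    lowers the choroid-sclera step and raises speckle and noise.
    """

    rows: int = 456
    cols: int = 760
    n_scans: int = 25
    scan_spacing: float = SCAN_SPACING_UM
    bm_center: float = 170.0          # mean BM-band centre row
    bm_band_thickness: int = 3        # px
    retina_thickness: float = 120.0   # px between retina top and BM
    choroid_thickness: tuple = (90.0, 115.0)  # (min, max) px per volume
    waviness_amplitude: float = 8.0   # px; 0 -> perfectly flat boundaries
    drift: float = 2.0                # max per-scan boundary change, px
    speckle_shape: float = 4.0        # gamma shape k (mean-1 multiplicative)
    vessel_count: int = 14
    vessel_radius: tuple = (3.0, 9.0)  # (min, max) semi-axis, px
    noise_sigma: float = 2.0          # additive Gaussian, intensity levels
    contrast: str = "easy"            # 'easy' | 'hard'
    seed: int = 0

    def __post_init__(self):
        if self.rows < 64 or self.cols < 64:
            raise ParameterError("phantom dims must be at least 64x64")
        if self.contrast not in ("easy", "hard"):
            raise ParameterError("contrast must be 'easy' or 'hard'")
        if self.bm_band_thickness < 1:
            raise ParameterError("BM band must be at least 1 px thick")
        lo, hi = self.choroid_thickness
        if not (0 < lo <= hi):
            raise ParameterError("invalid choroid thickness range")
        margin = self.waviness_amplitude + self.drift * max(self.n_scans - 1, 1)
        half = (self.bm_band_thickness - 1) / 2
        if self.bm_center - half - margin < 0:
            raise ParameterError("BM band can leave the top of the image")
        if self.bm_center + half + hi + 2 * margin >= self.rows:
            raise ParameterError(
                "choroid lower boundary can leave the bottom of the image"
            )
        if not self.vessel_radius[0] <= self.vessel_radius[1]:
            raise ParameterError("invalid vessel radius range")

    @property
    def sclera_level(self) -> float:
        # hard mode: nearly invisible choroid-sclera intensity step
        return 110.0 if self.contrast == "easy" else 96.0

    def effective(self) -> "PhantomParams":
        """Parameters after applying the contrast regime."""
        if self.contrast == "easy":
            return self
        return replace(
            self,
            speckle_shape=min(self.speckle_shape, 2.5),
            noise_sigma=max(self.noise_sigma, 5.0),
        )


def _volume_rng(params: PhantomParams) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, 0]))


def _scan_rng(params: PhantomParams, scan_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([params.seed, 1, scan_index])
    )


def _boundary_model(params: PhantomParams):
    """Volume-level boundary description, drawn once from the seed.

    Returns per-volume polynomial/sinusoid coefficients for the BM centre
    line, a choroid thickness profile, and per-scan drift offsets whose
    successive differences never exceed ``params.drift``.
    """
    rng = _volume_rng(params)
    amp = params.waviness_amplitude
    # BM centre: quadratic + one sinusoid, amplitudes scaled so that the
    # total excursion stays within +/- waviness_amplitude
    slope = rng.uniform(-0.3, 0.3) * amp
    curv = rng.uniform(-0.5, 0.5) * amp
    sin_amp = rng.uniform(0.2, 0.5) * amp
    sin_freq = rng.uniform(1.0, 2.5)      # cycles across the scan width
    sin_phase = rng.uniform(0, 2 * np.pi)
    # choroid thickness profile: its own gentle quadratic + sinusoid
    lo, hi = params.choroid_thickness
    base_thick = rng.uniform(lo, hi)
    t_slope = rng.uniform(-0.2, 0.2) * amp
    t_sin_amp = rng.uniform(0.1, 0.3) * amp
    t_sin_phase = rng.uniform(0, 2 * np.pi)
    # smooth bounded inter-scan drift (random walk with per-step clip)
    steps = rng.uniform(-params.drift, params.drift, size=max(params.n_scans, 1))
    steps[0] = 0.0
    drift = np.cumsum(steps)
    return {
        "slope": slope,
        "curv": curv,
        "sin": (sin_amp, sin_freq, sin_phase),
        "base_thick": base_thick,
        "t_slope": t_slope,
        "t_sin": (t_sin_amp, t_sin_phase),
        "drift": drift,
    }


def boundary_truth(params: PhantomParams, scan_index: int):
    """Exact BM and lower-choroid boundary curves for one scan."""
    m = _boundary_model(params)
    x = np.linspace(-0.5, 0.5, params.cols)
    sa, sf, sp = m["sin"]
    bm = (
        params.bm_center
        + m["slope"] * x
        + m["curv"] * (x**2 - 1 / 12)
        + sa * np.sin(2 * np.pi * sf * x + sp)
    )
    ta, tp = m["t_sin"]
    thick = (
        m["base_thick"]
        + m["t_slope"] * x
        + ta * np.sin(2 * np.pi * sf * x + tp)
    )
    if scan_index >= len(m["drift"]):
        raise ParameterError(
            f"scan_index {scan_index} outside volume of {params.n_scans} scans"
        )
    bm = bm + m["drift"][scan_index]
    lo, hi = params.choroid_thickness
    thick = np.clip(thick, lo, hi)
    return bm, bm + thick


def generate_scan(params: PhantomParams, scan_index: int = 0) -> AnnotatedScan:
    """Render one annotated phantom B-scan.

    The returned ground-truth curves are exact by construction: ``bm_truth``
    is the BM band centre line and ``choroid_truth`` the lower choroid
    boundary used to paint the layer stack.
    """
    eff = params.effective()
    bm, choroid = boundary_truth(params, scan_index)
    rng = _scan_rng(params, scan_index)

    rows, cols = params.rows, params.cols
    r = np.arange(rows, dtype=float)[:, None]
    half = (params.bm_band_thickness - 1) / 2.0
    retina_top = bm - params.retina_thickness

    # the band is rasterized around the rounded centre row so it is always
    # exactly bm_band_thickness rows thick (a thinner band would not
    # survive the 3x3 morphology downstream; real BM bands are
    # resolution-limited anyway); the float curve stays the ground truth
    bm_r = np.rint(bm)
    bm_mask = np.abs(r - bm_r) <= half + 1e-9

    img = np.full((rows, cols), VITREOUS_LEVEL)
    retina_mask = (r >= retina_top) & (r < bm_r - half)
    img[retina_mask] = RETINA_LEVEL
    # mild retina texture so the band is not perfectly flat
    img[retina_mask] += rng.normal(0.0, 4.0, size=int(retina_mask.sum()))

    choroid_mask = (r > bm_r + half) & (r <= choroid)
    sclera_mask = r > choroid
    img[sclera_mask] = eff.sclera_level
    img[sclera_mask] += rng.normal(0.0, 2.0, size=int(sclera_mask.sum()))

    # choroid: multiplicative gamma speckle (mean 1) over the base level
    k = eff.speckle_shape
    speckle = rng.gamma(k, 1.0 / k, size=(rows, cols))
    chor = CHOROID_LEVEL * speckle
    # dark elliptical vessel cross-sections, confined to the choroid
    c_grid = np.arange(cols, dtype=float)[None, :]
    depth = choroid - (bm + half)
    for _ in range(params.vessel_count):
        cc = rng.uniform(0, cols)
        frac = rng.uniform(0.2, 0.85)        # fractional depth in the choroid
        col_i = int(np.clip(round(cc), 0, cols - 1))
        cr = bm[col_i] + half + frac * depth[col_i]
        a = rng.uniform(*params.vessel_radius)   # row semi-axis
        b = a * rng.uniform(1.0, 2.5)            # vessels are wider than tall
        ell = ((r - cr) / a) ** 2 + ((c_grid - cc) / b) ** 2 <= 1.0
        chor = np.where(ell, VESSEL_LEVEL * speckle, chor)
    img[choroid_mask] = chor[choroid_mask]

    img[bm_mask] = BM_LEVEL  # painted last: nothing may cut into the band

    img += rng.normal(0.0, eff.noise_sigma, size=(rows, cols))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    image = BScanImage(pixels=pixels, scan_index=scan_index)
    return AnnotatedScan(
        image=image,
        bm_truth=BoundaryCurve(bm, layer_tag="bm"),
        choroid_truth=BoundaryCurve(choroid, layer_tag="choroid"),
    )


def generate_volume(params: PhantomParams, subject_id: str = "subject") -> OCTVolume:
    """Render a full phantom volume (25 scans by default, 240 um apart)."""
    scans = [generate_scan(params, k) for k in range(params.n_scans)]
    return OCTVolume(
        subject_id=subject_id, scans=scans, scan_spacing=params.scan_spacing
    )
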