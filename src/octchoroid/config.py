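"""Pipeline configuration: defaults, YAML round trip, CLI overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .datatypes import (
    AXIAL_UM_PER_PX,
    LATERAL_UM_PER_PX,
    SCAN_SPACING_UM,
    ParameterError,
)


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole segmentation pipeline.

    The defaults are the operating point used throughout: binarization
    threshold 190, 32x32 patches at stride 5, patches with more than a
    third of black pixels discarded.
    """

    threshold: int = 190            # BM binarization threshold t_b
    patch_size: int = 32
    stride: int = 5
    black_fraction: float = 1.0 / 3.0   # discard if black share exceeds this
    row_band_fraction: float = 0.10     # select_rows histogram floor
    knot_stride: int = 10               # BM spline knot subsampling
    lateral_um_per_px: float = LATERAL_UM_PER_PX
    axial_um_per_px: float = AXIAL_UM_PER_PX
    scan_spacing_um: float = SCAN_SPACING_UM
    seed: int = 0
    train: dict = field(default_factory=dict)  # overrides for TrainConfig

    def __post_init__(self):
        if not 0 < self.threshold < 255:
            raise ParameterError("threshold must lie in (0, 255)")
        if self.patch_size < 1:
            raise ParameterError("patch size must be positive")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if not 0 < self.black_fraction <= 1:
            raise ParameterError("black fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        section = data.get("pipeline", data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**section)

    def to_yaml(self, path) -> None:
        from ._util import atomic_write_text

        atomic_write_text(path, yaml.safe_dump({"pipeline": dataclasses.asdict(self)}))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
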