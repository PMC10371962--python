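"""Pipeline configuration.

Defaults follow the study protocol this package implements: routine static
scan at ~61 min and delayed scan at ~133 min post-injection, feature
discretization with 64 bins over the absolute intensity range [0, 20] (SUV
scale; Ki maps are multiplied by 100 first to share it), 4 mm isotropic
resampling, and 30%-of-max lesion thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

MODEL_VARIANTS = (
    "H_DTP",
    "H_Static",
    "H_DTP+Static",
    "Non-H_DTP",
    "Non-H_Static",
    "Non-H_DTP+Static",
)


@dataclass
class PipelineConfig:
    # acquisition timing (minutes post-injection)
    t1_min: float = 61.0
    t2_min: float = 133.0
    # feature preprocessing
    bin_count: int = 64
    intensity_min: float = 0.0
    intensity_max: float = 20.0
    resample_mm: float = 4.0
    threshold_fraction: float = 0.30
    peak_volume_ml: float = 0.5
    # modeling protocol
    model_variant: str = "H_DTP+Static"
    mrmr_k: int = 10
    n_repeats: int = 100
    n_search: int = 10        # random-search candidates per repeat
    n_boot: int = 25          # bootstrap resamples scoring each candidate
    combat_mode: str = "train"   # "train" (leak-free) or "all" (fit on all lesions)
    split_level: str = "patient"  # "patient" or "lesion"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t2_min > self.t1_min > 0):
            raise ValueError("need t2_min > t1_min > 0")
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")
        if not self.intensity_max > self.intensity_min:
            raise ValueError("intensity_max must exceed intensity_min")
        if not (0 < self.threshold_fraction < 1):
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.resample_mm <= 0:
            raise ValueError("resample_mm must be positive")
        if self.model_variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown model variant {self.model_variant!r}")
        if self.combat_mode not in ("train", "all"):
            raise ValueError("combat_mode must be 'train' or 'all'")
        if self.split_level not in ("patient", "lesion"):
            raise ValueError("split_level must be 'patient' or 'lesion'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
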