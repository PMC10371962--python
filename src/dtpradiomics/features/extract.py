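"""The 65-feature panel and its canonical ordering.

Categories (and counts): GLCM (7), NGLDM (3), GLRLM (11), GLZLM (11),
shape (5), histogram (4), conventional (12) and discretized (12) first-order
indices — 65 named scalars per lesion per image.  The same panel is computed
on the static SUV image ("static" features) and the scaled Ki map ("DTP"
features).
"""

from __future__ import annotations

from collections import OrderedDict

import pandas as pd

from ..config import PipelineConfig
from ..segmentation import VOI
from ..volumes import ImageVolume
from .intensity import conventional_indices, histogram_features, shape_features
from .preprocess import DiscretizedVolume, preprocess
from .texture import glcm_features, glrlm_features, glzlm_features, ngldm_features

_GLCM = ["Homogeneity", "Energy", "Contrast", "Correlation", "Entropy", "Entropy_log2", "Dissimilarity"]
_NGLDM = ["Coarseness", "Contrast", "Busyness"]
_GLRLM = ["SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLNU", "RLNU", "RP"]
_GLZLM = ["SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLNU", "ZLNU", "ZP"]
_SHAPE = ["Sphericity", "Compacity", "Surface_mm2", "Volume_mL", "Volume_vx"]
_HISTO = ["Entropy", "Entropy_log2", "Uniformity", "AUC_CSH"]
_FIRST_ORDER = ["Q1", "Q2", "Q3", "min", "mean", "max", "std", "peak", "TLG_mL",
                "Skewness", "Kurtosis", "ExcessKurtosis"]

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"GLCM_{n}" for n in _GLCM]
    + [f"NGLDM_{n}" for n in _NGLDM]
    + [f"GLRLM_{n}" for n in _GLRLM]
    + [f"GLZLM_{n}" for n in _GLZLM]
    + [f"SHAPE_{n}" for n in _SHAPE]
    + [f"HISTO_{n}" for n in _HISTO]
    + [f"CONV_{n}" for n in _FIRST_ORDER]
    + [f"DISC_{n}" for n in _FIRST_ORDER]
)
assert len(FEATURE_NAMES) == 65


def features_from_discretized(d: DiscretizedVolume, cfg: PipelineConfig) -> "OrderedDict[str, float]":
    out: "OrderedDict[str, float]" = OrderedDict()
    for name, value in glcm_features(d).items():
        out[f"GLCM_{name}"] = value
    for name, value in ngldm_features(d).items():
        out[f"NGLDM_{name}"] = value
    for name, value in glrlm_features(d).items():
        out[f"GLRLM_{name}"] = value
    for name, value in glzlm_features(d).items():
        out[f"GLZLM_{name}"] = value
    shape = shape_features(d.mask, d.spacing)
    for name, value in shape.items():
        out[f"SHAPE_{name}"] = value
    for name, value in histogram_features(d).items():
        out[f"HISTO_{name}"] = value
    conv = conventional_indices(
        d.continuous, d.mask, d.spacing, shape["Volume_mL"], cfg.peak_volume_ml
    )
    for name, value in conv.items():
        out[f"CONV_{name}"] = value
    disc = conventional_indices(
        d.bin_centers_volume(), d.mask, d.spacing, shape["Volume_mL"], cfg.peak_volume_ml
    )
    for name, value in disc.items():
        out[f"DISC_{name}"] = value
    assert tuple(out) == FEATURE_NAMES
    return out


def extract_features(vol: ImageVolume, voi: VOI, cfg: PipelineConfig) -> pd.Series:
    """All 65 features of one lesion on one image, canonical order."""
    d = preprocess(vol, voi, cfg)
    return pd.Series(features_from_discretized(d, cfg), dtype=float)


def extract_all(
    suv: ImageVolume,
    ki: ImageVolume,
    voi_suv: VOI,
    voi_ki: VOI,
    cfg: PipelineConfig,
) -> tuple[pd.Series, pd.Series]:
    """(static, DTP) feature vectors for one lesion.

    Static features come from the SUV image with its SUV-defined VOI; DTP
    features from the scaled Ki map with its (possibly edited) transferred
    VOI.
    """
    static = extract_features(suv, voi_suv, cfg)
    dtp = extract_features(ki, voi_ki, cfg)
    return static, dtp
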