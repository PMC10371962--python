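"""Shape, histogram and first-order (conventional/discretized) features."""

from __future__ import annotations

import numpy as np

from ..volumes import sphere_mask

PEAK_VOLUME_ML_DEFAULT = 0.5


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """Mesh-free voxel shape descriptors.

    Surface is counted from exposed voxel faces; sphericity compares the
    lesion to the sphere of equal volume (pi^(1/3) (6V)^(2/3) / S, so a cube
    scores ~0.806 and a digital ball slightly above 1 due to the staircase
    surface); compacity is V / (sqrt(pi) S^(3/2)) with V in mm3, S in mm2.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty VOI")
    spacing = np.asarray(spacing, float)
    count = int(mask.sum())
    vol_mm3 = count * float(np.prod(spacing))

    surface = 0.0
    for axis in range(3):
        face_area = float(np.prod(np.delete(spacing, axis)))
        m = np.moveaxis(mask, axis, 0)
        interior = np.abs(np.diff(m.astype(np.int8), axis=0)).sum()
        boundary = m[0].sum() + m[-1].sum()
        surface += face_area * float(interior + boundary)

    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * vol_mm3) ** (2.0 / 3.0) / surface
    compacity = vol_mm3 / (np.sqrt(np.pi) * surface**1.5)
    return {
        "Sphericity": float(sphericity),
        "Compacity": float(compacity),
        "Surface_mm2": float(surface),
        "Volume_mL": vol_mm3 / 1000.0,
        "Volume_vx": float(count),
    }


def histogram_features(d) -> dict[str, float]:
    """Histogram entropy/uniformity on the discretized levels, plus the area
    under the cumulative intensity-volume histogram (AUC-CSH) on the
    continuous resampled values: the fraction of lesion volume at or above
    x*max, trapezoid-integrated over x in [0, 1]."""
    lv = d.level_values()
    counts = np.bincount(lv, minlength=d.bin_count + 1)[1:]
    p = counts[counts > 0] / lv.size
    entropy = float(-(p * np.log(p)).sum())
    uniformity = float((p**2).sum())

    vals = d.voxel_values()
    vmax = float(vals.max())
    if vmax > 0:
        x = np.linspace(0.0, 1.0, 1001)
        frac = (vals[None, :] >= x[:, None] * vmax).mean(axis=1)
        auc_csh = float(np.trapezoid(frac, x))
    else:
        auc_csh = 0.0
    return {
        "Entropy": entropy,
        "Entropy_log2": entropy / np.log(2.0),
        "Uniformity": uniformity,
        "AUC_CSH": auc_csh,
    }


def _moments(vals: np.ndarray) -> tuple[float, float, float, float]:
    """(std, skewness, kurtosis, excess kurtosis) with population moments;
    the degenerate zero-spread case maps to (0, 0, 0, 0) by convention."""
    mu = vals.mean()
    m2 = ((vals - mu) ** 2).mean()
    if m2 <= 0:
        return 0.0, 0.0, 0.0, 0.0
    m3 = ((vals - mu) ** 3).mean()
    m4 = ((vals - mu) ** 4).mean()
    kurt = m4 / m2**2
    return float(np.sqrt(m2)), float(m3 / m2**1.5), float(kurt), float(kurt - 3.0)


def peak_value(
    values: np.ndarray,
    mask: np.ndarray,
    spacing,
    peak_volume_ml: float = PEAK_VOLUME_ML_DEFAULT,
) -> float:
    """Mean over a fixed-volume sphere (0.5 mL default) centered on the
    maximum-intensity VOI voxel, restricted to the VOI (partial spheres use
    the available intersection)."""
    spacing = np.asarray(spacing, float)
    masked = np.where(mask, values, -np.inf)
    center_idx = np.unravel_index(int(np.argmax(masked)), values.shape)
    radius = (3.0 * peak_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    center_mm = np.asarray(center_idx) * spacing
    sp = sphere_mask(values.shape, tuple(spacing), (0.0, 0.0, 0.0), tuple(center_mm), radius)
    sel = sp & mask
    return float(values[sel].mean())


def conventional_indices(
    values_volume: np.ndarray,
    mask: np.ndarray,
    spacing,
    volume_ml: float,
    peak_volume_ml: float = PEAK_VOLUME_ML_DEFAULT,
) -> dict[str, float]:
    """Twelve first-order indices on a continuous intensity volume.

    Used twice per lesion: on the raw resampled intensities ("conventional")
    and on the bin-center surrogate ("discretized").  Quantiles use linear
    interpolation between order statistics; TLG = mean * volume (mL).
    """
    vals = values_volume[mask]
    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
    std, skew, kurt, exkurt = _moments(vals)
    return {
        "Q1": float(q1),
        "Q2": float(q2),
        "Q3": float(q3),
        "min": float(vals.min()),
        "mean": float(vals.mean()),
        "max": float(vals.max()),
        "std": std,
        "peak": peak_value(values_volume, mask, spacing, peak_volume_ml),
        "TLG_mL": float(vals.mean() * volume_ml),
        "Skewness": skew,
        "Kurtosis": kurt,
        "ExcessKurtosis": exkurt,
    }
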