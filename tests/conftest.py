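import numpy as np
import pytest

from dtpradiomics.config import PipelineConfig
from dtpradiomics.features.preprocess import DiscretizedVolume


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


def make_disc(
    levels: np.ndarray,
    mask: np.ndarray | None = None,
    bin_count: int | None = None,
    bounds: tuple[float, float] = (0.0, 20.0),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    continuous: np.ndarray | None = None,
) -> DiscretizedVolume:
    """Build a DiscretizedVolume directly from an integer level array
    (levels >= 1 inside the VOI; 0 marks background unless a mask is given)."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim != 3:
        raise ValueError("levels must be 3D")
    if mask is None:
        mask = levels > 0
    mask = np.asarray(mask, bool)
    n = int(bin_count if bin_count is not None else max(levels.max(), 2))
    lo, hi = bounds
    if continuous is None:
        width = (hi - lo) / n
        continuous = lo + (levels - 0.5) * width
        continuous[~mask] = 0.0
    return DiscretizedVolume(
        levels=np.where(mask, levels, 0).astype(np.int32),
        mask=mask,
        bin_count=n,
        bounds=bounds,
        continuous=np.asarray(continuous, float),
        spacing=spacing,
        source_unit="SUV",
    )


@pytest.fixture
def random_lesion():
    """Factory for small random discretized lesions (blob-ish VOI)."""

    def _make(seed: int, shape=(6, 6, 6), n_levels: int = 4) -> DiscretizedVolume:
        rng = np.random.default_rng(seed)
        mask = rng.random(shape) < 0.7
        if not mask.any():
            mask[tuple(s // 2 for s in shape)] = True
        levels = np.where(mask, rng.integers(1, n_levels + 1, size=shape), 0)
        return make_disc(levels, mask=mask, bin_count=n_levels)

    return _make
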