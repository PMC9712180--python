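import numpy as np
import pytest

from xlung.prep import DiscretizedRoi, RoiMask, Volume


def droi(levels, n_bins=None, spacing=(1.0, 1.0, 1.0)) -> DiscretizedRoi:
    """Wrap an integer level grid (0 = outside ROI) as a DiscretizedRoi."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 1:
        levels = levels[np.newaxis, np.newaxis, :]
    elif levels.ndim == 2:
        levels = levels[np.newaxis, :, :]
    nb = int(n_bins if n_bins is not None else max(1, levels.max()))
    return DiscretizedRoi(levels, nb, 50.0, (-1000.0, 200.0), spacing)


def random_droi(rng, shape=(4, 4, 4), n_levels=3, p_roi=0.7) -> DiscretizedRoi:
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    roi = rng.random(shape) < p_roi
    levels[~roi] = 0
    if (levels > 0).sum() < 2:  # keep at least two ROI voxels
        levels[0, 0, 0] = 1
        levels[0, 0, 1] = 1
    return droi(levels, n_bins=n_levels)


@pytest.fixture(scope="session")
def small_volume():
    """A 20-cube volume with a centered spherical ROI and a HU gradient."""
    n = 20
    g = np.ogrid[0:n, 0:n, 0:n]
    dist2 = sum((c - n / 2) ** 2 for c in g)
    mask = dist2 <= 36
    data = -800.0 + 10.0 * np.add.outer(np.add.outer(np.arange(n), np.arange(n)), np.arange(n)) / 3
    return Volume(data, (1.0, 1.0, 1.0)), RoiMask(mask, (1.0, 1.0, 1.0))
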