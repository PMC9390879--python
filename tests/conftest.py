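import numpy as np
import pytest

from destreak.geometry import ScanGeometry, default_geometry
from destreak.image import AttenuationImage


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def small_geometry():
    """Coarse parallel-beam geometry for fast unit tests (N=64 images)."""
    return default_geometry(64, n_views=90)


@pytest.fixture()
def random_image(rng):
    values = rng.random((64, 64))
    return AttenuationImage(values)


def bilinear_sample(values: np.ndarray, row: float, col: float) -> float:
    """Independent bilinear lookup (zero outside the grid) used by oracles."""
    n = values.shape[0]
    r0, c0 = int(np.floor(row)), int(np.floor(col))
    fr, fc = row - r0, col - c0
    total = 0.0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < n and 0 <= cc < n:
                total += values[rr, cc] * wr * wc
    return total
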