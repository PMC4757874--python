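import numpy as np
import pytest

from rodmap.ellipse import EllipseParams, rasterize_ellipse


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_rod(a: float, b: float, phi_deg: float, pad: int = 6) -> np.ndarray:
    """Rasterised solid ellipse centred in a square frame."""
    size = int(2 * a) + 2 * pad
    p = EllipseParams(a=a, b=b, xc=size / 2, yc=size / 2, phi_deg=phi_deg)
    return rasterize_ellipse(p, (size, size))


@pytest.fixture
def crossed_rods() -> np.ndarray:
    """Two rods crossing in an X: a single ragged component of low solidity."""
    m1 = rasterize_ellipse(EllipseParams(a=15, b=2.5, xc=20, yc=20, phi_deg=45), (40, 40))
    m2 = rasterize_ellipse(EllipseParams(a=15, b=2.5, xc=20, yc=20, phi_deg=135), (40, 40))
    return m1 | m2
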