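import numpy as np
import pytest

from gelcaller.image import GelImage
from gelcaller.lanes import Lane, LaneBoundary


def vertical_lane(pixels: np.ndarray, index: int = 0) -> Lane:
    """Wrap a pixel block as a Lane with trivial vertical boundaries."""
    H, W = pixels.shape
    left = LaneBoundary(((0.0, 0.0), (float(H), 0.0)))
    right = LaneBoundary(((0.0, float(W)), (float(H), float(W))))
    return Lane(index, left, right, W, pixels.astype(np.uint8))


def gaussian_band_lane(
    H: int = 120,
    W: int = 20,
    band_rows=(30, 60, 90),
    sigma: float = 2.0,
    peak: float = 180.0,
    base: float = 20.0,
    noise_sd: float = 0.0,
    shifts=None,
    seed: int = 0,
) -> Lane:
    """A single synthetic lane: Gaussian-profile bands, optional per-column shifts."""
    rng = np.random.default_rng(seed)
    rows = np.arange(H, dtype=float)[:, None]
    img = np.zeros((H, W))
    for r0 in band_rows:
        img += peak * np.exp(-((rows - r0) ** 2) / (2 * sigma**2))
    if shifts is not None:
        out = np.zeros_like(img)
        for n, s in enumerate(shifts):
            s = int(s)
            if s >= 0:
                out[s:, n] = img[: H - s, n]
            else:
                out[:s, n] = img[-s:, n]
        img = out
    img = img + base
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return vertical_lane(np.clip(img, 0, 255))


@pytest.fixture
def checker_image() -> GelImage:
    return GelImage(np.array([[0, 255], [128, 64]], dtype=np.uint8))
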