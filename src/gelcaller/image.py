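"""Reading, cropping and polarity normalisation of gel densitometry images.

Images are 8-bit grayscale rasters of a gel slab: rows are the migration
axis (wells at row 0), columns run across the lanes.  All downstream
analysis assumes the *bands-bright* convention — stained bands are high
intensities on a dark background — so silver-stain scans (dark bands on a
bright background) are inverted on the way in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

BANDS_BRIGHT = "bands_bright"
BANDS_DARK = "bands_dark"


@dataclass(frozen=True)
class GelImage:
    """A 2-D grid of 8-bit intensities p[m, n] with polarity metadata.

    ``pixels`` is indexed (row m, column n), 0-based, origin top-left;
    rows are the migration axis.
    """

    pixels: np.ndarray
    polarity: str = BANDS_BRIGHT
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"gel image must be a non-empty 2-D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.polarity not in (BANDS_BRIGHT, BANDS_DARK):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CropRect:
    """Half-open crop window, 0-based, top-left origin."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("crop height and width must be >= 1")
        if self.top < 0 or self.left < 0:
            raise ValueError("crop top/left must be >= 0")


def load_image(path: str) -> GelImage:
    """Read a PNG/TIFF raster as an 8-bit grayscale gel image.

    RGB inputs are converted to luminance; 16-bit inputs are rescaled
    into [0, 255].  Polarity is recorded as unknown-bright; call
    :func:`normalize_polarity` before analysis.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap decoder errors uniformly
        raise IOError(f"cannot read gel image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        # ITU-R 601 luma, the scikit-image rgb2gray weighting
        arr = arr[:, :, 0] * 0.299 + arr[:, :, 1] * 0.587 + arr[:, :, 2] * 0.114
    if arr.size == 0:
        raise ValueError(f"zero-area image: {path!r}")
    arr = arr.astype(np.float64)
    if arr.max() > 255:  # 16-bit input
        arr = arr * (255.0 / 65535.0)
    return GelImage(np.clip(np.rint(arr), 0, 255).astype(np.uint8), source_path=str(path))


def save_image(image: GelImage, path: str) -> None:
    """Write pixels losslessly (PNG recommended)."""
    iio.imwrite(path, image.pixels)


def crop(image: GelImage, rect: CropRect) -> GelImage:
    """Extract the sub-image under ``rect``; polarity is preserved."""
    if rect.top + rect.height > image.height:
        raise ValueError(
            f"crop bottom edge {rect.top + rect.height} exceeds image height {image.height}"
        )
    if rect.left + rect.width > image.width:
        raise ValueError(
            f"crop right edge {rect.left + rect.width} exceeds image width {image.width}"
        )
    sub = image.pixels[rect.top : rect.top + rect.height, rect.left : rect.left + rect.width]
    return GelImage(sub.copy(), polarity=image.polarity, source_path=image.source_path)


def _tail_compactness(mask: np.ndarray) -> float:
    """Fraction of masked pixels with at least 2 masked 8-neighbours.

    Bands are spatially compact stripes, so the intensity tail they occupy
    scores high; a tail made of scattered noise pixels scores low.
    """
    if not mask.any():
        return 0.0
    m = mask.astype(np.uint8)
    padded = np.pad(m, 1)
    neigh = np.zeros_like(m, dtype=np.int32)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            neigh += padded[1 + dr : 1 + dr + m.shape[0], 1 + dc : 1 + dc + m.shape[1]]
    return float((neigh[mask] >= 2).mean())


def infer_polarity(image: GelImage) -> str:
    """Guess whether bands are the bright or the dark extreme.

    Compares the spatial compactness of the darkest 5% of pixels against
    the brightest 5%: bands form compact horizontal stripes, background
    extremes are diffuse.  Falls back to bands-dark (the silver-stain
    convention) on a tie.
    """
    px = image.pixels
    lo = np.percentile(px, 5)
    hi = np.percentile(px, 95)
    dark_score = _tail_compactness(px <= lo)
    bright_score = _tail_compactness(px >= hi)
    if bright_score > dark_score:
        return BANDS_BRIGHT
    if dark_score > bright_score:
        return BANDS_DARK
    logger.info("polarity auto-detection tied; assuming bands_dark (silver stain)")
    return BANDS_DARK


def normalize_polarity(image: GelImage, mode: str = "auto") -> GelImage:
    """Return an image with bands as high intensities.

    ``mode`` names the polarity of the *input*: ``bands_bright`` (no-op),
    ``bands_dark`` (invert), or ``auto`` (infer from the image).
    """
    if mode == "auto":
        mode = infer_polarity(image)
        logger.info("auto polarity: input read as %s", mode)
    if mode == BANDS_BRIGHT:
        if image.polarity == BANDS_BRIGHT:
            return image
        return replace(image, polarity=BANDS_BRIGHT)
    if mode == BANDS_DARK:
        return GelImage(
            (255 - image.pixels.astype(np.int16)).astype(np.uint8),
            polarity=BANDS_BRIGHT,
            source_path=image.source_path,
        )
    raise ValueError(f"unknown polarity mode {mode!r}")
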