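"""Loading and normalisation of fluorescence microscopy frames.

Confocal frames of Iba1-stained whole-mount retina arrive as 8- or 16-bit
TIFF/PNG images, single-channel or RGB (microglia pseudo-coloured green).
This module turns them into the normalised grayscale field consumed by the
segmentation stage:

    integer pixels -> unit-range floats -> luma grayscale -> log enhancement
    -> min-max normalisation to [0, 1]

Log enhancement compresses the dynamic range so that dim processes survive
thresholding; it is computed as ``log(1 + kappa * v)`` (defined at v = 0)
followed by a min-max rescale, which reproduces the behaviour of a plain
logarithm plus unit-range normalisation without the singularity at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Full-precision NTSC luma coefficients (R, G, B); they sum to exactly 1
#: and round to the conventional 0.2989 / 0.5870 / 0.1140.
LUMA_WEIGHTS: tuple[float, float, float] = (
    0.298936021293776,
    0.587043074451121,
    0.114020904255103,
)

#: Default gain of the log enhancement ``v -> log(1 + kappa * v)``.
DEFAULT_KAPPA: float = 1000.0


class ImageFormatError(ValueError):
    """Raised for unsupported pixel formats (float samples, 2/4+ channels)."""


@dataclass
class RawImage:
    """An integer pixel grid as read from disk.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``(H, W)`` or ``(H, W, 3)`` unsigned-integer array.
    bit_depth : int
        8 or 16; all values lie in ``[0, 2**bit_depth - 1]``.
    source_path : str or None
        Where the image came from, for error messages and provenance.
    """

    pixels: np.ndarray
    bit_depth: int
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ImageFormatError(
                f"expected a 2-D or 3-D pixel grid, got ndim={self.pixels.ndim}"
            )
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ImageFormatError(
                f"expected 1 or 3 channels, got {self.pixels.shape[2]}"
            )
        if self.bit_depth not in (8, 16):
            raise ImageFormatError(f"unsupported bit depth {self.bit_depth}")
        maxval = 2**self.bit_depth - 1
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > maxval
        ):
            raise ImageFormatError(
                f"pixel values outside [0, {maxval}] for bit depth {self.bit_depth}"
            )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else int(self.pixels.shape[2])


@dataclass
class GrayImage:
    """A real-valued 2-D intensity field in [0, 1] with a provenance trail."""

    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"GrayImage must be 2-D, got ndim={self.values.ndim}")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("GrayImage values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def as_array(img) -> np.ndarray:
    """Coerce a GrayImage or array-like to a float ndarray."""
    return np.asarray(getattr(img, "values", img), dtype=float)


def load_image(path: str | Path) -> RawImage:
    """Read a TIFF or PNG image from disk.

    Bit depth is inferred from the stored sample type (uint8 -> 8,
    uint16 -> 16).  Floating-point samples and channel counts other than
    1 or 3 are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise OSError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ImageFormatError(
            f"unsupported sample format {arr.dtype} in {path}; expected uint8 or uint16"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:
        raise ImageFormatError(f"4-channel (RGBA) image not supported: {path}")
    return RawImage(pixels=arr, bit_depth=depth, source_path=str(path))


def to_float(img: RawImage) -> np.ndarray:
    """Scale integer pixels to [0, 1]: ``v -> v / (2**bit_depth - 1)``.

    Shape (including a channel axis) is preserved; ranks are preserved.
    """
    scale = float(2**img.bit_depth - 1)
    return img.pixels.astype(np.float64) / scale


def rgb_to_gray(arr: np.ndarray, weights: tuple[float, float, float] = LUMA_WEIGHTS) -> np.ndarray:
    """Collapse a 3-channel [0, 1] image to grayscale with fixed luma weights.

    Single-channel input is passed through unchanged (logged, not an error),
    so the preprocessing chain accepts both raw grayscale and RGB frames.
    """
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        logger.info("rgb_to_gray: single-channel input, passing through")
        return arr
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"expected (H, W, 3) input, got shape {arr.shape}")
    w = np.asarray(weights, dtype=float)
    return arr @ w


def log_enhance(img, kappa: float = DEFAULT_KAPPA) -> np.ndarray:
    """Dynamic-range compression ``v -> log(1 + kappa*v)``, rescaled to [0, 1].

    Strictly monotone in the input, so intensity ranks are preserved.  A
    constant image has no range to rescale and maps to all zeros by
    convention.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    values = as_array(img)
    out = np.log1p(kappa * values)
    return normalize_unit(out)


def normalize_unit(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant array maps to all zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    lo = float(values.min())
    hi = float(values.max())
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def preprocess_image(
    img: RawImage | str | Path,
    kappa: float = DEFAULT_KAPPA,
    apply_log: bool = True,
) -> GrayImage:
    """Full preprocessing chain: float conversion, grayscale collapse,
    optional log enhancement, and unit-range normalisation.

    Returns a :class:`GrayImage` whose provenance lists the applied steps.
    """
    if not isinstance(img, RawImage):
        img = load_image(img)
    steps = [f"to_float(bit_depth={img.bit_depth})"]
    values = to_float(img)
    if values.ndim == 3:
        values = rgb_to_gray(values)
        steps.append("rgb_to_gray")
    if apply_log:
        values = log_enhance(values, kappa=kappa)
        steps.append(f"log_enhance(kappa={kappa})")
    else:
        values = normalize_unit(values)
        steps.append("normalize_unit")
    return GrayImage(values=values, provenance=steps)


def save_preview(img, path: str | Path) -> None:
    """Write a GrayImage (or [0,1] array) as an 8-bit PNG preview."""
    values = as_array(img)
    out = np.clip(np.round(values * 255), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out)
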