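"""Otsu thresholding and binarisation of the normalised intensity field.

The segmentation stage assumes a roughly bimodal histogram — dark
background versus bright Iba1-labelled cells — and picks the global
threshold that maximises between-class variance (equivalently minimises
within-class variance) over a 256-bin histogram of [0, 1].  Foreground is
defined by the strict comparison ``value > threshold``, which makes
``threshold = 1.0`` yield an empty mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import as_array


class DegenerateImageError(ValueError):
    """Raised when an image is constant and no threshold separates anything.

    Callers batch-processing frames should catch this and skip the frame.
    """


@dataclass
class SegmentationResult:
    """Threshold, binary mask and the histogram the threshold came from."""

    threshold: float
    mask: np.ndarray
    histogram: np.ndarray


def _histogram(values: np.ndarray, n_bins: int) -> np.ndarray:
    counts, _ = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return counts


def otsu_threshold(img, n_bins: int = 256) -> float:
    """Between-class-variance-maximising threshold on an [0, 1] image.

    The histogram uses ``n_bins`` uniform bins over [0, 1]; candidate
    thresholds are the interior bin edges ``k / n_bins``.  A cut at edge k
    assigns bins ``0..k-1`` to the background class and ``k..n_bins-1`` to
    the foreground class.  Ties are broken by the smallest qualifying edge.

    Raises
    ------
    DegenerateImageError
        If the image is constant (fewer than two distinct values).
    """
    values = as_array(img)
    if values.size == 0 or np.all(values == values.flat[0]):
        raise DegenerateImageError(
            "constant image: no threshold separates two classes; skip this frame"
        )
    counts = _histogram(values, n_bins)
    total = counts.sum()
    p = counts / total
    bin_centers = (np.arange(n_bins) + 0.5) / n_bins

    # Cumulative class weight and mean for cuts k = 1..n_bins-1.
    w0 = np.cumsum(p)[:-1]
    mu_cum = np.cumsum(p * bin_centers)
    mu_total = mu_cum[-1]
    mu0_sum = mu_cum[:-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, mu0_sum / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_total - mu0_sum) / w1, 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(between)) + 1  # argmax returns the first (smallest) maximiser
    return k / n_bins


def binarize(img, t: float) -> np.ndarray:
    """Boolean foreground mask ``value > t``.

    Foreground shrinks (never grows) as ``t`` increases.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    return as_array(img) > t


def segment(img, threshold: float | None = None, n_bins: int = 256) -> SegmentationResult:
    """Segment an image, computing the Otsu threshold unless one is given."""
    values = as_array(img)
    t = otsu_threshold(values, n_bins=n_bins) if threshold is None else float(threshold)
    return SegmentationResult(
        threshold=t,
        mask=binarize(values, t),
        histogram=_histogram(values, n_bins),
    )
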