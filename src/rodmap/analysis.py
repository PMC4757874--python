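"""Aggregation of per-cell morphometry: angle histograms, timepoint
summaries, an axial uniformity statistic and the FFT spectral view.

Cell orientations are *axial* data — an angle and its opposite describe
the same cell axis — so they live on [0, 180) and are analysed by the
standard device of doubling onto the full circle.  The uniformity test is
the Rayleigh test on doubled angles: a significant result means the cells
share a preferred axis (the aligned, rod-microglia signature), while
non-significance is consistent with the even spread of resting or
amoeboid populations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .preprocess import as_array, normalize_unit

logger = logging.getLogger(__name__)

N_BINS = 180


@dataclass
class AngleHistogram:
    """Counts over 180 half-open 1-degree bins [k, k+1), k = 0..179."""

    counts: np.ndarray
    n_cells: int

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(N_BINS + 1, dtype=float)


@dataclass
class TimepointSummary:
    """Pooled morphometry for one post-lesion timepoint (several images)."""

    label: str
    n_images: int
    mean_hist: np.ndarray
    area_stats: dict[str, float]
    cell_counts: list[int]


class AxialUniformity(NamedTuple):
    r_bar: float
    p_value: float
    mean_axis_deg: float


def angle_histogram(angles: Sequence[float]) -> AngleHistogram:
    """Bin orientations into 1-degree bins over [0, 180).

    Bins are half-open [k, k+1); counts sum to the number of angles.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() >= 180):
        bad = arr[(arr < 0) | (arr >= 180)][0]
        raise ValueError(f"angle {bad} outside [0, 180)")
    counts, _ = np.histogram(arr, bins=N_BINS, range=(0.0, 180.0))
    return AngleHistogram(counts=counts.astype(float), n_cells=int(arr.size))


def average_histograms(hists: Sequence[AngleHistogram]) -> np.ndarray:
    """Elementwise mean of histogram counts across images.

    Averages raw counts (not frequencies); the result's sum equals the
    mean number of cells per image.
    """
    if len(hists) == 0:
        raise ValueError("need at least one histogram to average")
    return np.mean([h.counts for h in hists], axis=0)


def axial_uniformity(angles: Sequence[float]) -> AxialUniformity:
    """Rayleigh test for a preferred axis in orientation data.

    Angles are doubled onto the full circle; ``r_bar`` is the mean
    resultant length of the doubled angles (0 = uniform, 1 = fully
    concentrated), ``p_value`` uses the standard large-sample series
    approximation, and ``mean_axis_deg`` is half the circular mean of the
    doubled angles, folded to [0, 180).
    """
    arr = np.asarray(list(angles), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError(f"need at least 2 angles, got {n}")
    doubled = np.deg2rad(2.0 * arr)
    c = float(np.cos(doubled).mean())
    s = float(np.sin(doubled).mean())
    r_bar = math.hypot(c, s)
    z = n * r_bar * r_bar
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    mean_axis = (math.degrees(math.atan2(s, c)) / 2.0) % 180.0
    return AxialUniformity(r_bar=r_bar, p_value=p, mean_axis_deg=mean_axis)


def summarize_timepoint(
    per_image: Sequence[tuple[AngleHistogram, Sequence[float]]],
    label: str = "",
) -> TimepointSummary:
    """Pool several images of one timepoint.

    ``per_image`` pairs each image's angle histogram with its kept-cell
    weighted areas.  Area statistics are pooled over all cells (quartiles
    by linear interpolation); per-image cell counts are retained.  Images
    with zero kept cells contribute nothing to the area pool but still
    count toward the histogram average.
    """
    if len(per_image) == 0:
        raise ValueError("need at least one image")
    hists = [h for h, _ in per_image]
    all_areas: list[float] = []
    cell_counts: list[int] = []
    for h, areas in per_image:
        cell_counts.append(int(h.n_cells))
        if len(areas) == 0:
            logger.warning("image with zero kept cells included in timepoint %r", label)
        all_areas.extend(float(a) for a in areas)
    if all_areas:
        arr = np.asarray(all_areas)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        stats = {
            "mean": float(arr.mean()),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    else:
        stats = {k: float("nan") for k in ("mean", "median", "q1", "q3", "min", "max")}
    return TimepointSummary(
        label=label,
        n_images=len(per_image),
        mean_hist=average_histograms(hists),
        area_stats=stats,
        cell_counts=cell_counts,
    )


def spectral_view(img) -> np.ndarray:
    """Log-magnitude 2-D Fourier spectrum, centred and rescaled to [0, 1].

    Aligned rod populations concentrate off-centre spectral energy along
    the axis perpendicular to the rod orientation; an even spread of
    orientations produces an isotropic spectrum.
    """
    values = as_array(img)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got shape {values.shape}")
    spectrum = np.fft.fftshift(np.fft.fft2(values))
    return normalize_unit(np.log1p(np.abs(spectrum)))
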