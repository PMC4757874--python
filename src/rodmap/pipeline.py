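"""End-to-end orchestration: image in, per-cell morphometry table out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import components as comp
from . import ellipse as ell
from .preprocess import DEFAULT_KAPPA, GrayImage, RawImage, preprocess_image
from .segment import SegmentationResult, segment

#: Columns of the per-cell output table (cells.csv).
TABLE_COLUMNS = [
    "id", "pixel_count", "weighted_area",
    "bbox_rmin", "bbox_cmin", "bbox_rmax", "bbox_cmax",
    "solidity", "status",
    "a", "b", "Xc", "Yc", "phi_deg", "fit_score", "converged",
]


@dataclass
class FrameResult:
    """Everything computed for one frame."""

    gray: GrayImage | None
    segmentation: SegmentationResult
    records: list[comp.ComponentRecord]
    fits: dict[int, ell.FitResult]
    table: pd.DataFrame

    @property
    def kept_angles(self) -> list[float]:
        return [
            ell.cell_angle(self.fits[r.id].params)
            for r in self.records
            if r.status == comp.STATUS_KEPT and r.id in self.fits
        ]

    @property
    def kept_areas(self) -> list[float]:
        return [r.weighted_area for r in self.records if r.status == comp.STATUS_KEPT]


def measure_mask(
    mask: np.ndarray,
    min_pixels: int = comp.DEFAULT_MIN_PIXELS,
    solidity_min: float = comp.DEFAULT_SOLIDITY_MIN,
    connectivity: int = 8,
    fit_mode: str = "approx",
    exclude: set[int] | None = None,
) -> tuple[list[comp.ComponentRecord], dict[int, ell.FitResult]]:
    """Detect, flag and ellipse-fit the components of a binary mask.

    Ellipses are fitted only to kept components; unfittable ones (fewer
    than 3 pixels, normally caught by the noise filter) are annotated and
    skipped rather than aborting the batch.
    """
    records = comp.find_components(mask, connectivity=connectivity)
    comp.filter_small(records, min_pixels=min_pixels)
    comp.flag_overlaps(records, solidity_min=solidity_min)
    if exclude:
        comp.exclude_ids(records, exclude)
    fits: dict[int, ell.FitResult] = {}
    for rec in records:
        if rec.status != comp.STATUS_KEPT:
            continue
        try:
            fits[rec.id] = ell.fit_ellipse(rec, mode=fit_mode)
        except ell.UnfittableComponentError as exc:
            rec.notes.append(str(exc))
    return records, fits


def results_table(
    records: list[comp.ComponentRecord], fits: dict[int, ell.FitResult]
) -> pd.DataFrame:
    """One row per component (including flagged ones), ellipse columns
    NaN where no fit was made."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "pixel_count": r.pixel_count,
            "weighted_area": r.weighted_area,
            "bbox_rmin": r.bbox[0],
            "bbox_cmin": r.bbox[1],
            "bbox_rmax": r.bbox[2],
            "bbox_cmax": r.bbox[3],
            "solidity": r.solidity,
            "status": r.status,
        }
        fit = fits.get(r.id)
        if fit is not None:
            row.update(
                a=fit.params.a, b=fit.params.b,
                Xc=fit.params.xc, Yc=fit.params.yc,
                phi_deg=ell.cell_angle(fit.params),
                fit_score=fit.score, converged=fit.converged,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def analyze_frame(
    img: RawImage | np.ndarray | str,
    kappa: float = DEFAULT_KAPPA,
    apply_log: bool = True,
    threshold: float | None = None,
    n_bins: int = 256,
    min_pixels: int = comp.DEFAULT_MIN_PIXELS,
    solidity_min: float = comp.DEFAULT_SOLIDITY_MIN,
    connectivity: int = 8,
    fit_mode: str = "approx",
) -> FrameResult:
    """Run the full pipeline on a raw frame (path, RawImage, or uint array).

    ``threshold`` overrides Otsu's automatic choice when given (the
    sensitivity-study workflow); all other stages run with their defaults
    unless configured.
    """
    if isinstance(img, np.ndarray) and img.dtype.kind == "u":
        depth = 16 if img.dtype == np.uint16 else 8
        img = RawImage(pixels=img, bit_depth=depth)
    gray = preprocess_image(img, kappa=kappa, apply_log=apply_log)
    seg = segment(gray, threshold=threshold, n_bins=n_bins)
    records, fits = measure_mask(
        seg.mask,
        min_pixels=min_pixels,
        solidity_min=solidity_min,
        connectivity=connectivity,
        fit_mode=fit_mode,
    )
    return FrameResult(
        gray=gray,
        segmentation=seg,
        records=records,
        fits=fits,
        table=results_table(records, fits),
    )
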