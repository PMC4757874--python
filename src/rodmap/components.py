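"""Cell detection on the binary mask: connected components, noise and
overlap flagging, and weighted pixel-area estimation.

Each microglial cell is one connected component (CC) of the foreground,
using 8-connectivity by default (a pixel's neighbours share an edge or a
corner).  Components are never deleted — small ones are flagged ``noise``
and ragged/merged ones ``overlap_excluded`` — so every detection remains
auditable in the output table.

The cell area is not the raw pixel count but a weighted count over all
2x2 windows of the (zero-padded) mask, which compensates for the staircase
bias of rasterised boundaries.  The six window rules are:

    no foreground pixel          -> 0
    one foreground pixel         -> 1/4
    two edge-adjacent pixels     -> 1/2
    two diagonal pixels          -> 3/4
    three foreground pixels      -> 7/8
    four foreground pixels       -> 1

Summed over all windows, a solid m x n rectangle scores exactly m*n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

logger = logging.getLogger(__name__)

STATUS_KEPT = "kept"
STATUS_NOISE = "noise"
STATUS_OVERLAP = "overlap_excluded"

#: Default minimum component size in pixels; smaller components are
#: flagged as noise (speckle from shot noise and staining debris).
DEFAULT_MIN_PIXELS = 20

#: Default solidity (pixels / convex-hull pixels) below which a component
#: is treated as severely overlapping cells and excluded from analysis.
DEFAULT_SOLIDITY_MIN = 0.5


@dataclass
class ComponentRecord:
    """One detected cell candidate.

    ``rows``/``cols`` hold the component's pixel coordinates (0-based,
    row increasing downward); ``bbox`` is (row_min, col_min, row_max,
    col_max), inclusive.
    """

    id: int
    rows: np.ndarray
    cols: np.ndarray
    bbox: tuple[int, int, int, int]
    pixel_count: int
    weighted_area: float
    solidity: float
    status: str = STATUS_KEPT
    notes: list[str] = field(default_factory=list)

    @property
    def pixels(self) -> set[tuple[int, int]]:
        """Pixel set as (row, col) tuples."""
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def local_mask(self, pad: int = 1) -> np.ndarray:
        """Boolean mask of this component in its padded bounding box."""
        r0, c0, r1, c1 = self.bbox
        h = r1 - r0 + 1 + 2 * pad
        w = c1 - c0 + 1 + 2 * pad
        m = np.zeros((h, w), dtype=bool)
        m[self.rows - r0 + pad, self.cols - c0 + pad] = True
        return m


_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def _solidity(local: np.ndarray, n_pixels: int) -> float:
    if n_pixels <= 2:
        return 1.0
    hull = convex_hull_image(local)
    return n_pixels / int(hull.sum())


def find_components(mask: np.ndarray, connectivity: int = 8) -> list[ComponentRecord]:
    """Detect connected components of a boolean mask.

    Components are labelled in raster-scan order of their first pixel.
    8-connectivity links edge and corner neighbours; 4-connectivity links
    edge neighbours only.  An empty mask yields an empty list.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []

    # Order labels by the raster index of each component's first pixel.
    flat = labels.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nonzero = np.flatnonzero(flat)
    # reversed so earlier raster indices overwrite later ones
    first_idx[flat[nonzero[::-1]]] = nonzero[::-1]
    order = np.argsort(first_idx[1:], kind="stable")

    objects = ndimage.find_objects(labels)
    records: list[ComponentRecord] = []
    for new_id, old in enumerate(order + 1, start=1):
        sl = objects[old - 1]
        sub = labels[sl] == old
        rr, cc = np.nonzero(sub)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
        local = np.pad(sub, 1)
        records.append(
            ComponentRecord(
                id=new_id,
                rows=rows,
                cols=cols,
                bbox=bbox,
                pixel_count=int(rows.size),
                weighted_area=weighted_area_padded(local),
                solidity=_solidity(sub, int(rows.size)),
            )
        )
    return records


def filter_small(
    ccs: list[ComponentRecord], min_pixels: int = DEFAULT_MIN_PIXELS
) -> list[ComponentRecord]:
    """Flag components below ``min_pixels`` as noise; nothing is deleted."""
    if min_pixels < 1:
        raise ValueError(f"min_pixels must be >= 1, got {min_pixels}")
    for cc in ccs:
        if cc.pixel_count < min_pixels and cc.status == STATUS_KEPT:
            cc.status = STATUS_NOISE
            cc.notes.append(f"pixel_count {cc.pixel_count} < min_pixels {min_pixels}")
    return ccs


def flag_overlaps(
    ccs: list[ComponentRecord], solidity_min: float = DEFAULT_SOLIDITY_MIN
) -> list[ComponentRecord]:
    """Flag ragged components (solidity below ``solidity_min``) as merged
    cells to be excluded from orientation analysis.

    Solidity is pixel count over convex-hull pixel count; crossing or
    touching rods produce concave unions with markedly lower solidity than
    any single convex soma.  Status counts are reported in the run log.
    """
    for cc in ccs:
        if cc.status == STATUS_KEPT and cc.solidity < solidity_min:
            cc.status = STATUS_OVERLAP
            cc.notes.append(f"solidity {cc.solidity:.3f} < {solidity_min}")
    counts: dict[str, int] = {}
    for cc in ccs:
        counts[cc.status] = counts.get(cc.status, 0) + 1
    logger.info("component statuses: %s", counts)
    return ccs


def exclude_ids(ccs: list[ComponentRecord], ids: set[int]) -> list[ComponentRecord]:
    """Manually exclude specific component IDs (curation escape hatch)."""
    for cc in ccs:
        if cc.id in ids:
            cc.status = STATUS_OVERLAP
            cc.notes.append("manually excluded")
    return ccs


def pattern_weight(window) -> float:
    """Area weight of a single 2x2 boolean window under the six rules."""
    w = np.asarray(window, dtype=bool)
    if w.shape != (2, 2):
        raise ValueError(f"window must be 2x2, got shape {w.shape}")
    n = int(w.sum())
    if n == 2:
        diagonal = (w[0, 0] and w[1, 1]) or (w[0, 1] and w[1, 0])
        return 0.75 if diagonal else 0.5
    return {0: 0.0, 1: 0.25, 3: 0.875, 4: 1.0}[n]


def weighted_area(mask: np.ndarray) -> float:
    """Weighted area of a mask: sum of ``pattern_weight`` over all 2x2
    windows after zero-padding by one pixel on every side.

    The padding guarantees each boundary pixel contributes its full four
    windows, making the measure translation invariant and additive over
    components separated by at least two background pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    return weighted_area_padded(np.pad(mask, 1))


def weighted_area_padded(padded: np.ndarray) -> float:
    """Weighted area of an already zero-padded mask (vectorised)."""
    p = np.asarray(padded, dtype=np.uint8)
    if p.shape[0] < 2 or p.shape[1] < 2:
        return 0.0
    a = p[:-1, :-1]
    b = p[:-1, 1:]
    c = p[1:, :-1]
    d = p[1:, 1:]
    n = a + b + c + d
    weights = np.array([0.0, 0.25, 0.5, 0.875, 1.0])
    w = weights[n]
    diag = (n == 2) & (((a == 1) & (d == 1)) | ((b == 1) & (c == 1)))
    w[diag] = 0.75
    return float(w.sum())
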