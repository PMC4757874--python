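"""Ellipse approximation of detected cells and orientation extraction.

Each kept component CC is approximated by a 5-parameter ellipse
``(a, b, Xc, Yc, phi)`` — semi-major axis, semi-minor axis, centre, and
the angle between the major axis and the horizontal.  The fit maximises

    objective(E, CC) = |E ∩ CC| − |E Δ CC|

over the rasterised candidate ellipse E: overlap is rewarded while both
missed cell area and spurious ellipse area are penalised symmetrically.
The maximum, |CC|, is attained exactly when E = CC.

Angle convention
----------------
``phi`` is measured counterclockwise from the +x (column) axis in standard
mathematical orientation, i.e. with y pointing *up*: the vertical offset of
a pixel at row r from the centre is ``Yc − r``.  Row-down rasters flip the
sign of naive atan2 angles; all orientations in this package use this y-up
convention and are folded into [0, 180) (an orientation, not a direction).
For an isotropic region (a = b) the angle is 0 by convention.

An alternative ``cover`` mode fits the minimum-area ellipse enclosing the
component's pixel centres (Khachiyan's algorithm on the convex hull); it
generally disagrees with the overlap criterion for ragged cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial import ConvexHull, QhullError

from .components import ComponentRecord


class UnfittableComponentError(ValueError):
    """Component too small to orient (fewer than 3 pixels)."""


@dataclass
class EllipseParams:
    """Five-parameter ellipse: semi-axes a >= b > 0 (pixels), centre
    (xc, yc) in pixel coordinates (xc = column, yc = row), and orientation
    phi_deg in [0, 180) measured y-up from the +x axis."""

    a: float
    b: float
    xc: float
    yc: float
    phi_deg: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"semi-axes must be positive, got a={self.a}, b={self.b}")
        if self.b > self.a:
            raise ValueError(f"require a >= b, got a={self.a}, b={self.b}")
        self.phi_deg = float(self.phi_deg) % 180.0


@dataclass
class FitResult:
    """Fitted ellipse plus the criterion value it achieves."""

    params: EllipseParams
    score: float
    ellipse_pixel_count: int
    converged: bool


def _canonical(a: float, b: float, phi_deg: float) -> tuple[float, float, float]:
    """Enforce a >= b by swapping axes and rotating phi by 90 degrees."""
    if b > a:
        a, b = b, a
        phi_deg += 90.0
    return a, b, phi_deg % 180.0


def rasterize_ellipse(p: EllipseParams, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the ellipse.

    Pixel (r, c) is foreground iff, with dx = c − xc and dy = yc − r
    (y-up) and theta = phi in radians,

        ((dx cosθ + dy sinθ)/a)² + ((−dx sinθ + dy cosθ)/b)² <= 1.
    """
    return _rasterize(p.a, p.b, p.xc, p.yc, p.phi_deg, shape)


def _rasterize(a, b, xc, yc, phi_deg, shape) -> np.ndarray:
    if a <= 0 or b <= 0:
        raise ValueError(f"semi-axes must be positive, got a={a}, b={b}")
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    dx = cc - xc
    dy = yc - rr
    theta = math.radians(phi_deg)
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return u * u + v * v <= 1.0


def objective(ellipse_mask: np.ndarray, cc_mask: np.ndarray) -> int:
    """|E ∩ CC| − |E Δ CC|; maximal value |CC|, attained iff E = CC."""
    e = np.asarray(ellipse_mask, dtype=bool)
    c = np.asarray(cc_mask, dtype=bool)
    if e.shape != c.shape:
        raise ValueError(f"shape mismatch: {e.shape} vs {c.shape}")
    inter = int(np.count_nonzero(e & c))
    sym = int(np.count_nonzero(e ^ c))
    return inter - sym


def _moments_from_pixels(rows: np.ndarray, cols: np.ndarray):
    """Centroid, regularised second central moments (y-up) and orientation.

    The covariance of pixel centres is regularised by the intra-pixel
    variance 1/12 per axis (a pixel is a unit square, not a point), which
    removes the axis-length bias for thin rods and makes collinear runs
    well-posed.
    """
    x = cols.astype(float)
    y = -rows.astype(float)  # y-up
    xc = x.mean()
    yc = y.mean()
    dx = x - xc
    dy = y - yc
    n = x.size
    mu20 = float(dx @ dx) / n + 1.0 / 12.0
    mu02 = float(dy @ dy) / n + 1.0 / 12.0
    mu11 = float(dx @ dy) / n
    if mu11 == 0.0 and mu20 == mu02:
        phi = 0.0  # isotropic tie rule
    else:
        phi = math.degrees(0.5 * math.atan2(2.0 * mu11, mu20 - mu02)) % 180.0
    common = (mu20 + mu02) / 2.0
    diff = math.hypot(mu20 - mu02, 2.0 * mu11) / 2.0
    lam1 = common + diff
    lam2 = max(common - diff, 1e-9)
    return xc, -yc, phi, lam1, lam2  # return yc back in row coordinates


def moment_init(cc: ComponentRecord | np.ndarray) -> EllipseParams:
    """Moment-based starting ellipse for a component.

    Centre at the pixel centroid; orientation from the second central
    moments, ``phi = 1/2 · atan2(2 μ11, μ20 − μ02)`` (y-up) folded to
    [0, 180); axes ``2 √λ`` from the moment eigenvalues, matching the
    second moments of a solid ellipse (variance a²/4 along the major axis).
    """
    rows, cols = _pixels_of(cc)
    if rows.size < 3:
        raise UnfittableComponentError(
            f"component has {rows.size} pixels; at least 3 required to orient"
        )
    xc, yc, phi, lam1, lam2 = _moments_from_pixels(rows, cols)
    a = 2.0 * math.sqrt(lam1)
    b = 2.0 * math.sqrt(lam2)
    a, b, phi = _canonical(a, b, phi)
    return EllipseParams(a=a, b=b, xc=xc, yc=yc, phi_deg=phi)


def _pixels_of(cc) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(cc, ComponentRecord):
        return cc.rows, cc.cols
    mask = np.asarray(cc, dtype=bool)
    rr, cols = np.nonzero(mask)
    return rr, cols


def fit_ellipse(
    cc: ComponentRecord | np.ndarray,
    mode: str = "approx",
    max_iter: int = 400,
    xatol: float = 1e-3,
) -> FitResult:
    """Fit the approximating (or covering) ellipse for one component.

    ``approx`` (default) refines the moment initialiser by Nelder-Mead
    simplex search on the overlap criterion, evaluated on the component's
    padded bounding box; the returned score never falls below the
    initialiser's (monotone refinement), and an optimizer failure falls
    back to the initialiser with ``converged=False`` so batch runs never
    crash.  ``cover`` computes the minimum-area ellipse enclosing the
    pixel centres instead.
    """
    rows, cols = _pixels_of(cc)
    if mode == "cover":
        params = min_cover_ellipse(rows, cols)
        return _finalize(params, rows, cols, converged=True)
    if mode != "approx":
        raise ValueError(f"unknown fit mode {mode!r}")

    init = moment_init(cc)

    # Work in a local frame: component bbox padded enough for the ellipse
    # to move and grow without clipping.
    r0, c0 = int(rows.min()), int(cols.min())
    pad = int(math.ceil(init.a)) + 3
    lr = rows - r0 + pad
    lc = cols - c0 + pad
    shape = (int(lr.max()) + pad + 1, int(lc.max()) + pad + 1)
    cc_local = np.zeros(shape, dtype=bool)
    cc_local[lr, lc] = True

    x0 = np.array(
        [init.a, init.b, init.xc - c0 + pad, init.yc - r0 + pad, init.phi_deg]
    )

    def neg_score(x: np.ndarray) -> float:
        a, b = abs(x[0]), abs(x[1])
        if a < 0.2 or b < 0.2 or max(a, b) > max(shape):
            return float(len(rows))  # worse than any sane candidate
        e = _rasterize(a, b, x[2], x[3], x[4], shape)
        return -float(objective(e, cc_local))

    score0 = -neg_score(x0)
    converged = False
    best_x = x0
    best_score = score0
    try:
        res = optimize.minimize(
            neg_score,
            x0,
            method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": xatol, "fatol": 0.49},
        )
        if -res.fun >= best_score:
            best_x = res.x
            best_score = -res.fun
            converged = bool(res.success) or -res.fun > score0
    except Exception:  # pragma: no cover - optimizer failure fallback
        converged = False

    a, b, phi = _canonical(abs(best_x[0]), abs(best_x[1]), float(best_x[4]))
    params = EllipseParams(
        a=a, b=b, xc=float(best_x[2]) + c0 - pad, yc=float(best_x[3]) + r0 - pad,
        phi_deg=phi,
    )
    return _finalize(params, rows, cols, converged=converged)


def _finalize(params: EllipseParams, rows, cols, converged: bool) -> FitResult:
    """Score the final parameters against the component in a local frame."""
    r0 = int(rows.min())
    c0 = int(cols.min())
    pad = int(math.ceil(params.a)) + 3
    shape = (int(rows.max()) - r0 + 2 * pad + 1, int(cols.max()) - c0 + 2 * pad + 1)
    cc_local = np.zeros(shape, dtype=bool)
    cc_local[rows - r0 + pad, cols - c0 + pad] = True
    local = EllipseParams(
        a=params.a, b=params.b,
        xc=params.xc - c0 + pad, yc=params.yc - r0 + pad,
        phi_deg=params.phi_deg,
    )
    e = rasterize_ellipse(local, shape)
    return FitResult(
        params=params,
        score=float(objective(e, cc_local)),
        ellipse_pixel_count=int(e.sum()),
        converged=converged,
    )


def cell_angle(p: EllipseParams) -> float:
    """Orientation of the cell in degrees, in [0, 180).

    For an isotropic ellipse (a == b) the orientation is undefined and 0
    is returned by convention.
    """
    if math.isclose(p.a, p.b, rel_tol=1e-9, abs_tol=1e-9):
        return 0.0
    return p.phi_deg % 180.0


def min_cover_ellipse(rows: np.ndarray, cols: np.ndarray, tol: float = 1e-5) -> EllipseParams:
    """Minimum-area ellipse enclosing the pixel centres of a component.

    Khachiyan's iterative algorithm on the convex hull vertices.  Returns
    canonical parameters (a >= b, phi in [0, 180), y-up convention).
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    if rows.size < 3:
        raise UnfittableComponentError(
            f"component has {rows.size} pixels; at least 3 required"
        )
    pts = np.column_stack([cols, -rows])  # y-up plane
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # collinear points: run Khachiyan on the raw (degenerate) set

    n, d = pts.shape
    q = np.column_stack([pts, np.ones(n)]).T  # (3, n)
    u = np.full(n, 1.0 / n)
    err = tol + 1.0
    for _ in range(1000):
        if err <= tol:
            break
        x_mat = q @ np.diag(u) @ q.T
        m = np.einsum("ij,ji->i", q.T, np.linalg.solve(x_mat, q))
        j = int(np.argmax(m))
        step = (m[j] - d - 1.0) / ((d + 1.0) * (m[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        err = float(np.linalg.norm(new_u - u))
        u = new_u

    center = pts.T @ u
    cov = pts.T @ np.diag(u) @ pts - np.outer(center, center)
    cov += np.eye(2) * 1e-9  # keep invertible for (near-)collinear hulls
    # ellipse matrix: (x-c)^T A (x-c) <= 1 with A = inv(cov)/d
    A = np.linalg.inv(cov) / d
    eigvals, eigvecs = np.linalg.eigh(A)
    axes = 1.0 / np.sqrt(eigvals)  # ascending eigvals -> descending axes
    major = axes[0] if axes[0] >= axes[1] else axes[1]
    minor = axes[1] if axes[0] >= axes[1] else axes[0]
    vec = eigvecs[:, 0] if axes[0] >= axes[1] else eigvecs[:, 1]
    phi = math.degrees(math.atan2(vec[1], vec[0])) % 180.0
    # inflate by half a pixel so the ellipse covers pixel extents, not only centres
    major += 0.5
    minor += 0.5
    if math.isclose(major, minor, rel_tol=1e-9):
        phi = 0.0
    return EllipseParams(a=major, b=minor, xc=float(center[0]), yc=float(-center[1]), phi_deg=phi)
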