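"""Per-object morphometrics: moments, best-fit-ellipse axes, convex hull, shape.

Each labeled object is reduced to a handful of field-standard descriptors:

* ``IS`` — inflorescence size, the pixel count scaled to cm²;
* ``IL``/``IW`` — length and width of the best-fit ellipse, the ellipse whose
  second-order central moments match the object's;
* ``CH``/``HP`` — area and perimeter of the convex hull;
* ``ISH`` — shape ratio IW/IL (1 = circular, → 0 = elongated).

The moment-to-axis conversion is

    length = 2·sqrt(2) · sqrt((u20 + u02 + sqrt((u20 − u02)² + 4·u11²)) / u00)

(width with the inner root subtracted), where ``u_pq`` are central second
moments and ``u00`` the point count.  The 2·sqrt(2) constant calibrates the
formula for *filled* regions: for an ideal filled ellipse it returns the exact
axis lengths.  Feeding boundary pixels instead (an option kept for
compatibility with other tools) inflates a disk's diameter by sqrt(2), which
is why region moments are the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MomentSet:
    """Central moments of a planar point set.

    ``u00`` is the point count; ``u20``, ``u02``, ``u11`` are the second
    central moments (sums, not normalized).
    """

    u00: float
    u20: float
    u02: float
    u11: float
    centroid_x: float
    centroid_y: float


def central_moments(points: np.ndarray) -> MomentSet:
    """Central moments up to order two of a set of (x, y) positions."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    cx, cy = pts.mean(axis=0)
    dx = pts[:, 0] - cx
    dy = pts[:, 1] - cy
    return MomentSet(
        u00=float(pts.shape[0]),
        u20=float(np.dot(dx, dx)),
        u02=float(np.dot(dy, dy)),
        u11=float(np.dot(dx, dy)),
        centroid_x=float(cx),
        centroid_y=float(cy),
    )


def ellipse_axes(m: MomentSet) -> tuple[float, float]:
    """Best-fit-ellipse (length, width) in pixels from central moments."""
    if m.u00 <= 0:
        raise ValueError("u00 must be positive")
    root = math.hypot(m.u20 - m.u02, 2.0 * m.u11)
    trace = m.u20 + m.u02
    length = 2.0 * math.sqrt(2.0) * math.sqrt(max(trace + root, 0.0) / m.u00)
    width = 2.0 * math.sqrt(2.0) * math.sqrt(max(trace - root, 0.0) / m.u00)
    return length, width


def boundary_pixels(pixels: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Object pixels that touch the background.

    A pixel belongs to the boundary when at least one of its neighbors (under
    the given adjacency; default 4) is not part of the object.
    """
    pts = np.asarray(pixels)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("pixels must be a non-empty (n, 2) integer array")
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        offsets = [
            (dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
        ]
    else:
        raise ValueError("connectivity must be 4 or 8")
    members = {(int(x), int(y)) for x, y in pts}
    out = [
        (x, y)
        for (x, y) in members
        if any((x + dx, y + dy) not in members for dx, dy in offsets)
    ]
    out.sort(key=lambda p: (p[1], p[0]))  # raster order for determinism
    return np.asarray(out, dtype=pts.dtype)


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull by Andrew's monotone chain, as a counter-clockwise polygon.

    Collinear points on hull edges are excluded.  One or two distinct input
    points return the degenerate 1- or 2-vertex "polygon".
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    uniq = np.unique(pts, axis=0)  # lexicographic sort on (x, y)
    if uniq.shape[0] <= 2:
        return uniq

    def half_chain(seq):
        chain: list[np.ndarray] = []
        for p in seq:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half_chain(uniq)
    upper = half_chain(uniq[::-1])
    hull = lower[:-1] + upper[:-1]
    return np.asarray(hull)


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a polygon; degenerate (<3 vertices) polygons return 0."""
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("vertices must be an (n, 2) array")
    if v.shape[0] < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def polygon_perimeter(vertices: np.ndarray) -> float:
    """Closed-loop perimeter; a 2-vertex polygon counts the segment out and back."""
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("perimeter needs at least 2 vertices")
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def pixel_corners(pixels: np.ndarray) -> np.ndarray:
    """The four corner points of every pixel (centers at integer coordinates)."""
    pts = np.asarray(pixels, dtype=np.float64)
    shifts = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (pts[:, None, :] + shifts[None, :, :]).reshape(-1, 2)
    return np.unique(corners, axis=0)


@dataclass(frozen=True)
class ObjectRecord:
    """Morphometrics of one inflorescence, in absolute units.

    ``degenerate`` flags objects (single pixels, collinear pixel runs) whose
    width is zero; their ``ISH`` is NaN and they are excluded from shape
    statistics downstream.
    """

    object_id: int
    pixel_count: int
    IS_cm2: float
    IL_cm: float
    IW_cm: float
    CH_cm2: float
    HP_cm: float
    ISH: float
    centroid_x_px: float
    centroid_y_px: float

    @property
    def degenerate(self) -> bool:
        return not (self.IW_cm > 0 and self.IL_cm > 0)


def measure_object(
    pixels: np.ndarray,
    cm_per_pixel: float,
    object_id: int = 0,
    moment_source: str = "region",
    hull_points: str = "corners",
) -> ObjectRecord:
    """Measure one object given its pixel positions ``(x, y)`` and the scale.

    ``moment_source`` selects the point set for the ellipse moments: all
    object pixels (``"region"``, default — the calibration the axis formula
    assumes) or only boundary pixels (``"boundary"``).  ``hull_points``
    selects whether the convex hull is taken over pixel corner points
    (``"corners"``, default — guarantees the hull encloses the full pixel
    area, so CH ≥ IS) or pixel centers (``"centers"``).
    """
    if cm_per_pixel <= 0:
        raise ValueError("cm_per_pixel must be positive")
    pts = np.asarray(pixels)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("pixels must be a non-empty (n, 2) array")

    if moment_source == "region":
        moment_pts = pts
    elif moment_source == "boundary":
        moment_pts = boundary_pixels(pts)
    else:
        raise ValueError("moment_source must be 'region' or 'boundary'")
    m = central_moments(moment_pts)
    length_px, width_px = ellipse_axes(m)

    if hull_points == "corners":
        hull_pts = pixel_corners(pts)
    elif hull_points == "centers":
        hull_pts = pts
    else:
        raise ValueError("hull_points must be 'corners' or 'centers'")
    hull = convex_hull(hull_pts)

    p = float(cm_per_pixel)
    n_a = int(pts.shape[0])
    il = length_px * p
    iw = width_px * p
    return ObjectRecord(
        object_id=object_id,
        pixel_count=n_a,
        IS_cm2=n_a * p * p,
        IL_cm=il,
        IW_cm=iw,
        CH_cm2=polygon_area(hull) * p * p,
        HP_cm=(polygon_perimeter(hull) if hull.shape[0] >= 2 else 0.0) * p,
        ISH=(iw / il) if (iw > 0 and il > 0) else float("nan"),
        centroid_x_px=m.centroid_x,
        centroid_y_px=m.centroid_y,
    )


def measure_labels(
    labeled,
    cm_per_pixel: float,
    image_id: str = "",
    moment_source: str = "region",
    hull_points: str = "corners",
):
    """Measure every labeled object of a scene into a tidy table.

    Returns a pandas DataFrame with one row per object, columns
    ``image_id, object_id, pixel_count, IS_cm2, IL_cm, IW_cm, CH_cm2, HP_cm,
    ISH, centroid_x_px, centroid_y_px``.
    """
    import pandas as pd

    rows: list[dict] = []
    for idx, pts in enumerate(labeled.pixel_sets(), start=1):
        rec = measure_object(
            pts,
            cm_per_pixel,
            object_id=idx,
            moment_source=moment_source,
            hull_points=hull_points,
        )
        rows.append(
            {
                "image_id": image_id,
                "object_id": rec.object_id,
                "pixel_count": rec.pixel_count,
                "IS_cm2": rec.IS_cm2,
                "IL_cm": rec.IL_cm,
                "IW_cm": rec.IW_cm,
                "CH_cm2": rec.CH_cm2,
                "HP_cm": rec.HP_cm,
                "ISH": rec.ISH,
                "centroid_x_px": rec.centroid_x_px,
                "centroid_y_px": rec.centroid_y_px,
            }
        )
    columns = [
        "image_id",
        "object_id",
        "pixel_count",
        "IS_cm2",
        "IL_cm",
        "IW_cm",
        "CH_cm2",
        "HP_cm",
        "ISH",
        "centroid_x_px",
        "centroid_y_px",
    ]
    return pd.DataFrame(rows, columns=columns)
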