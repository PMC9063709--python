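"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: flood fill
by explicit BFS, hull membership by O(n³) triangle tests, areas by fan
triangulation — so each test compares two independent routes to the same
answer.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest


def rasterize_ellipse(a_px: float, b_px: float, angle_deg: float = 0.0) -> np.ndarray:
    """Pixel centers (x, y) inside an ellipse with semi-axes a, b rotated by angle."""
    half = int(math.ceil(max(a_px, b_px))) + 2
    xs = np.arange(-half, half + 1, dtype=np.float64)
    gx, gy = np.meshgrid(xs, xs)
    t = math.radians(angle_deg)
    u = gx * math.cos(t) + gy * math.sin(t)
    v = -gx * math.sin(t) + gy * math.cos(t)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return np.column_stack([gx[inside], gy[inside]]).astype(np.int64)


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Brute-force connected-component labeling by BFS, raster-scan numbering."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    k = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                k += 1
                queue = deque([(r, c)])
                labels[r, c] = k
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = k
                            queue.append((nr, nc))
    return labels


def brute_force_small_component_filter(
    mask: np.ndarray, min_px: int, connectivity: int = 8
) -> np.ndarray:
    """Delete components below min_px using the BFS labeling oracle."""
    labels = flood_fill_components(mask, connectivity)
    out = np.zeros_like(mask, dtype=bool)
    for k in range(1, labels.max() + 1):
        comp = labels == k
        if comp.sum() >= min_px:
            out |= comp
    return out


def brute_force_hull_vertices(points: np.ndarray) -> set[tuple[float, float]]:
    """O(n³) hull oracle via the half-plane test over all point pairs.

    A directed pair (i, j) is a hull edge iff every other point lies strictly
    on its left; the hull vertex set is the set of edge endpoints.  Assumes
    general position (random continuous coordinates), where no three points
    are collinear.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    vertices: set[tuple[float, float]] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            others = np.delete(cross, [i, j])
            if (others > 0).all():
                vertices.add(tuple(pts[i]))
                vertices.add(tuple(pts[j]))
    return vertices


def fan_triangulation_area(vertices: np.ndarray) -> float:
    """Area of a convex polygon as the sum of fan triangles from vertex 0."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for i in range(1, len(v) - 1):
        ax, ay = v[i] - v[0]
        bx, by = v[i + 1] - v[0]
        total += 0.5 * abs(ax * by - ay * bx)
    return total


def bayes_boundary(w1, mu1, s1, w2, mu2, s2) -> float:
    """Equal-posterior boundary of a two-Gaussian mixture (between the means)."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    return brentq(
        lambda x: w1 * norm.pdf(x, mu1, s1) - w2 * norm.pdf(x, mu2, s2), mu1, mu2
    )


def mixture_error_at(threshold, w1, mu1, s1, w2, mu2, s2) -> float:
    """Misclassification probability of the rule 'class 1 iff value <= t'."""
    from scipy.stats import norm

    return w1 * norm.sf(threshold, mu1, s1) + w2 * norm.cdf(threshold, mu2, s2)


@pytest.fixture(scope="session")
def default_scene():
    """One rendered scene with its truth table, reused by read-only tests."""
    from inflorascan import generate_scene

    return generate_scene(seed=42)
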