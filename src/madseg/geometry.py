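"""Shared low-level geometry on polylines and rasters."""

from __future__ import annotations

import numpy as np


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polyline (no duplicated endpoint).

    Positive area corresponds to the package-wide CCW convention
    (coordinates as stored, x=col, y=row).
    """
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the polyline with positive signed area, reversing if needed."""
    return points if signed_area(points) > 0 else points[::-1].copy()


def arc_lengths(points: np.ndarray, closed: bool = True) -> np.ndarray:
    """Cumulative arc length at each vertex; includes the closing segment
    as a final extra entry when ``closed``."""
    p = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    if closed:
        seg = np.append(seg, np.linalg.norm(p[0] - p[-1]))
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_length(points: np.ndarray, closed: bool = True) -> float:
    return float(arc_lengths(points, closed)[-1])


def resample_closed(points: np.ndarray, spacing: float = 1.0,
                    n: int | None = None) -> np.ndarray:
    """Resample a closed polyline at (approximately) uniform arc spacing.

    Either a target ``spacing`` in pixels or an explicit point count ``n``
    may be given; the result never duplicates the start point.
    """
    p = np.asarray(points, dtype=float)
    s = arc_lengths(p, closed=True)
    total = s[-1]
    if n is None:
        n = max(8, int(round(total / spacing)))
    t = np.linspace(0.0, total, n, endpoint=False)
    ring = np.vstack([p, p[:1]])
    x = np.interp(t, s, ring[:, 0])
    y = np.interp(t, s, ring[:, 1])
    return np.column_stack([x, y])


def menger_curvature(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Unsigned curvature of the circle through three points.

    1/R of the circumscribed circle: kappa = 4 * Area / (|ab| |bc| |ca|).
    Collinear triples give 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
    if area2 == 0.0:
        return 0.0
    la = np.linalg.norm(b - a)
    lb = np.linalg.norm(c - b)
    lc = np.linalg.norm(a - c)
    denom = la * lb * lc
    if denom == 0.0:
        return 0.0
    return float(2.0 * area2 / denom)


def path_curvatures(path: np.ndarray) -> np.ndarray:
    """Menger curvature at each interior vertex of an open path."""
    p = np.asarray(path, dtype=float)
    if len(p) < 3:
        return np.zeros(0)
    a, b, c = p[:-2], p[1:-1], p[2:]
    cross = np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))
    la = np.linalg.norm(b - a, axis=1)
    lb = np.linalg.norm(c - b, axis=1)
    lc = np.linalg.norm(a - c, axis=1)
    denom = la * lb * lc
    out = np.zeros(len(cross))
    ok = denom > 0
    out[ok] = 2.0 * cross[ok] / denom[ok]
    return out


def rasterize_polyline(points: np.ndarray, shape: tuple[int, int],
                       closed: bool = True) -> np.ndarray:
    """Rasterize a polyline into a boolean 1-px-wide raster.

    Uses dense resampling at sub-pixel spacing, so adjacent pixels are
    8-connected along the curve.
    """
    dense = resample_closed(points, spacing=0.4) if closed else points
    grid = np.zeros(shape, dtype=bool)
    cols = np.clip(np.rint(dense[:, 0]).astype(int), 0, shape[1] - 1)
    rows = np.clip(np.rint(dense[:, 1]).astype(int), 0, shape[0] - 1)
    grid[rows, cols] = True
    return grid


def fill_contour(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the interior (plus boundary) of a closed contour."""
    from skimage.draw import polygon

    p = np.asarray(points, dtype=float)
    rr, cc = polygon(p[:, 1], p[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    mask |= rasterize_polyline(p, shape, closed=True)
    return mask


def polyline_is_simple(points: np.ndarray, closed: bool = True) -> bool:
    """True if the polyline has no self-intersection (shapely test)."""
    import shapely.geometry as sg

    p = np.asarray(points, dtype=float)
    if closed:
        ring = sg.LinearRing(np.vstack([p, p[:1]]))
        return bool(ring.is_simple and ring.is_valid)
    return bool(sg.LineString(p).is_simple)


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def rotate(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])
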