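"""Offset trajectories around the attention-mask contour.

The mask contour is displaced along its normals by signed multiples of a
spacing; displacement can create local self-intersection loops at
concavities, which are trimmed and the curve rejoined (delegated to
polygon buffering with round joins, which performs exactly this
trim-and-join on the polyline level). Each surviving offset is refit
with a periodic cubic spline and exposes fast nearest-point/tangent
lookups, which the agents use as their guidance field.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import interpolate
from scipy.spatial import cKDTree

from . import geometry

log = logging.getLogger(__name__)

DEFAULT_N_LEVELS = 3
DEFAULT_SPACING = 6.0
_N_SAMPLES = 512


def _fit_periodic_spline(points: np.ndarray, smooth: float = 0.0):
    """Periodic cubic spline through a closed polyline; returns tck."""
    p = np.asarray(points, dtype=float)
    ring = np.vstack([p, p[:1]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tck, _ = interpolate.splprep([ring[:, 0], ring[:, 1]], per=1,
                                     s=smooth, k=3)
    return tck


@dataclass
class OffsetTrajectory:
    """One closed offset curve at a signed distance from the contour."""

    tck: object                      # periodic cubic spline parameters
    points: np.ndarray               # dense CCW samples (n, 2)
    level: float                     # signed offset distance, + outward
    orientation: str = "CCW"         # stored orientation of ``points``

    @property
    def arc_length(self) -> float:
        return geometry.polyline_length(self.points, closed=True)

    def tangents(self) -> np.ndarray:
        """Unit tangents at the dense samples, in stored orientation."""
        u = np.linspace(0.0, 1.0, len(self.points), endpoint=False)
        dx, dy = interpolate.splev(u, self.tck, der=1)
        t = np.column_stack([dx, dy])
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return t / norms


@dataclass
class OffsetField:
    """Family of nested offset trajectories plus nearest-point index."""

    trajectories: list[OffsetTrajectory]
    spacing: float
    n_levels: int
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _flat_tangents: np.ndarray | None = field(default=None, repr=False,
                                              compare=False)
    _owner: np.ndarray | None = field(default=None, repr=False, compare=False)

    def _index(self):
        if self._tree is None:
            pts = np.vstack([t.points for t in self.trajectories])
            tans = np.vstack([t.tangents() for t in self.trajectories])
            owner = np.concatenate([
                np.full(len(t.points), i)
                for i, t in enumerate(self.trajectories)])
            self._tree = cKDTree(pts)
            self._flat_tangents = tans
            self._owner = owner
        return self._tree

    def nearest(self, position) -> tuple[int, np.ndarray, np.ndarray]:
        """(trajectory index, nearest point, unit tangent in CCW sense)."""
        tree = self._index()
        _, idx = tree.query(np.asarray(position, float), k=1)
        return (int(self._owner[idx]), tree.data[idx].copy(),
                self._flat_tangents[idx].copy())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spacing": self.spacing,
            "n_levels": self.n_levels,
            "trajectories": [
                {"level": t.level, "orientation": t.orientation,
                 "control_points": t.points.tolist()}
                for t in self.trajectories],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "OffsetField":
        with open(path) as fh:
            payload = json.load(fh)
        trajs = []
        for item in payload["trajectories"]:
            pts = np.asarray(item["control_points"], dtype=float)
            trajs.append(OffsetTrajectory(
                tck=_fit_periodic_spline(pts), points=pts,
                level=item["level"], orientation=item["orientation"]))
        return cls(trajs, payload["spacing"], payload["n_levels"])


def extract_contour(mask: np.ndarray, smooth: float | None = None
                    ) -> np.ndarray:
    """Ordered closed CCW boundary polyline of a single-component mask,
    with sub-pixel smoothing by a periodic spline fit."""
    from skimage import measure

    m = np.asarray(mask, bool)
    labels = measure.label(m)
    if labels.max() != 1:
        raise ValueError(f"mask must have exactly one component, "
                         f"found {labels.max()}")
    contours = measure.find_contours(m.astype(float), 0.5)
    contour = max(contours, key=len)          # (row, col)
    pts = contour[:-1, ::-1].copy()           # -> (x, y), drop repeat
    if smooth is None:
        smooth = 0.5 * len(pts)
    tck = _fit_periodic_spline(pts, smooth=smooth)
    u = np.linspace(0.0, 1.0, max(256, len(pts)), endpoint=False)
    x, y = interpolate.splev(u, tck)
    return geometry.ensure_ccw(np.column_stack([x, y]))


def _offset_ring(contour: np.ndarray, dist: float) -> np.ndarray | None:
    """Trimmed offset polyline at signed distance (+ outward) or None on
    annihilation (inward offset exceeding the inradius)."""
    import shapely.geometry as sg

    poly = sg.Polygon(np.vstack([contour, contour[:1]]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    if dist == 0.0:
        return contour.copy()
    out = poly.buffer(dist, quad_segs=16, join_style="round")
    if out.is_empty:
        return None
    if out.geom_type == "MultiPolygon":
        out = max(out.geoms, key=lambda g: g.area)
    ring = np.asarray(out.exterior.coords)[:-1]
    if len(ring) < 8:
        return None
    return geometry.ensure_ccw(ring)


def generate_offsets(contour: np.ndarray,
                     n_levels: int = DEFAULT_N_LEVELS,
                     spacing: float = DEFAULT_SPACING) -> OffsetField:
    """Build the offset family around a simple closed contour.

    Levels are taken as 0, +1, -1, +2, -2, ... (times ``spacing``) up to
    ``n_levels`` curves; inward levels that annihilate are dropped with a
    warning.
    """
    if spacing < 1.0:
        raise ValueError("spacing must be >= 1 px")
    contour = geometry.ensure_ccw(np.asarray(contour, dtype=float))
    level_seq = [0]
    step = 1
    while len(level_seq) < n_levels:
        level_seq.extend([step, -step])
        step += 1
    level_seq = level_seq[:n_levels]

    trajectories = []
    for lvl in level_seq:
        dist = lvl * spacing
        ring = _offset_ring(contour, dist)
        if ring is None:
            log.warning("offset level %+d annihilated (distance %.1f px), "
                        "dropped", lvl, dist)
            continue
        dense = geometry.resample_closed(ring, n=_N_SAMPLES)
        tck = _fit_periodic_spline(dense, smooth=len(dense) * 0.05)
        u = np.linspace(0.0, 1.0, _N_SAMPLES, endpoint=False)
        x, y = interpolate.splev(u, tck)
        pts = np.column_stack([x, y])
        trajectories.append(OffsetTrajectory(tck=tck, points=pts,
                                             level=float(dist)))
    return OffsetField(trajectories=trajectories, spacing=float(spacing),
                       n_levels=n_levels)


def tangent_at_nearest(field: OffsetField, position, sense: str = "CCW"
                       ) -> np.ndarray:
    """Unit tangent of the nearest offset point, oriented for the
    querying agent's traversal sense."""
    if not field.trajectories:
        raise ValueError("empty offset field")
    _, _, tangent = field.nearest(position)
    if sense == "CW":
        tangent = -tangent
    return geometry.unit(tangent)
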