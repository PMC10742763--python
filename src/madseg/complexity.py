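"""S|Cmax|C edge-map complexity taxonomy.

Edge maps are scored by three statistics: the fraction of the boundary
length missing from the edge map (total-gap fraction ``L_g``), the
fraction covered by the single largest gap (``L_g_max``), and a shape
complexity score (one minus the ratio of the lesion area to the area of
its minimum enclosing circle). Each statistic is binarized against a
corpus-relative threshold (mean plus one standard deviation); a statistic
strictly below its threshold is Baseline (B), otherwise Tough (T). The
three letters are assembled as shape | max-gap | total-gap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import geometry

#: coverage tolerance (px): a contour sample is covered when an edge
#: pixel lies within this distance (1-px edges plus rasterization jitter).
DEFAULT_COVERAGE_TOL = 2.0


@dataclass(frozen=True)
class ComplexityLabel:
    L_g: float
    L_g_max: float
    S_score: float
    codes: tuple[str, str, str]      # (S, C_max, C), each "B" or "T"

    @property
    def code_string(self) -> str:
        return "|".join(self.codes)


@dataclass(frozen=True)
class ThresholdSet:
    """mean + std thresholds per statistic over a reference corpus."""

    L_prime: float          # total-gap threshold
    S_max_prime: float      # max-gap threshold
    S_prime: float          # shape-score threshold
    corpus_stats: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def gap_statistics(edge_map: np.ndarray, gt_contour: np.ndarray,
                   tol: float = DEFAULT_COVERAGE_TOL
                   ) -> tuple[float, float]:
    """Total and maximum gap fractions of a contour against an edge map.

    The contour is sampled at fine arc spacing; a sample is covered when
    an edge pixel lies within ``tol``; gaps are maximal uncovered runs
    (circular). Returns ``(L_g, L_g_max)`` as fractions of the contour
    length.
    """
    contour = np.asarray(gt_contour, dtype=float)
    if len(contour) < 3:
        raise ValueError("gt_contour must be a closed polyline")
    samples = geometry.resample_closed(contour, spacing=0.25)
    n = len(samples)
    edge_rc = np.argwhere(edge_map)
    if len(edge_rc) == 0:
        return 1.0, 1.0
    tree = cKDTree(edge_rc[:, ::-1].astype(float))  # (x, y)
    d, _ = tree.query(samples, k=1)
    covered = d <= tol
    if covered.all():
        return 0.0, 0.0
    if not covered.any():
        return 1.0, 1.0
    # circular runs of uncovered samples
    u = ~covered
    # rotate so position 0 is covered, then runs never wrap
    start = int(np.argmax(covered))
    u = np.roll(u, -start)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], u.view(np.int8), [0]])))
    runs = edges[1::2] - edges[0::2]
    frac = runs / n
    return float(frac.sum()), float(frac.max())


# ----------------------------------------------------------------------
# minimum enclosing circle (Welzl's randomized incremental algorithm)

def _circle_two(a, b):
    c = (a + b) / 2.0
    return c[0], c[1], float(np.linalg.norm(a - b) / 2.0)


def _circle_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    center = np.array([ux, uy])
    return ux, uy, float(np.linalg.norm(a - center))


def _in_circle(circle, p, eps=1e-7) -> bool:
    cx, cy, r = circle
    return (p[0] - cx) ** 2 + (p[1] - cy) ** 2 <= (r + eps) ** 2


def min_enclosing_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Exact minimum enclosing circle ``(cx, cy, r)`` of a point set."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if len(pts) == 1:
        return float(pts[0, 0]), float(pts[0, 1]), 0.0
    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]
    c = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if _in_circle(c, pts[i]):
            continue
        # pts[i] on the boundary
        c = _circle_two(pts[0], pts[i])
        for j in range(1, i):
            if _in_circle(c, pts[j]):
                continue
            c = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(c, pts[k]):
                    continue
                c3 = _circle_three(pts[i], pts[j], pts[k])
                if c3 is not None:
                    c = c3
    return c


def shape_score(gt_mask: np.ndarray) -> float:
    """Shape complexity: 1 - area(mask) / area(min enclosing circle).

    Near 0 for a disk, toward 1 for elongated or spiculated shapes; the
    enclosing-circle normalization makes the score scale invariant.
    """
    mask = np.asarray(gt_mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    rc = np.argwhere(mask)
    # pixel centers suffice: convex-hull extremes drive the circle
    from scipy.spatial import ConvexHull

    pts = rc[:, ::-1].astype(float)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    _, _, r = min_enclosing_circle(pts)
    if r <= 0:
        return 0.0
    return float(max(0.0, 1.0 - area / (np.pi * r * r)))


def fit_thresholds(labels) -> ThresholdSet:
    """Fit mean + population-std thresholds from corpus statistics.

    ``labels`` is an iterable of objects with ``L_g``, ``L_g_max`` and
    ``S_score`` attributes (or 3-tuples in that order).
    """
    rows = []
    for item in labels:
        if hasattr(item, "L_g"):
            rows.append((item.L_g, item.L_g_max, item.S_score))
        else:
            rows.append(tuple(item))
    arr = np.asarray(rows, dtype=float)
    if len(arr) < 10:
        raise ValueError("need at least 10 corpus items to fit thresholds")
    thresholds = []
    for col in range(3):
        v = arr[:, col]
        std = float(v.std())        # population std
        if std < 1e-12:
            warnings.warn("degenerate corpus statistic: zero variance; "
                          "threshold equals the mean", stacklevel=2)
            std = 0.0
        thresholds.append(float(v.mean()) + std)
    lg_t, max_t, s_t = thresholds
    stats = {
        "n": int(len(arr)),
        "L_g_mean": float(arr[:, 0].mean()), "L_g_std": float(arr[:, 0].std()),
        "L_g_max_mean": float(arr[:, 1].mean()),
        "L_g_max_std": float(arr[:, 1].std()),
        "S_mean": float(arr[:, 2].mean()), "S_std": float(arr[:, 2].std()),
    }
    return ThresholdSet(L_prime=lg_t, S_max_prime=max_t, S_prime=s_t,
                        corpus_stats=stats)


def categorize(L_g: float, L_g_max: float, S_score: float,
               thresholds: ThresholdSet) -> ComplexityLabel:
    """Assemble the S|Cmax|C label (B strictly below threshold, else T)."""
    s = "B" if S_score < thresholds.S_prime else "T"
    cmax = "B" if L_g_max < thresholds.S_max_prime else "T"
    c = "B" if L_g < thresholds.L_prime else "T"
    return ComplexityLabel(L_g=float(L_g), L_g_max=float(L_g_max),
                           S_score=float(S_score), codes=(s, cmax, c))


def label_phantom(phantom, thresholds: ThresholdSet,
                  tol: float = DEFAULT_COVERAGE_TOL) -> ComplexityLabel:
    """Measure a phantom's statistics and categorize them."""
    lg, lgm = gap_statistics(phantom.edge_map, phantom.gt_contour, tol=tol)
    s = shape_score(phantom.gt_mask)
    return categorize(lg, lgm, s, thresholds)
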