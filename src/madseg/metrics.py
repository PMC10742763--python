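"""Contour and area segmentation-quality metrics.

Contour metrics: the Hausdorff distance (max of the two directed
max-min distances), the average Hausdorff distance (max of the two
directed mean-min distances, normalized by the contour lengths), and the
relative Hausdorff distance H3 = H2 / L_X * 100% which normalizes by the
ground-truth contour length and is therefore comparable across lesion
sizes. A segmentation is successful when H3 <= 2%; corpus-level results
report the success ratio (SGratio) and aggregate the area metrics over
the successful subset only.

Contours are resampled to unit arc-length spacing before evaluation so
the point count equals the contour length and the 1/L normalization of
the average Hausdorff distance is well posed independent of the input
sampling density. X always denotes the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from . import geometry

SUCCESS_H3_PERCENT = 2.0


@dataclass
class MetricsReport:
    distH1: float
    distH2: float
    distH3: float               # percent
    L_X: float
    L_Y: float
    TP: int
    FP: int
    TN: int
    FN: int
    Rec: Optional[float]
    Pre: Optional[float]
    Acc: Optional[float]
    Jac: Optional[float]
    Dice: Optional[float]
    success: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _directed_mins(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(x, y)
    return d.min(axis=1), d.min(axis=0)


def hausdorff(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty point set")
    dxy, dyx = _directed_mins(x, y)
    return float(max(dxy.max(), dyx.max()))


def avg_hausdorff(x: np.ndarray, y: np.ndarray,
                  l_x: float | None = None, l_y: float | None = None) -> float:
    """Average Hausdorff distance with 1/L_X, 1/L_Y normalizations.

    ``l_x``/``l_y`` default to the point counts, which equal the contour
    lengths when the contours are resampled at unit spacing.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty point set")
    l_x = float(len(x)) if l_x is None else float(l_x)
    l_y = float(len(y)) if l_y is None else float(l_y)
    if l_x <= 0 or l_y <= 0:
        raise ValueError("contour lengths must be positive")
    dxy, dyx = _directed_mins(x, y)
    return float(max(dxy.sum() / l_x, dyx.sum() / l_y))


def relative_hausdorff(dist_h2: float, l_x: float) -> float:
    """H3 = H2 / L_X * 100, in percent of the ground-truth length."""
    if l_x <= 0:
        raise ValueError("L_X must be positive")
    return float(dist_h2 / l_x * 100.0)


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray
              ) -> tuple[int, int, int, int]:
    """Pixelwise (TP, FP, TN, FN) of a predicted vs ground-truth mask."""
    p = np.asarray(pred_mask, bool)
    g = np.asarray(gt_mask, bool)
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    tn = int(np.sum(~p & ~g))
    fn = int(np.sum(~p & g))
    return tp, fp, tn, fn


def area_metrics(counts: tuple[int, int, int, int]
                 ) -> tuple[Optional[float], ...]:
    """(Rec, Pre, Acc, Jac, Dice) in percent; undefined metrics are None
    rather than 0 so corpus averages are not silently deflated."""
    tp, fp, tn, fn = counts

    def pct(num, den):
        return float(num / den * 100.0) if den > 0 else None

    rec = pct(tp, tp + fn)
    pre = pct(tp, tp + fp)
    acc = pct(tp + tn, tp + tn + fp + fn)
    jac = pct(tp, tp + fp + fn)
    dice = pct(2 * tp, 2 * tp + fp + fn)
    return rec, pre, acc, jac, dice


def evaluate_contours(gt_contour: np.ndarray, pred_contour: np.ndarray,
                      gt_mask: np.ndarray, pred_mask: np.ndarray
                      ) -> MetricsReport:
    """Full report for one segmentation; X is the ground truth."""
    x = geometry.resample_closed(np.asarray(gt_contour, float), spacing=1.0)
    y = geometry.resample_closed(np.asarray(pred_contour, float), spacing=1.0)
    h1 = hausdorff(x, y)
    h2 = avg_hausdorff(x, y)           # L = point count = length
    h3 = relative_hausdorff(h2, len(x))
    counts = confusion(pred_mask, gt_mask)
    rec, pre, acc, jac, dice = area_metrics(counts)
    return MetricsReport(
        distH1=h1, distH2=h2, distH3=h3,
        L_X=float(len(x)), L_Y=float(len(y)),
        TP=counts[0], FP=counts[1], TN=counts[2], FN=counts[3],
        Rec=rec, Pre=pre, Acc=acc, Jac=jac, Dice=dice,
        success=h3 <= SUCCESS_H3_PERCENT,
    )


def sg_ratio(reports) -> tuple[float, list[MetricsReport]]:
    """Success percentage over a corpus and the successful subset.

    Aggregate quality statistics should be computed over the returned
    subset only; the failures are counted by the ratio itself.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports")
    good = [r for r in reports if r.success]
    return 100.0 * len(good) / len(reports), good


def summarize(reports) -> dict:
    """Corpus summary: SGratio plus mean/std of each metric over the
    successful subset (None-valued metrics are skipped)."""
    reports = list(reports)
    ratio, good = sg_ratio(reports)
    out = {"SGratio": ratio, "n": len(reports), "n_success": len(good)}
    for name in ("distH1", "distH2", "distH3", "Rec", "Pre", "Acc",
                 "Jac", "Dice"):
        vals = [getattr(r, name) for r in good
                if getattr(r, name) is not None]
        if vals:
            out[f"{name}_mean"] = float(np.mean(vals))
            out[f"{name}_std"] = float(np.std(vals))
    return out
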