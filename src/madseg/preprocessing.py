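"""Attention mask and edge map: the agents' world.

The lesion boundary occupies only a few percent of an edge map, so the
search space is first reduced by a coarse binary attention mask:
histogram equalization, a superpixel decomposition, and a simplified
neutrosophic membership scheme that keeps superpixels confidently
belonging to the dark (hypoechoic) class. Edges come either from a
synthetic phantom's known edge map or from a Canny-style detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class NoCandidateLesionError(RuntimeError):
    """Raised when the attention stage finds no plausible lesion region."""


@dataclass
class AttentionMask:
    mask: np.ndarray          # bool (H, W)
    contour: np.ndarray       # closed CCW polyline (x, y)


@dataclass
class EdgeMap:
    edges: np.ndarray         # bool (H, W)
    source: str               # "synthetic" or "detected"

    @property
    def edge_fraction(self) -> float:
        return float(self.edges.mean())


def equalize(image: np.ndarray) -> np.ndarray:
    """Cumulative-histogram equalization of an 8-bit grayscale image.

    A constant image is returned unchanged (its CDF is degenerate).
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("expected an 8-bit grayscale image")
    if img.min() == img.max():
        return img.copy()
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist).astype(float)
    lut = np.rint(cdf / cdf[-1] * 255.0)
    return lut.astype(np.uint8)[img]


def superpixels(image: np.ndarray, n_segments: int = 300,
                compactness: float = 10.0) -> np.ndarray:
    """SLIC-style superpixel labels (k-means in intensity-position space).

    Labels are contiguous integers starting at 0; every pixel is labeled.
    """
    from skimage.segmentation import slic

    img = np.asarray(image)
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n_segments > img.size:
        raise ValueError("more segments than pixels")
    labels = slic(img.astype(float) / 255.0, n_segments=n_segments,
                  compactness=compactness, channel_axis=None,
                  start_label=0, enforce_connectivity=True)
    if len(np.unique(labels)) < min(n_segments, 2):
        # grid-seeded SLIC degenerates for very small segment counts;
        # fall back to plain k-means on (intensity, x, y)
        from scipy.cluster.vq import kmeans2

        h, w = img.shape
        yy, xx = np.mgrid[:h, :w]
        s = np.sqrt(img.size / n_segments)
        spatial_w = compactness / s
        feats = np.column_stack([
            img.ravel().astype(float) / 255.0,
            spatial_w * xx.ravel(), spatial_w * yy.ravel()])
        _, labels = kmeans2(feats, n_segments, minit="++", seed=0)
        labels = labels.reshape(img.shape)
    # compact the label range (ids may be skipped)
    _, labels = np.unique(labels, return_inverse=True)
    return labels.reshape(img.shape)


def neutrosophic_binarize(image: np.ndarray, labels: np.ndarray,
                          polarity: str = "dark") -> AttentionMask:
    """Attention mask from per-superpixel truth/indeterminacy/falsity.

    Truth is the normalized proximity of a superpixel's mean intensity to
    the dark-class centroid of a 2-means split; indeterminacy is the
    normalized local intensity spread. A superpixel joins the mask when
    truth dominates falsity and indeterminacy is below 1/2; the largest
    connected component is kept and holes are filled.

    ``polarity="bright"`` searches for a bright lesion instead.
    """
    from .offsets import extract_contour

    img = np.asarray(image, dtype=float)
    if polarity == "bright":
        img = 255.0 - img
    elif polarity != "dark":
        raise ValueError("polarity must be 'dark' or 'bright'")

    n = int(labels.max()) + 1
    sums = np.bincount(labels.ravel(), weights=img.ravel(), minlength=n)
    counts = np.bincount(labels.ravel(), minlength=n)
    means = sums / np.maximum(counts, 1)
    sq = np.bincount(labels.ravel(), weights=img.ravel() ** 2, minlength=n)
    stds = np.sqrt(np.maximum(sq / np.maximum(counts, 1) - means ** 2, 0.0))

    # 2-means on superpixel mean intensities (1-D Lloyd iteration)
    c_dark, c_bright = means.min(), means.max()
    for _ in range(50):
        assign = np.abs(means - c_dark) <= np.abs(means - c_bright)
        new_dark = means[assign].mean() if assign.any() else c_dark
        new_bright = means[~assign].mean() if (~assign).any() else c_bright
        if np.isclose(new_dark, c_dark) and np.isclose(new_bright, c_bright):
            break
        c_dark, c_bright = new_dark, new_bright
    if c_bright - c_dark < 1e-9:
        raise NoCandidateLesionError("image has no intensity contrast")

    truth = np.clip((c_bright - means) / (c_bright - c_dark), 0.0, 1.0)
    falsity = 1.0 - truth
    indet = stds / max(stds.max(), 1e-9)
    member = (truth > falsity) & (indet < 0.5)
    if not member.any():
        raise NoCandidateLesionError("no superpixel joins the dark class")

    mask = member[labels]
    lab, n_comp = ndimage.label(mask)
    if n_comp == 0:
        raise NoCandidateLesionError("empty candidate mask")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n_comp + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    contour = extract_contour(mask)
    return AttentionMask(mask=mask, contour=contour)


def detect_edges(image: np.ndarray, low: float = 0.1, high: float = 0.2
                 ) -> EdgeMap:
    """Gradient-magnitude edge detection with hysteresis (Canny-style).

    ``low``/``high`` are fractions of the maximum gradient magnitude.
    """
    from skimage.feature import canny

    if low >= high:
        raise ValueError("low threshold must be below high")
    img = np.asarray(image, dtype=float) / 255.0
    edges = canny(img, sigma=1.5, low_threshold=low, high_threshold=high,
                  use_quantiles=False)
    return EdgeMap(edges=edges, source="detected")


def attention_pipeline(image: np.ndarray, n_segments: int = 300,
                       compactness: float = 10.0, polarity: str = "dark"
                       ) -> AttentionMask:
    """equalize -> superpixels -> neutrosophic binarization."""
    eq = equalize(image)
    labels = superpixels(eq, n_segments=n_segments, compactness=compactness)
    return neutrosophic_binarize(eq, labels, polarity=polarity)
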