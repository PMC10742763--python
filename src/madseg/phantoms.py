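"""Synthetic ultrasound-like phantoms with known ground truth.

A phantom is a grayscale image of a dark (hypoechoic) lesion on a brighter
background, its exact closed boundary, the filled ground-truth mask, and a
binary edge map derived from the boundary raster with a controlled gap
structure (total gap fraction, single largest gap), distractor false-edge
arcs and speckle-like multiplicative noise.

The boundary is a star-shaped radial curve
``r(phi) = R * (1 + sum_j a_j sin(k_j phi + phi_j))``
which is guaranteed simple whenever ``r > 0`` everywhere; lobe count and
amplitude act directly as the shape-complexity knob, and gaps are placed
as exact arc-length intervals so the realized gap fractions are known to
sub-pixel precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import geometry

#: extra arc length carved beyond each gap end so that coverage-based gap
#: measurement with a 2 px tolerance reproduces the nominal gap length
#: (tolerance minus half the boundary-pixel spacing along the curve).
GAP_MEASURE_PAD = 1.6

#: minimum arc-length separation between carved gaps so measured gaps
#: never merge.
MIN_GAP_SEPARATION = 5.0

SHAPE_MODES = ("simple_blob", "lobulated", "spiculated")

#: the eight complexity codes S|Cmax|C, easiest first (number of tough
#: letters, then tough letters in later slots first).
CATEGORY_ORDER = (
    "B|B|B", "B|B|T", "B|T|B", "T|B|B",
    "B|T|T", "T|B|T", "T|T|B", "T|T|T",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters of one phantom."""

    image_size: int = 128
    shape_mode: str = "simple_blob"
    n_lobes: int = 0
    lobe_amplitude: float = 0.0
    gap_total_frac: float = 0.0
    gap_max_frac: float = 0.0
    n_false_edges: int = 0
    noise_sigma: float = 0.0
    seed: int = 0
    radius_frac: float = 0.32
    tumor_intensity: float = 60.0
    background_intensity: float = 150.0

    def validate(self) -> None:
        if not (0.0 <= self.gap_total_frac < 1.0):
            raise ValueError("gap_total_frac must lie in [0, 1)")
        if not (0.0 <= self.gap_max_frac < 1.0):
            raise ValueError("gap_max_frac must lie in [0, 1)")
        if self.gap_max_frac > self.gap_total_frac:
            raise ValueError("gap_max_frac must not exceed gap_total_frac")
        if self.gap_total_frac > 0 and self.gap_max_frac <= 0:
            raise ValueError("gap_max_frac must be positive when gaps exist")
        if self.shape_mode not in SHAPE_MODES:
            raise ValueError(f"unknown shape_mode {self.shape_mode!r}")
        if self.image_size < 32:
            raise ValueError("image_size too small")


@dataclass
class Phantom:
    """A rendered phantom with ground truth and realized statistics."""

    image: np.ndarray            # uint8 (H, W)
    edge_map: np.ndarray         # bool (H, W)
    gt_contour: np.ndarray       # float (N, 2), (x, y), closed, CCW
    gt_mask: np.ndarray          # bool (H, W)
    realized_gap_total_frac: float
    realized_gap_max_frac: float
    realized_shape_score: float
    spec: PhantomSpec

    def save(self, directory: str | Path, stem: str) -> dict[str, str]:
        """Write image/mask PNGs and the contour JSON; return file paths."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, arr in (("image", self.image),
                          ("mask", self.gt_mask.astype(np.uint8) * 255),
                          ("edges", self.edge_map.astype(np.uint8) * 255)):
            p = directory / f"{stem}_{name}.png"
            Image.fromarray(np.asarray(arr, dtype=np.uint8), mode="L").save(p)
            paths[name] = str(p)
        p = directory / f"{stem}_contour.json"
        with open(p, "w") as fh:
            json.dump({"points": self.gt_contour.tolist(), "closed": True}, fh)
        paths["contour"] = str(p)
        return paths


def _harmonics(spec: PhantomSpec, rng: np.random.Generator):
    """Radial harmonic terms (amplitude, frequency, phase) per shape mode."""
    a = spec.lobe_amplitude
    if spec.shape_mode == "simple_blob":
        k = max(spec.n_lobes, 3)
        return [(a, k, rng.uniform(0, 2 * np.pi))]
    # the second harmonic's phase is locked to the first so lobe peaks
    # coincide; the profile maximum (hence the enclosing circle) then
    # depends only on the amplitude, not on the random rotation
    if spec.shape_mode == "lobulated":
        k = max(spec.n_lobes, 4)
        p0 = rng.uniform(0, 2 * np.pi)
        return [(a, k, p0), (0.25 * a, 2 * k, 2 * p0 - np.pi / 2)]
    k = max(spec.n_lobes, 8)
    p0 = rng.uniform(0, 2 * np.pi)
    return [(a, k, p0), (0.35 * a, 2 * k, 2 * p0 - np.pi / 2)]


def _radial_profile(harmonics, phi: np.ndarray) -> np.ndarray:
    r = np.ones_like(phi)
    for a, k, p0 in harmonics:
        r = r + a * np.sin(k * phi + p0)
    return r


def boundary_curve(spec: PhantomSpec, n_samples: int = 2048) -> np.ndarray:
    """Dense closed boundary polyline (CCW, (x, y)) for a spec.

    Raises ``ValueError`` when the radial function is not strictly
    positive (the curve would self-intersect or collapse).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    harmonics = _harmonics(spec, rng)
    phi = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    prof = _radial_profile(harmonics, phi)
    if np.any(prof <= 0.05):
        raise ValueError("radial profile nonpositive: boundary not simple")
    radius = spec.radius_frac * spec.image_size
    c = (spec.image_size - 1) / 2.0
    x = c + radius * prof * np.cos(phi)
    y = c + radius * prof * np.sin(phi)
    pts = np.column_stack([x, y])
    margin = 2.0
    if pts.min() < margin or pts.max() > spec.image_size - 1 - margin:
        raise ValueError("boundary does not fit inside the image")
    return geometry.ensure_ccw(pts)


def _plan_gaps(rng: np.random.Generator, total_len: float,
               total_frac: float, max_frac: float) -> list[tuple[float, float]]:
    """Plan gap arc intervals [(start, length), ...] in arc-length units.

    The largest gap is placed with exactly ``max_frac * total_len``;
    secondary gaps are strictly smaller so the realized maximum is the
    requested one. Start positions keep every pair of gaps separated.
    """
    if total_frac <= 0:
        return []
    last_error = None
    for attempt in range(6):
        min_sep = max(3.0, MIN_GAP_SEPARATION - attempt)
        lengths = [max_frac * total_len]
        remaining = (total_frac - max_frac) * total_len
        cap = max(3.0, 0.95 * max_frac * total_len)
        while remaining > 1.0:
            if remaining <= cap:
                g = remaining
            else:
                g = cap * rng.uniform(0.85, 0.95)
                if remaining - g < 3.0:
                    g = remaining / 2.0
            g = max(g, 1.0)
            lengths.append(g)
            remaining -= g
        n = len(lengths)
        occupied = sum(lengths) + n * 2 * GAP_MEASURE_PAD
        free = total_len - occupied
        if free < n * min_sep:
            last_error = ValueError(
                "gap fractions too large for this contour length")
            continue
        seps = min_sep + rng.dirichlet(np.ones(n)) * (free - n * min_sep)
        order = rng.permutation(n)
        s = rng.uniform(0.0, total_len)
        intervals = []
        for j in range(n):
            s += seps[j]
            length = lengths[order[j]]
            intervals.append((s % total_len, length))
            s += length + 2 * GAP_MEASURE_PAD
        return intervals
    raise last_error


def _carve_gaps(edge_map: np.ndarray, pixel_params: np.ndarray,
                pixel_rc: np.ndarray, intervals, total_len: float) -> None:
    """Remove boundary pixels whose arc parameter falls inside a gap
    interval extended by the measurement pad at both ends."""
    for start, length in intervals:
        lo = (start - GAP_MEASURE_PAD) % total_len
        hi = (start + length + GAP_MEASURE_PAD) % total_len
        p = pixel_params
        inside = (p >= lo) & (p < hi) if lo < hi else (p >= lo) | (p < hi)
        rc = pixel_rc[inside]
        edge_map[rc[:, 0], rc[:, 1]] = False


def _false_edge_arcs(rng: np.random.Generator, spec: PhantomSpec,
                     boundary_raster: np.ndarray) -> np.ndarray:
    """Distractor arcs inside/outside the lesion, kept off the boundary."""
    from scipy.ndimage import distance_transform_edt

    shape = boundary_raster.shape
    clearance = distance_transform_edt(~boundary_raster)
    out = np.zeros(shape, dtype=bool)
    c = (spec.image_size - 1) / 2.0
    base_r = spec.radius_frac * spec.image_size
    for _ in range(spec.n_false_edges):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.3, 1.35) * base_r
        cx, cy = c + dist * np.cos(ang), c + dist * np.sin(ang)
        rho = rng.uniform(0.15, 0.5) * base_r
        span = np.deg2rad(rng.uniform(60, 150))
        a0 = rng.uniform(0, 2 * np.pi)
        t = np.arange(0.0, span, 0.35 / max(rho, 1.0))
        xs = cx + rho * np.cos(a0 + t)
        ys = cy + rho * np.sin(a0 + t)
        cols = np.rint(xs).astype(int)
        rows = np.rint(ys).astype(int)
        ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
        rows, cols = rows[ok], cols[ok]
        keep = clearance[rows, cols] > 4.0
        out[rows[keep], cols[keep]] = True
    return out


def _render_image(spec: PhantomSpec, gt_mask: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    img = np.full(gt_mask.shape, spec.background_intensity, dtype=float)
    img[gt_mask] = spec.tumor_intensity
    img = gaussian_filter(img, sigma=2.0)
    if spec.noise_sigma > 0:
        sig = spec.noise_sigma
        speckle = rng.lognormal(mean=-0.5 * sig * sig, sigma=sig,
                                size=img.shape)
        img = gaussian_filter(img * speckle, sigma=1.0)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom deterministically from its spec."""
    contour = boundary_curve(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 917]))
    shape = (spec.image_size, spec.image_size)

    # boundary raster with an arc-length parameter per pixel (first hit)
    dense = geometry.resample_closed(contour, spacing=0.4)
    params = geometry.arc_lengths(dense, closed=True)[:-1]
    total_len = geometry.polyline_length(contour, closed=True)
    cols = np.clip(np.rint(dense[:, 0]).astype(int), 0, shape[1] - 1)
    rows = np.clip(np.rint(dense[:, 1]).astype(int), 0, shape[0] - 1)
    flat = rows * shape[1] + cols
    _, first = np.unique(flat, return_index=True)
    pixel_rc = np.column_stack([rows[first], cols[first]])
    pixel_params = params[first]
    boundary_raster = np.zeros(shape, dtype=bool)
    boundary_raster[pixel_rc[:, 0], pixel_rc[:, 1]] = True

    edge_map = boundary_raster.copy()
    intervals = _plan_gaps(rng, total_len, spec.gap_total_frac,
                           spec.gap_max_frac)
    if intervals:
        _carve_gaps(edge_map, pixel_params, pixel_rc, intervals, total_len)
    realized_total = sum(length for _, length in intervals) / total_len
    realized_max = (max(length for _, length in intervals) / total_len
                    if intervals else 0.0)

    if spec.n_false_edges > 0:
        edge_map |= _false_edge_arcs(rng, spec, boundary_raster)

    gt_mask = geometry.fill_contour(contour, shape)
    image = _render_image(spec, gt_mask, rng)

    from .complexity import shape_score
    return Phantom(
        image=image,
        edge_map=edge_map,
        gt_contour=contour,
        gt_mask=gt_mask,
        realized_gap_total_frac=float(realized_total),
        realized_gap_max_frac=float(realized_max),
        realized_shape_score=float(shape_score(gt_mask)),
        spec=spec,
    )


# ----------------------------------------------------------------------
# corpus construction

# Prescribed per-letter statistic values. Tough letters get a tight high
# band plus exactly one borderline specimen per category (phantom index
# 0), which the mean+std taxonomy deliberately classifies as baseline:
# with a balanced corpus the fitted threshold always sits above the mean
# of the tough group, so a tough group with no low tail cannot be
# recovered; the borderline specimens supply that tail while bounding the
# designed misclassification to one phantom per tough letter category.
_SHAPE_B = (0.10, 0.20)
_SHAPE_T_BULK = (0.545, 0.555)
_SHAPE_T_BORDER = 0.25
_MAX_B = (0.030, 0.045)
_MAX_T_BULK = (0.198, 0.202)
_MAX_T_BORDER = 0.06
_TOTAL_B_WHEN_MAX_B = (0.14, 0.16)
_TOTAL_B_WHEN_MAX_T = (0.235, 0.245)
_TOTAL_T_BULK = (0.558, 0.562)
_TOTAL_T_BORDER = 0.36


def _letter_values(tough: bool, n: int, band_b, bulk_t, border_t) -> np.ndarray:
    if not tough:
        return np.linspace(band_b[0], band_b[1], n)
    vals = np.empty(n)
    vals[0] = border_t
    vals[1:] = np.linspace(bulk_t[0], bulk_t[1], n - 1) if n > 1 else border_t
    return vals


def amplitude_for_shape_score(target: float, shape_mode: str, n_lobes: int,
                              seed: int, image_size: int,
                              radius_frac: float = 0.32,
                              raster: bool = True) -> float:
    """Invert the shape-score curve by bisection on the lobe amplitude.

    With ``raster`` the score is measured exactly as the taxonomy
    measures it (on the rasterized mask), so the realized score matches
    the target to raster precision; the analytic variant (polyline area
    over min-enclosing-circle area) is cheaper and used for a first pass.
    """
    from .complexity import min_enclosing_circle, shape_score

    def score(a: float) -> float:
        spec = PhantomSpec(image_size=image_size, shape_mode=shape_mode,
                           n_lobes=n_lobes, lobe_amplitude=a, seed=seed,
                           radius_frac=radius_frac)
        pts = boundary_curve(spec, n_samples=720)
        if raster:
            mask = geometry.fill_contour(
                geometry.resample_closed(pts, spacing=0.5),
                (image_size, image_size))
            return shape_score(mask)
        area = abs(geometry.signed_area(pts))
        _, _, r = min_enclosing_circle(pts)
        return 1.0 - area / (np.pi * r * r)

    # keep the radial profile strictly positive (second harmonic adds
    # up to 0.35 * a for the spiky modes) and the curve inside the frame
    hi = 0.68 if shape_mode != "simple_blob" else 0.80
    hi = min(hi, (0.45 / radius_frac - 1.0) / 1.45)
    lo = 0.0
    f_hi = score(hi)
    if target >= f_hi:
        return hi
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        s_mid = score(mid)
        if abs(s_mid - target) < 0.003:
            return mid
        if s_mid < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 5e-4:
            break
    return 0.5 * (lo + hi)


def spec_for_category(code: str, index: int, n_per_category: int,
                      seed: int, image_size: int = 192) -> PhantomSpec:
    """Build the PhantomSpec for phantom ``index`` of a category."""
    s_t, cmax_t, c_t = (letter == "T" for letter in code.split("|"))
    n = n_per_category
    shape_targets = _letter_values(s_t, n, _SHAPE_B, _SHAPE_T_BULK,
                                   _SHAPE_T_BORDER)
    max_vals = _letter_values(cmax_t, n, _MAX_B, _MAX_T_BULK, _MAX_T_BORDER)
    total_band = _TOTAL_B_WHEN_MAX_T if cmax_t else _TOTAL_B_WHEN_MAX_B
    total_vals = _letter_values(c_t, n, total_band, _TOTAL_T_BULK,
                                _TOTAL_T_BORDER)

    shape_mode = "spiculated" if s_t else "simple_blob"
    n_lobes = 9 if s_t else 3
    phantom_seed = int(np.random.SeedSequence(
        [seed, CATEGORY_ORDER.index(code), index]).generate_state(1)[0]
        % (2 ** 31))
    target_s = float(shape_targets[index])
    amp0 = amplitude_for_shape_score(target_s, shape_mode, n_lobes,
                                     phantom_seed, image_size,
                                     radius_frac=0.20, raster=False)
    # shrink the base radius so spiky profiles still fit in the frame,
    # then refine the amplitude against the rasterized score at that size
    radius_frac = min(0.32, 0.42 / (1.0 + 1.4 * amp0))
    amp = amplitude_for_shape_score(target_s, shape_mode, n_lobes,
                                    phantom_seed, image_size,
                                    radius_frac=radius_frac)
    n_false = 3 if (s_t or cmax_t) else (1 if c_t else 0)
    return PhantomSpec(
        image_size=image_size,
        shape_mode=shape_mode,
        n_lobes=n_lobes,
        lobe_amplitude=float(amp),
        gap_total_frac=float(total_vals[index]),
        gap_max_frac=float(max_vals[index]),
        n_false_edges=n_false,
        noise_sigma=0.25,
        seed=phantom_seed,
        radius_frac=radius_frac,
    )


def make_corpus(n_per_category: int, seed: int, image_size: int = 192,
                categories=CATEGORY_ORDER,
                out_dir: str | Path | None = None
                ) -> list[tuple[Phantom, str]]:
    """Generate a labeled corpus spanning the complexity categories.

    Returns ``[(phantom, category_code), ...]``; when ``out_dir`` is
    given, phantom files and a CSV manifest are written there.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    corpus: list[tuple[Phantom, str]] = []
    rows = []
    for code in categories:
        for j in range(n_per_category):
            spec = spec_for_category(code, j, n_per_category, seed,
                                     image_size)
            ph = make_phantom(spec)
            corpus.append((ph, code))
            rows.append({
                "id": f"{code.replace('|', '')}_{j:03d}",
                "category_code": code,
                "gap_total_frac": ph.realized_gap_total_frac,
                "gap_max_frac": ph.realized_gap_max_frac,
                "shape_score": ph.realized_shape_score,
                "seed": spec.seed,
            })
    if out_dir is not None:
        import pandas as pd

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for row, (ph, code) in zip(rows, corpus):
            paths = ph.save(out_dir, row["id"])
            row.update(paths)
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return corpus
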