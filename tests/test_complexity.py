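import numpy as np
import pytest

from madseg.complexity import (ComplexityLabel, ThresholdSet, categorize,
                               fit_thresholds, gap_statistics,
                               min_enclosing_circle, shape_score)


def brute_force_mec(points):
    """Smallest circle from all pairs and triples (O(n^3) oracle)."""
    from madseg.complexity import _circle_three, _circle_two, _in_circle

    pts = np.asarray(points, float)
    best = None
    candidates = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            candidates.append(_circle_two(pts[i], pts[j]))
            for k in range(j + 1, len(pts)):
                c = _circle_three(pts[i], pts[j], pts[k])
                if c is not None:
                    candidates.append(c)
    for c in candidates:
        if all(_in_circle(c, p) for p in pts):
            if best is None or c[2] < best[2]:
                best = c
    return best


class TestGapStatistics:
    def test_full_boundary_zero(self, clean_phantom):
        assert gap_statistics(clean_phantom.edge_map,
                              clean_phantom.gt_contour) == (0.0, 0.0)

    def test_empty_edge_map(self, clean_phantom):
        empty = np.zeros_like(clean_phantom.edge_map)
        assert gap_statistics(empty, clean_phantom.gt_contour) == (1.0, 1.0)

    def test_constructed_fractions_recovered(self, gappy_phantom):
        lg, lgm = gap_statistics(gappy_phantom.edge_map,
                                 gappy_phantom.gt_contour)
        assert lg == pytest.approx(0.30, abs=0.02)
        assert lgm == pytest.approx(0.20, abs=0.02)
        assert lgm <= lg

    def test_open_contour_rejected(self, clean_phantom):
        with pytest.raises(ValueError):
            gap_statistics(clean_phantom.edge_map,
                           clean_phantom.gt_contour[:2])


class TestMinEnclosingCircle:
    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            pts = rng.uniform(0, 100, size=(int(rng.integers(2, 13)), 2))
            cx, cy, r = min_enclosing_circle(pts)
            bx, by, br = brute_force_mec(pts)
            assert r == pytest.approx(br, abs=1e-6)
            d = np.sqrt((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2)
            assert d.max() <= r + 1e-6

    def test_cross_check_against_shapely(self):
        import shapely.geometry as sg
        from shapely import minimum_bounding_circle

        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, size=(40, 2))
        _, _, r = min_enclosing_circle(pts)
        mbc = minimum_bounding_circle(sg.MultiPoint(pts))
        # the polygonized circle's extent gives the diameter exactly
        # (its vertices lie on the true circle)
        x0, y0, x1, y1 = mbc.bounds
        r_shapely = max(x1 - x0, y1 - y0) / 2
        assert r == pytest.approx(r_shapely, rel=1e-6)


class TestShapeScore:
    def test_disk_near_zero(self):
        from skimage.draw import disk

        m = np.zeros((256, 256), bool)
        rr, cc = disk((128, 128), 100)
        m[rr, cc] = True
        assert shape_score(m) <= 0.02

    def test_thin_bar_high(self):
        m = np.zeros((120, 120), bool)
        m[58:62, 10:110] = True
        assert shape_score(m) >= 0.9

    def test_enclosing_circle_contains_all_pixel_centers(self, easy_phantom):
        rc = np.argwhere(easy_phantom.gt_mask)
        cx, cy, r = min_enclosing_circle(rc[:, ::-1].astype(float))
        d = np.sqrt((rc[:, 1] - cx) ** 2 + (rc[:, 0] - cy) ** 2)
        assert d.max() <= r + 1e-6

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_score(np.zeros((10, 10), bool))


class TestThresholdsAndCategorize:
    def test_mean_plus_std_arithmetic(self):
        lg = [0.1] * 9 + [1.0]
        rows = [(v, v / 2, v / 3) for v in lg]
        th = fit_thresholds(rows)
        assert th.L_prime == pytest.approx(0.46, abs=1e-9)

    def test_degenerate_corpus_warns(self):
        rows = [(0.2, 0.1, 0.3)] * 12
        with pytest.warns(UserWarning):
            th = fit_thresholds(rows)
        assert th.L_prime == pytest.approx(0.2)

    def test_order_independent(self):
        rng = np.random.default_rng(2)
        rows = rng.uniform(0, 1, size=(20, 3))
        a = fit_thresholds(rows)
        b = fit_thresholds(rows[::-1])
        assert a.L_prime == pytest.approx(b.L_prime)

    def test_code_assembly_and_boundaries(self):
        th = ThresholdSet(L_prime=0.3, S_max_prime=0.2, S_prime=0.4,
                          corpus_stats={})
        assert categorize(0, 0, 0, th).code_string == "B|B|B"
        assert categorize(0.9, 0.9, 0.9, th).code_string == "T|T|T"
        # exactly at threshold -> tough (strict < for baseline)
        assert categorize(0.3, 0.2, 0.4, th).code_string == "T|T|T"
        # order of letters is shape | max gap | total gap
        lab = categorize(0.9, 0.0, 0.0, th)
        assert lab.code_string == "B|B|T"

    def test_monotonicity_never_t_to_b(self):
        th = ThresholdSet(L_prime=0.3, S_max_prime=0.2, S_prime=0.4,
                          corpus_stats={})
        rng = np.random.default_rng(3)
        for _ in range(50):
            base = rng.uniform(0, 1, 3)
            bumped = np.clip(base + rng.uniform(0, 0.5, 3), 0, 1)
            a = categorize(*base, th).codes
            b = categorize(*bumped, th).codes
            for x, y in zip(a, b):
                assert not (x == "T" and y == "B")

    def test_threshold_roundtrip(self, tmp_path):
        th = fit_thresholds([(i / 20, i / 40, i / 60) for i in range(20)])
        th.save(tmp_path / "th.json")
        back = ThresholdSet.load(tmp_path / "th.json")
        assert back.L_prime == th.L_prime
        assert back.corpus_stats == th.corpus_stats
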