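"""Segmentation, projection, counting, colocalization and puncta splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from astrospat.detection import (
    CellRecord,
    colocalize,
    count_cells_per_frame,
    count_puncta,
    detect_cell_centers,
    max_project,
    segment_channel,
)
from astrospat.spatial import PointPattern
from astrospat.synthetic import render_channel


def cells_at(points, marker="m"):
    return [
        CellRecord(id=i + 1, marker=marker, centroid_um=(float(x), float(y)))
        for i, (x, y) in enumerate(points)
    ]


class TestSegment:
    def test_constant_image_below_threshold(self):
        seg = segment_channel(np.full((50, 50), 20, np.uint8), 70)
        assert seg.n_objects == 0
        assert seg.label_mask.max() == 0

    def test_two_squares(self):
        img = np.zeros((50, 50), np.uint8)
        img[5:15, 5:15] = 200
        img[30:40, 30:40] = 200
        seg = segment_channel(img, 70, pixel_size_um=1.0)
        assert seg.n_objects == 2
        assert seg.objects["area_um2"].tolist() == [100.0, 100.0]
        # centroid of a square occupying pixels 5..14 is at 10.0 μm
        assert seg.objects.loc[0, "x_um"] == pytest.approx(10.0)

    def test_min_area_filter_and_relabel(self):
        img = np.zeros((50, 50), np.uint8)
        img[5:15, 5:15] = 200   # 100 μm²
        img[30, 30] = 200       # 1 μm² speck
        seg = segment_channel(img, 70, min_area_um2=20.0)
        assert seg.n_objects == 1
        assert set(np.unique(seg.label_mask)) == {0, 1}

    def test_rejects_stack_and_bad_threshold(self):
        with pytest.raises(ValueError, match="2D"):
            segment_channel(np.zeros((2, 5, 5), np.uint8), 70)
        with pytest.raises(ValueError, match="threshold"):
            segment_channel(np.zeros((5, 5), np.uint8), 300)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 2**16), t1=st.integers(10, 120), dt=st.integers(1, 100))
    def test_threshold_monotonicity(self, seed, t1, dt):
        """Raising the threshold never increases the segmented area."""
        img = np.random.default_rng(seed).integers(0, 256, (60, 60), dtype=np.uint8)
        a1 = segment_channel(img, t1).total_area_um2
        a2 = segment_channel(img, t1 + dt).total_area_um2
        assert a2 <= a1


class TestMaxProject:
    def test_single_plane_identity(self):
        img = np.arange(25, dtype=np.uint8).reshape(5, 5)
        np.testing.assert_array_equal(max_project(img), img)
        np.testing.assert_array_equal(max_project(img[None]), img)

    def test_disjoint_bright_pixels_union(self):
        a = np.zeros((5, 5), np.uint8)
        b = np.zeros((5, 5), np.uint8)
        a[1, 1] = 200
        b[3, 3] = 150
        proj = max_project(np.stack([a, b]))
        assert proj[1, 1] == 200 and proj[3, 3] == 150

    def test_matches_elementwise_oracle(self, rng):
        stack = rng.integers(0, 256, (4, 6, 6), dtype=np.uint8)
        proj = max_project(stack)
        for r in range(6):
            for c in range(6):
                assert proj[r, c] == max(stack[z, r, c] for z in range(4))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.zeros((0, 5, 5), np.uint8))


class TestCounting:
    @pytest.mark.parametrize(
        "n, frame, expected",
        [(12, 0.4, 12.0), (6, 0.2, 12.0), (0, 0.4, 0.0)],
    )
    def test_normalized_counts(self, n, frame, expected):
        raw, per_ref = count_cells_per_frame(n, frame)
        assert raw == n
        assert per_ref == pytest.approx(expected)

    def test_zero_frame_area_rejected(self):
        with pytest.raises(ValueError, match="frame_area"):
            count_cells_per_frame(3, 0.0)


class TestCenterDots:
    def test_recovers_isolated_somata(self, rng):
        pts: list[np.ndarray] = []
        while len(pts) < 20:
            c = rng.uniform(20, 180, size=2)
            if all(np.hypot(*(c - q)) > 25 for q in pts):
                pts.append(c)
        pat = PointPattern(np.array(pts), (200.0, 200.0))
        img = render_channel(pat, 2.5, 160, 10, 0.0, 1.0, 0)
        cells = detect_cell_centers(img, "gfap", 70, pixel_size_um=1.0)
        assert len(cells) == 20
        centers = np.array([c.centroid_um for c in cells])
        d = np.sqrt(((centers[:, None, :] - pat.points[None, :, :]) ** 2).sum(-1))
        assert d.min(axis=1).max() <= 1.5

    def test_blank_image_gives_no_cells(self):
        assert detect_cell_centers(np.full((50, 50), 10, np.uint8)) == []


class TestColocalize:
    def test_identical_lists_full_overlap(self, rng):
        pts = rng.uniform(0, 100, size=(10, 2))
        res = colocalize(cells_at(pts), cells_at(pts), 5.0)
        assert res.n_dual == 10
        assert res.pct_a_also_b == 100.0 and res.pct_b_also_a == 100.0

    def test_distant_lists_no_pairs(self):
        a = cells_at([(0, 0), (10, 0)])
        b = cells_at([(500, 500), (600, 600)])
        res = colocalize(a, b, 5.0)
        assert res.n_dual == 0

    def test_one_to_one_pairing(self):
        # two a-cells near one b-cell: only one may claim it
        a = cells_at([(0.0, 0.0), (2.0, 0.0)])
        b = cells_at([(1.0, 0.0)])
        res = colocalize(a, b, 5.0)
        assert res.n_dual == 1

    def test_symmetry_of_dual_count(self, rng):
        a = cells_at(rng.uniform(0, 200, (40, 2)))
        b = cells_at(rng.uniform(0, 200, (30, 2)))
        assert colocalize(a, b, 10.0).n_dual == colocalize(b, a, 10.0).n_dual

    def test_matches_optimal_assignment_on_separated_pairs(self, rng):
        """On well-separated dual cells (≤12 points) greedy pairing equals the
        exhaustive minimum-cost assignment."""
        for trial in range(20):
            r = np.random.default_rng(900 + trial)
            base: list[np.ndarray] = []
            while len(base) < 10:
                c = r.uniform(10, 290, size=2)
                if all(np.hypot(*(c - q)) > 25 for q in base):
                    base.append(c)
            a_pts = np.array(base)
            b_pts = a_pts[:6] + r.normal(0, 1.0, (6, 2))  # 6 dual partners
            res = colocalize(cells_at(a_pts), cells_at(b_pts), 5.0)
            d = np.sqrt(((a_pts[:, None] - b_pts[None]) ** 2).sum(-1))
            big = d.copy()
            big[big > 5.0] = 1e9
            ri, ci = linear_sum_assignment(big)
            optimal = {(i + 1, j + 1) for i, j in zip(ri, ci) if d[i, j] <= 5.0}
            assert set(res.pairing) == optimal

    def test_coloc_fraction_recovered(self, rng):
        """200 cells with 30% dual: measured percentage within binomial 3 SE."""
        a_pts = rng.uniform(0, 2000, size=(200, 2))
        dual = rng.random(200) < 0.3
        b_pts = a_pts[dual]
        res = colocalize(cells_at(a_pts), cells_at(b_pts), 5.0)
        se = 100 * np.sqrt(0.3 * 0.7 / 200)
        assert abs(res.pct_a_also_b - 30.0) < 3 * se


class TestCountPuncta:
    def _seg(self, points, window=(100.0, 100.0)):
        img = np.zeros((int(window[1]), int(window[0])), np.uint8)
        for x, y in points:
            img[int(y), int(x)] = 200
        return segment_channel(img, 70, 0.0, 1.0, "puncta")

    def test_full_frame_mask_puts_all_inside(self, rng):
        seg = self._seg(rng.uniform(0, 99, (30, 2)))
        res = count_puncta(seg, np.ones((100, 100), bool))
        assert res.n_outside == 0 and res.n_inside == seg.n_objects

    def test_constructed_densities(self):
        # 5 puncta in a 100 μm² mask, 10 outside in the remaining 900 μm²
        mask = np.zeros((100, 10), bool)   # frame 10x100 px = 1000 μm²
        mask[:10, :] = True                # 100 μm²
        inside = [(2, r) for r in (0, 2, 4, 6, 8)]
        outside = [(5, 20 + 5 * k) for k in range(10)]
        img = np.zeros((100, 10), np.uint8)
        for x, y in inside + outside:
            img[y, x] = 200
        seg = segment_channel(img, 70, 0.0, 1.0)
        res = count_puncta(seg, mask)
        assert (res.n_inside, res.n_outside) == (5, 10)
        assert res.density_inside == pytest.approx(0.05)
        assert res.density_outside == pytest.approx(10 / 900)

    def test_conservation_over_random_scenes(self):
        for s in range(100):
            r = np.random.default_rng(s)
            seg = self._seg(r.uniform(0, 99, (r.integers(0, 40), 2)))
            mask = r.random((100, 100)) < 0.3
            res = count_puncta(seg, mask)
            assert res.n_inside + res.n_outside == seg.n_objects

    def test_zero_area_compartment_flagged(self):
        seg = self._seg([(5, 5)])
        mask = np.zeros((100, 100), bool)
        mask[5, 5] = True
        with pytest.warns(UserWarning, match="zero-area"):
            res = count_puncta(seg, mask, compartment_area_um2=0.0)
        assert res.flagged and np.isnan(res.density_inside)
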