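"""Fitting primitives and the radius-adaptive distance criterion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circledet import (
    CircleModel,
    DegenerateFitError,
    PointSet,
    adaptive_tolerance,
    fit_circle,
    fit_line,
    lsqv,
    segment_circle_distance,
)


def circle_points(a, b, r, n, jitter=0.0, rng=None):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rr = r + (rng.uniform(-jitter, jitter, n) if jitter else 0.0)
    return np.column_stack([a + rr * np.cos(theta), b + rr * np.sin(theta)])


class TestPointSet:
    def test_set_algebra_and_dedup(self):
        a = PointSet([(0, 0), (1, 0), (1, 0), (2, 2)])
        b = PointSet([(1, 0), (3, 3)])
        assert len(a) == 3
        assert len(a | b) == 4
        assert len(a - b) == 2
        assert (a & b) == PointSet([(1, 0)])

    def test_min_point_is_y_then_x(self):
        assert PointSet([(5, 1), (0, 2), (3, 1)]).min_point_yx() == (1, 3)


class TestFitLine:
    def test_collinear_points_recovered_exactly(self):
        m = fit_line(PointSet([(0, 0), (1, 0), (2, 0)]))
        # y = 0: normal (0, 1), offset 0
        assert abs(abs(m.ny) - 1) < 1e-12 and abs(m.c) < 1e-12

    def test_two_point_vertical_line(self):
        m = fit_line(PointSet([(0, 0), (0, 5)]))
        assert abs(abs(m.nx) - 1) < 1e-12 and abs(m.c) < 1e-12

    def test_total_least_squares_matches_eigendecomposition(self):
        # symmetric triangle: TLS line is horizontal through the centroid
        m = fit_line(PointSet([(0, 0), (1, 1), (2, 0)]))
        d = m.distances(np.array([[0.0, 1 / 3]]))
        assert abs(m.nx) < 1e-12
        assert d[0] < 1e-12

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_line(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestFitCircle:
    def test_three_points_on_unit_circle(self):
        m = fit_circle(PointSet([(1, 0), (0, 1), (-1, 0)]))
        assert np.allclose([m.a, m.b, m.r], [0, 0, 1], atol=1e-12)

    def test_exact_points_recovered_to_machine_precision(self):
        pts = circle_points(10, 20, 7, 12)
        m = fit_circle(pts)
        assert np.allclose([m.a, m.b, m.r], [10, 20, 7], atol=1e-9)

    def test_jittered_circle_close_to_truth_and_geometric_fit(self):
        rng = np.random.default_rng(3)
        pts = circle_points(0, 0, 50, 20, jitter=0.5, rng=rng)
        m = fit_circle(pts)
        assert max(abs(m.a), abs(m.b), abs(m.r - 50)) <= 0.5
        # independent oracle: brute-force grid refinement of the geometric
        # (sum of squared radial residuals) objective
        ga, gb, gr = _grid_refine_circle(pts)
        assert max(abs(m.a - ga), abs(m.b - gb), abs(m.r - gr)) <= 0.3

    def test_collinear_input_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_circle(np.array([[float(i), 2.0 * i] for i in range(10)]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        angle=st.floats(0, 2 * np.pi),
    )
    def test_rigid_motion_equivariance(self, dx, dy, angle):
        rng = np.random.default_rng(7)
        pts = circle_points(5, -3, 20, 15, jitter=0.3, rng=rng)
        m0 = fit_circle(pts)
        c, s = np.cos(angle), np.sin(angle)
        moved = pts @ np.array([[c, s], [-s, c]]).T + [dx, dy]
        m1 = fit_circle(moved)
        expect = np.array([m0.a * c + m0.b * s + dx, -m0.a * s + m0.b * c + dy])
        assert np.allclose([m1.a, m1.b], expect, atol=1e-6)
        assert abs(m1.r - m0.r) < 1e-6


def _grid_refine_circle(pts, levels=6):
    """Brute-force geometric circle fit by shrinking-grid search."""
    cx, cy = pts.mean(axis=0)
    r0 = np.hypot(*(pts - [cx, cy]).T).mean()
    best = (cx, cy, r0)
    span = 2.0
    for _ in range(levels):
        grids = [np.linspace(v - span, v + span, 9) for v in best]
        best_obj = np.inf
        for a in grids[0]:
            for b in grids[1]:
                d = np.hypot(pts[:, 0] - a, pts[:, 1] - b)
                for r in grids[2]:
                    obj = ((d - r) ** 2).sum()
                    if obj < best_obj:
                        best_obj, best = obj, (a, b, r)
        span /= 4.0
    return best


class TestDistanceCriterion:
    def test_on_circle_points_have_zero_distance(self):
        m = CircleModel(0, 0, 5)
        assert segment_circle_distance(np.array([[5.0, 0], [0, 5.0]]), m) == 0

    def test_maximum_over_points(self):
        m = CircleModel(0, 0, 5)
        assert segment_circle_distance(np.array([[6.0, 0.0]]), m) == pytest.approx(1)
        pts = np.array([[6.0, 0.0], [0.0, 7.0], [-5.0, 0.0]])
        assert segment_circle_distance(pts, m) == pytest.approx(2)

    @pytest.mark.parametrize("r,expected", [(10, 1.0), (40, 2.0), (100, 3.0)])
    def test_tolerance_clamp(self, r, expected, params):
        assert adaptive_tolerance(r, params) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 500))
    def test_tolerance_bounded_and_monotone(self, r):
        from circledet import DetectorParams

        p = DetectorParams()
        t = adaptive_tolerance(r, p)
        assert p.t_dp <= t <= p.k_px
        assert adaptive_tolerance(r + 1, p) >= t


class TestLsqv:
    def test_exact_arc_accepted(self, params):
        theta = np.linspace(0, np.pi / 2, 30)
        pts = np.column_stack([30 * np.cos(theta), 30 * np.sin(theta)])
        m = lsqv(pts, params)
        assert m is not None
        assert np.allclose([m.a, m.b, m.r], [0, 0, 30], atol=1e-6)

    def test_straight_segment_rejected(self, params):
        pts = np.column_stack([np.arange(20.0), np.zeros(20)])
        assert lsqv(pts, params) is None

    def test_outlier_breaks_the_distance_criterion(self, params):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([30 * np.cos(theta), 30 * np.sin(theta)])
        pts[0] = [35.0, 0.0]  # 5 px radial outlier vs tolerance 1.5
        assert lsqv(pts, params) is None

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_returned_model_satisfies_its_own_criterion(self, seed):
        from circledet import DetectorParams

        p = DetectorParams()
        rng = np.random.default_rng(seed)
        r = rng.uniform(10, 80)
        pts = circle_points(0, 0, r, 25, jitter=0.4, rng=rng)
        m = lsqv(pts, p)
        if m is not None:
            assert segment_circle_distance(pts, m) < adaptive_tolerance(m.r, p)
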