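"""Hierarchical merging of segments into candidate circles."""

import numpy as np
import pytest

from circledet import PointSet, Segment, hs, lsqv, merge_pass, search_extension
from circledet.hs import SegmentLibrary

from conftest import arc_points


def line_segment(x0, x1, y):
    return Segment(pts=PointSet([(x, y) for x in range(x0, x1 + 1)]),
                   model=None, kind="line")


def arc_segment(a, b, r, t0, t1, params):
    pts = arc_points(a, b, r, t0, t1)
    return Segment(pts=pts, model=lsqv(pts, params), kind="arc")


class TestSearchExtension:
    def test_line_extension_boxes_catch_nearby_segment(self, params):
        seg = line_segment(0, 20, 0)
        near = Segment(pts=PointSet([(30, 2), (31, 2)]))
        far = Segment(pts=PointSet([(60, 40), (61, 40)]))
        lib = SegmentLibrary([seg, near, far])
        found = search_extension(seg, lib, params)
        # extension points (-8, 0) and (28, 0); squares of side 16:
        # (30, 2) lies inside the right square, (60, 40) inside neither
        assert found == [near]

    def test_arc_extension_points_advance_by_arc_length(self, params):
        seg = arc_segment(0, 0, 20, 0, np.pi / 2, params)
        dtheta = (params.m_min / 2) / 20  # 8/20 rad
        probe_lo = Segment(pts=PointSet(
            [(round(20 * np.cos(-dtheta)), round(20 * np.sin(-dtheta)))]
        ))
        probe_hi = Segment(pts=PointSet(
            [(round(20 * np.cos(np.pi / 2 + dtheta)),
              round(20 * np.sin(np.pi / 2 + dtheta)))]
        ))
        off = Segment(pts=PointSet([(-20, -20)]))
        lib = SegmentLibrary([seg, probe_lo, probe_hi, off])
        found = search_extension(seg, lib, params)
        assert probe_lo in found and probe_hi in found and off not in found

    def test_full_circle_has_no_extension(self, params):
        seg = arc_segment(50, 50, 30, 0, 2 * np.pi, params)
        other = Segment(pts=PointSet([(80, 50)]))
        assert search_extension(seg, SegmentLibrary([seg, other]), params) == []

    def test_empty_library_empty_candidates(self, params):
        seg = line_segment(0, 20, 0)
        assert search_extension(seg, SegmentLibrary([seg]), params) == []


class TestMergePass:
    def test_contiguous_arcs_merge_toward_true_circle(self, params):
        a, b, r = 100, 100, 40
        segs = [
            arc_segment(a, b, r, t, t + np.pi / 3, params)
            for t in (0, np.pi / 3, 2 * np.pi / 3)
        ]
        lib, changed = merge_pass(SegmentLibrary(segs), params)
        assert changed
        assert len(lib.entries) < 3

    def test_isolated_line_without_model_deleted(self, params):
        lib, changed = merge_pass(
            SegmentLibrary([line_segment(0, 20, 0)]), params
        )
        assert lib.entries == [] and not changed

    def test_distant_arcs_do_not_merge(self, params):
        s1 = arc_segment(50, 50, 30, 0, np.pi, params)
        s2 = arc_segment(300, 50, 30, 0, np.pi, params)
        lib, changed = merge_pass(SegmentLibrary([s1, s2]), params)
        assert not changed
        assert set(lib.entries) == {s1, s2}


class TestHs:
    def test_four_arcs_assemble_into_one_circle(self, params):
        a, b, r = 150, 120, 45
        segs = [
            arc_segment(a, b, r, t, t + np.pi / 2, params)
            for t in (0, np.pi / 2, np.pi, 3 * np.pi / 2)
        ]
        out = hs(SegmentLibrary(segs), params)
        assert len(out.entries) == 1
        m = out.entries[0].model
        assert m is not None
        assert max(abs(m.a - a), abs(m.b - b), abs(m.r - r)) <= 1.0

    def test_two_separate_circles_stay_separate(self, params):
        segs = []
        for (a, b, r) in [(80, 80, 35), (280, 180, 50)]:
            segs += [
                arc_segment(a, b, r, t, t + np.pi / 2, params)
                for t in (0, np.pi / 2, np.pi, 3 * np.pi / 2)
            ]
        out = hs(SegmentLibrary(segs), params)
        models = sorted(
            (e.model.as_tuple() for e in out.entries), key=lambda t: t[0]
        )
        assert len(models) == 2
        assert np.allclose(models[0], (80, 80, 35), atol=1.0)
        assert np.allclose(models[1], (280, 180, 50), atol=1.0)

    def test_empty_library_fixed_point(self, params):
        assert hs(SegmentLibrary([]), params).entries == []

    def test_no_points_invented(self, params):
        a, b, r = 100, 100, 40
        segs = [
            arc_segment(a, b, r, t, t + np.pi / 3, params)
            for t in (0, np.pi / 3, 2 * np.pi / 3, np.pi)
        ]
        all_in = PointSet([])
        for s in segs:
            all_in = all_in | s.pts
        out = hs(SegmentLibrary(segs), params)
        for e in out.entries:
            assert e.pts.issubset(all_in)
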