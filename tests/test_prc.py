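"""Patch partitioning and adaptive in-patch RANSAC."""

import numpy as np
import pytest

from circledet import (
    DetectorParams,
    EdgeMap,
    PointSet,
    extract_structures,
    iteration_count,
    partition,
    sample_ok,
)
from circledet.prc import Patch, covered_extent


def edge_map_from_points(shape, pts):
    mask = np.zeros(shape, bool)
    for x, y in pts:
        mask[y, x] = True
    return EdgeMap(mask)


class TestPartition:
    def test_64x64_has_nine_patches(self, params):
        em = EdgeMap(np.zeros((64, 64), bool))
        patches = partition(em, params)
        origins = {(p.x0, p.y0) for p in patches}
        assert origins == {(x, y) for x in (0, 16, 32) for y in (0, 16, 32)}

    def test_image_smaller_than_patch_yields_none(self, params):
        assert partition(EdgeMap(np.zeros((31, 31), bool)), params) == []

    def test_exact_patch_size_single_tile(self, params):
        patches = partition(EdgeMap(np.zeros((32, 32), bool)), params)
        assert len(patches) == 1 and (patches[0].x0, patches[0].y0) == (0, 0)

    def test_interior_points_covered_and_assigned(self, params):
        rng = np.random.default_rng(0)
        pts = np.unique(rng.integers(16, 112, size=(200, 2)), axis=0)
        em = edge_map_from_points((128, 128), pts)
        patches = partition(em, params)
        covered = set()
        for p in patches:
            for x, y in p.pts:
                assert p.x0 <= x < p.x0 + p.size
                assert p.y0 <= y < p.y0 + p.size
                covered.add((x, y))
        assert covered == {tuple(pt) for pt in pts}

    def test_covered_extent_accounts_for_stride_misalignment(self, params):
        assert covered_extent((300, 400), params) == (288, 400)
        assert covered_extent((64, 64), params) == (64, 64)
        assert covered_extent((20, 64), params) == (0, 64)


class TestIterationCount:
    def test_adaptive_budget_matches_arbitrary_precision_oracle(self, params):
        b256 = iteration_count(256, params, t=2)
        assert b256.b == pytest.approx(0.99609375, abs=1e-12)
        assert b256.n_iter == 1177
        b32 = iteration_count(32, params, t=2)
        assert b32.b == pytest.approx(0.75, abs=1e-12)
        assert b32.n_iter == 17

    def test_at_or_below_m_min_is_skipped(self, params):
        assert iteration_count(16, params, t=2).n_iter == 0
        assert iteration_count(5, params, t=3).n_iter == 0

    def test_cap_applies_for_dense_patches(self, params):
        b = iteration_count(1024, params, t=3)
        assert b.n_iter == params.n_max

    @pytest.mark.parametrize("n", [17, 40, 100, 500])
    @pytest.mark.parametrize("t", [2, 3])
    def test_budget_invariants(self, n, t, params):
        b = iteration_count(n, params, t)
        assert 0 <= b.b < 1
        assert 1 <= b.n_iter <= params.n_max


class TestSampleOk:
    def test_far_pair_accepted(self, params):
        assert sample_ok(PointSet([(0, 0), (10, 0)]), params)

    def test_close_pair_rejected(self, params):
        assert not sample_ok(PointSet([(0, 0), (2, 0)]), params)

    def test_boundary_distance_not_rejected(self, params):
        # min pairwise distance exactly K: the strict "< K" guard passes it
        assert sample_ok(PointSet([(0, 0), (0, 4), (3, 0)]), params)


class TestExtractStructures:
    def run_many(self, pts, params, seeds=range(10)):
        patch = Patch(0, 0, 32, np.asarray(pts, dtype=np.int64))
        return [
            extract_structures(patch, params, np.random.default_rng(s))
            for s in seeds
        ]

    def test_straight_chain_found_as_one_line(self, params):
        pts = [(x, 12) for x in range(32)]
        successes = 0
        for segs in self.run_many(pts, params):
            lines = [s for s in segs if s.kind == "line"]
            if len(segs) == 1 and lines and len(lines[0].pts) >= 31:
                successes += 1
        assert successes >= 9

    def test_quarter_arc_recovered_with_model(self, params):
        theta = np.linspace(0, np.pi / 2, 40)
        pts = np.unique(
            np.round(np.column_stack([20 * np.cos(theta), 20 * np.sin(theta)])),
            axis=0,
        ).astype(int)
        pts = pts[(pts[:, 0] < 32) & (pts[:, 1] < 32)]
        successes = 0
        for segs in self.run_many(pts, params):
            arcs = [s for s in segs if s.kind == "arc" and s.model]
            if arcs and abs(arcs[0].model.r - 20) <= 1.0:
                successes += 1
        assert successes >= 9

    def test_scattered_points_yield_nothing(self, params):
        rng = np.random.default_rng(1)
        pts = rng.integers(0, 32, size=(10, 2))
        patch = Patch(0, 0, 32, np.unique(pts, axis=0))
        assert extract_structures(patch, params, np.random.default_rng(2)) == []

    def test_emitted_segments_are_disjoint(self, params):
        rng = np.random.default_rng(4)
        theta = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        circ = np.round(np.column_stack(
            [16 + 13 * np.cos(theta), 16 + 13 * np.sin(theta)]
        ))
        line = np.column_stack([np.arange(32), np.full(32, 3)])
        pts = np.unique(np.vstack([circ, line]).astype(int), axis=0)
        pts = pts[(pts >= 0).all(axis=1) & (pts < 32).all(axis=1)]
        patch = Patch(0, 0, 32, pts)
        segs = extract_structures(patch, params, rng)
        assert len(segs) >= 2
        for i, a in enumerate(segs):
            for b in segs[i + 1:]:
                assert len(a.pts & b.pts) == 0

    def test_identical_seed_identical_output(self, params):
        theta = np.linspace(0, 2 * np.pi, 70, endpoint=False)
        pts = np.unique(np.round(np.column_stack(
            [16 + 12 * np.cos(theta), 16 + 12 * np.sin(theta)]
        )).astype(int), axis=0)
        patch = Patch(0, 0, 32, pts)
        a = extract_structures(patch, params, np.random.default_rng(11))
        b = extract_structures(patch, params, np.random.default_rng(11))
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sa.pts == sb.pts and sa.kind == sb.kind
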