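"""Hierarchical segment merging: bottom-up assembly of candidate circles.

Each library entry is a segment (point set) with, when the validated
least-squares fit succeeds, a circle model.  A merge pass extends every
segment beyond its two endpoints — along the fitted line for model-less
segments, along the circle by arc length for model-bearing ones — and
searches square regions around the extension points for partners.  The
partner whose joint fit has the smallest maximum radial deviation (within
the radius-adaptive tolerance) is merged in; segments with neither a
model nor a partner are dropped as un-circle-like.  Passes alternate with
non-maximum suppression until a pass changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .geometry import (
    CircleModel,
    DegenerateFitError,
    Segment,
    adaptive_tolerance,
    fit_circle,
    fit_line,
    lsqv,
    segment_circle_distance,
)
from .params import DetectorParams
from .suppression import nms

__all__ = ["SegmentLibrary", "search_extension", "merge_pass", "hs"]


@dataclass
class SegmentLibrary:
    """Working set of segments during hierarchical merging."""

    entries: List[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def _arc_endpoints(
    pts: np.ndarray, model: CircleModel, params: DetectorParams
) -> Optional[Tuple[Tuple[float, int], Tuple[float, int]]]:
    """Angular endpoints of an arc and their outward directions.

    The arc occupies the complement of the largest angular gap between
    consecutive support points.  Returns ((θ1, +1), (θ2, −1)) where the
    sign is the outward angular direction, or ``None`` for a full circle
    (largest gap shorter than K along the circumference — nothing to
    extend into).
    """
    ang = np.sort(
        np.mod(np.arctan2(pts[:, 1] - model.b, pts[:, 0] - model.a), 2 * np.pi)
    )
    gaps = np.diff(ang, append=ang[0] + 2 * np.pi)
    i = int(np.argmax(gaps))
    if gaps[i] * model.r <= params.k_px:
        return None
    theta_ccw = float(ang[i])          # extends counter-clockwise into the gap
    theta_cw = float(ang[(i + 1) % len(ang)])  # extends clockwise into the gap
    return (theta_ccw, +1), (theta_cw, -1)


def _extension_centers(
    seg: Segment, params: DetectorParams
) -> List[Tuple[float, float]]:
    half = params.m_min / 2.0
    if seg.model is None:
        try:
            line = fit_line(seg.pts)
        except DegenerateFitError:
            return []
        (p_lo, p_hi) = line.endpoints
        dx, dy = line.direction
        return [
            (p_lo[0] - half * dx, p_lo[1] - half * dy),
            (p_hi[0] + half * dx, p_hi[1] + half * dy),
        ]
    m = seg.model
    span = _arc_endpoints(seg.pts.array.astype(float), m, params)
    if span is None:
        return []
    dtheta = half / m.r  # advance by arc length m_min/2
    centers = []
    for theta, sign in span:
        t = theta + sign * dtheta
        centers.append((m.a + m.r * np.cos(t), m.b + m.r * np.sin(t)))
    return centers


def search_extension(
    seg: Segment, lib: SegmentLibrary, params: DetectorParams
) -> List[Segment]:
    """Find library segments reachable beyond the endpoints of ``seg``.

    Builds two square search regions of side m_min centred m_min/2 beyond
    the endpoints (along the line for model-less segments, along the arc
    for model-bearing ones) and returns every *other* entry with at least
    one point inside either region.  Full circles have no endpoints and
    return no candidates.
    """
    if len(seg.pts) < 2:
        return []
    centers = _extension_centers(seg, params)
    if not centers:
        return []
    half = params.m_min / 2.0
    found: List[Segment] = []
    for other in lib.entries:
        if other is seg:
            continue
        arr = other.pts.array
        for cx, cy in centers:
            inside = (
                (np.abs(arr[:, 0] - cx) <= half)
                & (np.abs(arr[:, 1] - cy) <= half)
            )
            if inside.any():
                found.append(other)
                break
    return found


def merge_pass(
    lib: SegmentLibrary, params: DetectorParams
) -> Tuple[SegmentLibrary, bool]:
    """One sweep of best-partner merging over the library.

    For each segment (longest first), the extension candidate minimizing
    the joint-fit maximum radial deviation D — subject to D below the
    tolerance for the joint radius — is merged in immediately, so later
    iterations see the merged segment.  A model-less segment with no
    partner is deleted.  ``changed`` reports whether any merge happened
    (deletions alone do not count).
    """
    order = sorted(
        lib.entries, key=lambda s: (-len(s.pts), s.pts.min_point_yx())
    )
    working = list(order)
    changed = False
    for seg in order:
        if seg not in working:
            continue  # consumed by an earlier merge
        snapshot = SegmentLibrary(working)
        best: Optional[Segment] = None
        best_d = np.inf
        for cand in search_extension(seg, snapshot, params):
            joint = seg.pts | cand.pts
            try:
                m = fit_circle(joint)
            except DegenerateFitError:
                continue
            d = segment_circle_distance(joint, m)
            if d < best_d and d < adaptive_tolerance(m.r, params):
                best, best_d = cand, d
        if best is not None:
            joint = seg.pts | best.pts
            merged = Segment(pts=joint, model=lsqv(joint, params), kind="arc")
            working.remove(seg)
            working.remove(best)
            working.append(merged)
            changed = True
        elif seg.model is None:
            working.remove(seg)
    return SegmentLibrary(working), changed


def hs(lib: SegmentLibrary, params: DetectorParams) -> SegmentLibrary:
    """Merge segments bottom-up until a fixed point.

    The input models are recomputed first (every entry gets the validated
    least-squares fit of its own points, or ``None``), then merge passes
    alternate with non-maximum suppression until a pass performs no merge.
    Each merge reduces the entry count by one, so the pass count is
    bounded by the initial library size; exceeding it indicates a logic
    error and aborts.
    """
    entries = [
        Segment(pts=s.pts, model=lsqv(s.pts, params), kind=s.kind)
        for s in lib.entries
    ]
    current = SegmentLibrary(entries)
    cap = len(entries) + 1
    passes = 0
    while True:
        current, changed = merge_pass(current, params)
        if not changed:
            return current
        current = SegmentLibrary(nms(current.entries, params))
        passes += 1
        if passes > cap:
            raise RuntimeError(
                f"hierarchical merging did not converge within {cap} passes "
                f"({len(current)} entries remain)"
            )
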