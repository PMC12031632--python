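"""Patch-local RANSAC extraction of line segments and circular arcs.

The edge map is tiled into overlapping square patches (side L, stride S;
the defaults give 50 % overlap so structures crossing a patch boundary are
still seen whole by some patch).  Within each patch, RANSAC competes two
structure hypotheses — lines (2 support points) and circles (3 support
points) — with the iteration count computed adaptively from the worst-case
inlier fraction m_min/|V|: the number of samplings N guarantees probability
p_f of hitting at least one all-inlier support for any structure of at
least m_min points.

Extraction is iterative: the best-supported candidate of a round is
accepted, its inliers removed, and budgets recomputed from the shrunken
point set, until nothing of size m_min remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .edges import EdgeMap
from .geometry import PointSet, Segment, lsqv
from .params import DetectorParams

__all__ = [
    "Patch",
    "RansacBudget",
    "covered_extent",
    "partition",
    "iteration_count",
    "sample_ok",
    "extract_structures",
]


def covered_extent(shape: Tuple[int, int], params: DetectorParams) -> Tuple[int, int]:
    """Extent (height, width) of the image area covered by some patch.

    Patch origins are multiples of the stride and patches must lie fully
    inside the image, so when a dimension minus the patch size is not a
    multiple of the stride, a strip along that border is outside every
    patch and invisible to the detector.
    """
    L, S = params.patch_size, params.patch_stride
    h, w = shape
    h_cov = ((h - L) // S) * S + L if h >= L else 0
    w_cov = ((w - L) // S) * S + L if w >= L else 0
    return h_cov, w_cov

_CHUNK = 4096  # samplings vectorized per block


@dataclass(frozen=True)
class Patch:
    """A square window of the edge map with the edge points inside it."""

    x0: int
    y0: int
    size: int
    pts: np.ndarray  # (n, 2) int array of (x, y)

    def __len__(self) -> int:
        return self.pts.shape[0]


@dataclass(frozen=True)
class RansacBudget:
    """Adaptive sampling budget for one structure type in one patch.

    ``b`` is the per-sampling failure probability 1 − (m_min/|V|)^t;
    ``n_iter`` = ⌈log_b(1 − p_f)⌉ samplings, capped at ``n_max``.
    A budget of 0 means the patch is skipped (too few points).
    """

    b: float
    n_iter: int
    t: int


def partition(edge_map: EdgeMap, params: DetectorParams) -> List[Patch]:
    """Tile the edge map into L×L patches at stride S.

    Patch origins are multiples of S; windows that would overlap the image
    border are discarded, so an image smaller than L in either axis yields
    no patches.
    """
    L, S = params.patch_size, params.patch_stride
    h, w = edge_map.height, edge_map.width
    pts = edge_map.points()
    patches: List[Patch] = []
    for y0 in range(0, h - L + 1, S):
        for x0 in range(0, w - L + 1, S):
            inside = (
                (pts[:, 0] >= x0)
                & (pts[:, 0] < x0 + L)
                & (pts[:, 1] >= y0)
                & (pts[:, 1] < y0 + L)
            )
            patches.append(Patch(x0, y0, L, pts[inside]))
    return patches


def iteration_count(n_points: int, params: DetectorParams, t: int) -> RansacBudget:
    """Sampling budget guaranteeing confidence p_f for m_min-point structures.

    With |V| = ``n_points`` edge points, the worst admissible structure has
    inlier fraction m_min/|V|; one sampling of t support points is
    all-inlier with probability (m_min/|V|)^t, so N = ⌈log(1−p_f)/log(b)⌉
    samplings with b = 1 − (m_min/|V|)^t leave at most 1−p_f probability
    of missing it.  Patches with |V| ≤ m_min are skipped (budget 0).
    """
    if n_points < 0:
        raise ValueError("n_points must be non-negative")
    if n_points <= params.m_min:
        return RansacBudget(b=0.0, n_iter=0, t=t)
    ratio = (params.m_min / n_points) ** t
    b = 1.0 - ratio
    n = math.ceil(math.log(1.0 - params.p_f) / math.log(b))
    n = max(1, min(int(n), params.n_max))
    return RansacBudget(b=b, n_iter=n, t=t)


def sample_ok(support: PointSet | np.ndarray, params: DetectorParams) -> bool:
    """Reject minimal samples containing a point pair closer than K.

    Points separated by less than the minimum distinguishable distance
    carry no independent constraint and produce unstable fits.
    """
    arr = support.array if isinstance(support, PointSet) else np.asarray(support, float)
    n = arr.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if math.hypot(*(arr[i] - arr[j])) < params.k_px:
                return False
    return True


# -- vectorized sampling helpers --------------------------------------


def _draw_pairs(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    """Uniform distinct index pairs, shape (count, 2)."""
    i = rng.integers(0, n, size=count)
    j = rng.integers(0, n - 1, size=count)
    j = j + (j >= i)
    return np.column_stack([i, j])


def _draw_triples(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    """Uniform distinct index triples, shape (count, 3)."""
    i = rng.integers(0, n, size=count)
    j = rng.integers(0, n - 1, size=count)
    j = j + (j >= i)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    k = rng.integers(0, n - 2, size=count)
    k = k + (k >= lo)
    k = k + (k >= hi)
    return np.column_stack([i, j, k])


def _pairwise_min_dist(support: np.ndarray) -> np.ndarray:
    """Minimum pairwise distance within each (count, t, 2) support block."""
    count, t, _ = support.shape
    dmin = np.full(count, np.inf)
    for a in range(t):
        for b in range(a + 1, t):
            d = np.hypot(
                support[:, a, 0] - support[:, b, 0],
                support[:, a, 1] - support[:, b, 1],
            )
            dmin = np.minimum(dmin, d)
    return dmin


def _line_inlier_counts(
    support: np.ndarray, V: np.ndarray, t_dp: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Inlier counts for line hypotheses through point pairs.

    Returns (counts, valid); degenerate pairs are invalid.
    """
    p1, p2 = support[:, 0, :], support[:, 1, :]
    d = p2 - p1
    norm = np.hypot(d[:, 0], d[:, 1])
    valid = norm > 0
    nx = np.where(valid, -d[:, 1] / np.where(valid, norm, 1.0), 0.0)
    ny = np.where(valid, d[:, 0] / np.where(valid, norm, 1.0), 0.0)
    # distance of every V point from every hypothesized line
    dist = np.abs(
        (V[None, :, 0] - p1[:, None, 0]) * nx[:, None]
        + (V[None, :, 1] - p1[:, None, 1]) * ny[:, None]
    )
    counts = (dist < t_dp).sum(axis=1)
    return counts, valid


def _circum_circles(support: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circumcircle (cx, cy, r) of each point triple; NaN radius if collinear."""
    ax, ay = support[:, 0, 0], support[:, 0, 1]
    bx, by = support[:, 1, 0], support[:, 1, 1]
    cx_, cy_ = support[:, 2, 0], support[:, 2, 1]
    d = 2.0 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
    ok = np.abs(d) > 1e-9
    dd = np.where(ok, d, 1.0)
    a2 = ax**2 + ay**2
    b2 = bx**2 + by**2
    c2 = cx_**2 + cy_**2
    ux = (a2 * (by - cy_) + b2 * (cy_ - ay) + c2 * (ay - by)) / dd
    uy = (a2 * (cx_ - bx) + b2 * (ax - cx_) + c2 * (bx - ax)) / dd
    r = np.hypot(ax - ux, ay - uy)
    r = np.where(ok, r, np.nan)
    return ux, uy, r


def _circle_inlier_counts(
    support: np.ndarray, V: np.ndarray, t_dp: float
) -> Tuple[np.ndarray, np.ndarray, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    ux, uy, r = _circum_circles(support)
    valid = np.isfinite(r) & (r > 0)
    dist = np.abs(
        np.hypot(V[None, :, 0] - ux[:, None], V[None, :, 1] - uy[:, None])
        - r[:, None]
    )
    counts = np.where(valid, (dist < t_dp).sum(axis=1), 0)
    return counts, valid, (ux, uy, r)


def _best_candidate(
    V: np.ndarray,
    rng: np.random.Generator,
    params: DetectorParams,
    t: int,
) -> Optional[Tuple[int, np.ndarray]]:
    """Best hypothesis of one structure type within the adaptive budget.

    Runs the full budget of samplings (vectorized in blocks), rejects
    supports with a pair closer than K, and returns the inlier mask of
    the hypothesis with the most inliers, provided it reaches m_min.
    """
    n = V.shape[0]
    budget = iteration_count(n, params, t)
    if budget.n_iter == 0:
        return None
    best_count = 0
    best_model: Optional[Tuple] = None
    remaining = budget.n_iter
    while remaining > 0:
        block = min(_CHUNK, remaining)
        remaining -= block
        idx = (_draw_pairs if t == 2 else _draw_triples)(rng, n, block)
        support = V[idx].astype(float)
        ok = _pairwise_min_dist(support) >= params.k_px
        if t == 2:
            counts, valid = _line_inlier_counts(support, V.astype(float), params.t_dp)
            models = support
        else:
            counts, valid, (ux, uy, r) = _circle_inlier_counts(
                support, V.astype(float), params.t_dp
            )
            models = (ux, uy, r)
        counts = np.where(ok & valid, counts, 0)
        i = int(np.argmax(counts))
        if counts[i] > best_count:
            best_count = int(counts[i])
            if t == 2:
                best_model = ("line", support[i, 0], support[i, 1])
            else:
                best_model = ("circle", ux[i], uy[i], r[i])
    if best_count < params.m_min or best_model is None:
        return None
    # recompute the winning hypothesis' inlier mask
    Vf = V.astype(float)
    if best_model[0] == "line":
        _, p1, p2 = best_model
        d = p2 - p1
        norm = math.hypot(*d)
        nx, ny = -d[1] / norm, d[0] / norm
        dist = np.abs((Vf[:, 0] - p1[0]) * nx + (Vf[:, 1] - p1[1]) * ny)
    else:
        _, ux, uy, r = best_model
        dist = np.abs(np.hypot(Vf[:, 0] - ux, Vf[:, 1] - uy) - r)
    mask = dist < params.t_dp
    return best_count, mask


def extract_structures(
    patch: Patch, params: DetectorParams, rng: np.random.Generator
) -> List[Segment]:
    """Extract line segments and circular arcs from one patch.

    Each round runs the adaptive line and circle budgets against the
    current point set; the candidate with the most inliers wins (ties go
    to the circle, since large-radius arcs mimic lines locally), its
    points are removed, and the round repeats until no structure of
    m_min points remains.  Arc segments carry a validated least-squares
    model when the refit meets the distance criterion.
    """
    V = np.asarray(patch.pts, dtype=np.int64).copy()
    out: List[Segment] = []
    while V.shape[0] > params.m_min:
        line_cand = _best_candidate(V, rng, params, t=2)
        circ_cand = _best_candidate(V, rng, params, t=3)
        line_n = line_cand[0] if line_cand else 0
        circ_n = circ_cand[0] if circ_cand else 0
        if line_n == 0 and circ_n == 0:
            break
        if circ_n >= line_n:  # tie broken toward the richer (arc) model
            mask = circ_cand[1]
            kind = "arc"
        else:
            mask = line_cand[1]
            kind = "line"
        pts = PointSet.from_array(V[mask])
        model = lsqv(pts, params) if kind == "arc" else None
        out.append(Segment(pts=pts, model=model, kind=kind))
        V = V[~mask]
    return out
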