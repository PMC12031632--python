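"""Structure models, least-squares fitting, and the radius-adaptive distance
criterion.

A candidate structure is judged against its support points by the *maximum*
radial deviation (a Chebyshev-style criterion, not an RMS one): a fitted
circle is accepted only if every support point lies within a tolerance band
around it.  The band width scales with the radius — two arcs whose lengths
differ by less than the perceptual ratio λ cannot be told apart, so the
permissible deviation grows as r·λ — clamped between the fixed point
tolerance ``t_dp`` and the minimum distinguishable distance ``k_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

import numpy as np

from .params import DetectorParams

__all__ = [
    "PointSet",
    "LineModel",
    "CircleModel",
    "Segment",
    "DegenerateFitError",
    "fit_line",
    "fit_circle",
    "segment_circle_distance",
    "adaptive_tolerance",
    "lsqv",
]

# relative eigenvalue ratio below which a point cloud is treated as collinear
_COLLINEAR_RTOL = 1e-9


class DegenerateFitError(ValueError):
    """The point configuration does not determine the requested model."""


class PointSet:
    """Ordered set of integer pixel coordinates belonging to one structure.

    Points are ``(x, y)`` pairs with x the column and y the row index,
    0-based.  Duplicates are collapsed; set algebra (union, difference,
    intersection) is available because the suppression and merging stages
    reason about point-set overlap.
    """

    __slots__ = ("_set", "_arr")

    def __init__(self, points: Iterable[Tuple[int, int]]):
        if isinstance(points, PointSet):
            self._set = points._set
            self._arr = points._arr
            return
        self._set = frozenset((int(x), int(y)) for x, y in points)
        self._arr: Optional[np.ndarray] = None

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PointSet":
        return cls(map(tuple, np.asarray(arr, dtype=int)))

    @property
    def array(self) -> np.ndarray:
        """Points as an (n, 2) int array sorted by (x, y); cached."""
        if self._arr is None:
            if self._set:
                self._arr = np.array(sorted(self._set), dtype=np.int64)
            else:
                self._arr = np.empty((0, 2), dtype=np.int64)
        return self._arr

    def __len__(self) -> int:
        return len(self._set)

    def __iter__(self):
        return iter(sorted(self._set))

    def __contains__(self, pt) -> bool:
        return (int(pt[0]), int(pt[1])) in self._set

    def __eq__(self, other) -> bool:
        return isinstance(other, PointSet) and self._set == other._set

    def __hash__(self) -> int:
        return hash(self._set)

    def __or__(self, other: "PointSet") -> "PointSet":
        out = PointSet(())
        out._set = self._set | other._set
        out._arr = None
        return out

    def __sub__(self, other: "PointSet") -> "PointSet":
        out = PointSet(())
        out._set = self._set - other._set
        out._arr = None
        return out

    def __and__(self, other: "PointSet") -> "PointSet":
        out = PointSet(())
        out._set = self._set & other._set
        out._arr = None
        return out

    def issubset(self, other: "PointSet") -> bool:
        return self._set <= other._set

    def min_point_yx(self) -> Tuple[int, int]:
        """Lexicographically smallest point in (y, x) order; tie-break key."""
        if not self._set:
            raise ValueError("empty point set has no minimum point")
        return min((y, x) for x, y in self._set)

    def __repr__(self) -> str:
        return f"PointSet(n={len(self._set)})"


@dataclass(frozen=True)
class LineModel:
    """Line in Hessian normal form nx·x + ny·y + c = 0 with unit normal."""

    nx: float
    ny: float
    c: float
    #: extreme points of the supporting span, projected onto the line
    endpoints: Tuple[Tuple[float, float], Tuple[float, float]] = field(
        default=((0.0, 0.0), (0.0, 0.0))
    )

    def distances(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return np.abs(pts[:, 0] * self.nx + pts[:, 1] * self.ny + self.c)

    @property
    def direction(self) -> Tuple[float, float]:
        return (-self.ny, self.nx)


@dataclass(frozen=True)
class CircleModel:
    """Circle with centre (a, b) and radius r, in pixel coordinates."""

    a: float
    b: float
    r: float

    def __post_init__(self):
        if not (np.isfinite([self.a, self.b, self.r]).all() and self.r > 0):
            raise DegenerateFitError(
                f"invalid circle parameters ({self.a}, {self.b}, {self.r})"
            )

    def radial_deviation(self, pts: np.ndarray) -> np.ndarray:
        """|distance from centre − r| for each point."""
        pts = np.asarray(pts, dtype=float)
        d = np.hypot(pts[:, 0] - self.a, pts[:, 1] - self.b)
        return np.abs(d - self.r)

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.a, self.b, self.r)


@dataclass(eq=False)
class Segment:
    """A point set plus, for arcs, the circle it was validated against.

    Identity semantics (no value equality): the merge stages track library
    entries by object identity while mutating the library in place.
    """

    pts: PointSet
    model: Optional[CircleModel] = None
    kind: str = "arc"  # "line" | "arc"

    def __len__(self) -> int:
        return len(self.pts)


def fit_line(pts: PointSet | np.ndarray) -> LineModel:
    """Total-least-squares line through a point set.

    Minimizes the sum of squared orthogonal distances via the
    eigen-decomposition of the 2×2 scatter matrix; the normal is the
    eigenvector of the smallest eigenvalue.
    """
    arr = pts.array if isinstance(pts, PointSet) else np.asarray(pts, float)
    arr = arr.astype(float)
    if arr.shape[0] < 2:
        raise DegenerateFitError("need at least two points to fit a line")
    centroid = arr.mean(axis=0)
    centered = arr - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0:  # all points coincident
        raise DegenerateFitError("all points coincident; no line defined")
    normal = evecs[:, 0]
    # canonical orientation for determinism
    if (normal[0], normal[1]) < (0.0, 0.0) or (
        normal[0] == 0.0 and normal[1] < 0.0
    ):
        normal = -normal
    nx, ny = float(normal[0]), float(normal[1])
    c = -(nx * centroid[0] + ny * centroid[1])
    # endpoints: extreme projections onto the line direction
    t = centered @ np.array([-ny, nx])
    lo, hi = np.argmin(t), np.argmax(t)
    d = np.array([-ny, nx])
    p_lo = centroid + t[lo] * d
    p_hi = centroid + t[hi] * d
    return LineModel(nx, ny, c, (tuple(p_lo), tuple(p_hi)))


def fit_circle(pts: PointSet | np.ndarray) -> CircleModel:
    """Algebraic least-squares circle (Kåsa fit).

    Solves the linear system in (2a, 2b, r² − a² − b²) that minimizes
    Σ ((x−a)² + (y−b)² − r²)².  Closed-form, deterministic, and exact when
    the points lie exactly on a circle.  Collinear input raises
    :class:`DegenerateFitError` — the caller treats that as "no circle"
    rather than accepting a near-infinite radius.
    """
    arr = pts.array if isinstance(pts, PointSet) else np.asarray(pts, float)
    arr = arr.astype(float)
    n = arr.shape[0]
    if n < 3:
        raise DegenerateFitError("need at least three points to fit a circle")
    centroid = arr.mean(axis=0)
    centered = arr - centroid
    cov = centered.T @ centered
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= _COLLINEAR_RTOL * max(evals[1], 1.0):
        raise DegenerateFitError("points are (near-)collinear; no circle defined")
    # Kåsa in centred coordinates for conditioning
    A = np.column_stack([2.0 * centered, np.ones(n)])
    rhs = (centered**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    ac, bc, c0 = sol
    r2 = c0 + ac**2 + bc**2
    if not np.isfinite(r2) or r2 <= 0:
        raise DegenerateFitError("degenerate circle fit (non-positive radius)")
    return CircleModel(float(ac + centroid[0]), float(bc + centroid[1]), float(np.sqrt(r2)))


def segment_circle_distance(pts: PointSet | np.ndarray, m: CircleModel) -> float:
    """Maximum radial deviation of the points from the circle.

    Zero iff every point lies exactly on the circle.
    """
    arr = pts.array if isinstance(pts, PointSet) else np.asarray(pts, float)
    if arr.shape[0] == 0:
        raise ValueError("distance of an empty point set is undefined")
    return float(m.radial_deviation(arr).max())


def adaptive_tolerance(r: float, params: DetectorParams) -> float:
    """Radius-adaptive segment-to-circle tolerance: r·λ clamped to [t_dp, k_px]."""
    if r <= 0:
        raise ValueError("radius must be positive")
    scaled = r * params.lambda_ratio
    if scaled < params.t_dp:
        return params.t_dp
    if scaled > params.k_px:
        return params.k_px
    return scaled


def lsqv(pts: PointSet | np.ndarray, params: DetectorParams) -> Optional[CircleModel]:
    """Validated circle fit: the model, or ``None`` if the fit misses tolerance.

    Fits the least-squares circle and returns it iff the maximum radial
    deviation of the support points is strictly below the radius-adaptive
    tolerance.  Collinear input yields ``None``.
    """
    try:
        model = fit_circle(pts)
    except DegenerateFitError:
        return None
    d = segment_circle_distance(pts, model)
    if d < adaptive_tolerance(model.r, params):
        return model
    return None
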