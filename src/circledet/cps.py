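"""Circle parameter synthesis: merging candidates in (a, b, r) space.

Candidate circles arriving from hierarchical merging may still be split —
two halves of one physical circle, found far apart in the image, never
meet through endpoint extension but sit next to each other in parameter
space.  Each entry therefore queries its nearest neighbours in (a, b, r)
(kd-tree, unweighted Euclidean distance in pixels), trial-merges the point
sets, and keeps the best validated joint fit.  Passes alternate with
non-maximum suppression until nothing merges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import CircleModel, PointSet, lsqv, segment_circle_distance
from .params import DetectorParams
from .suppression import nms

__all__ = ["CircleEntry", "CircleLibrary", "knn_params", "cps"]

_MAX_LOOPS = 100


@dataclass(eq=False)
class CircleEntry:
    """A candidate circle: support points plus fitted parameters."""

    pts: PointSet
    model: CircleModel


@dataclass
class CircleLibrary:
    """Collection of candidate circles handed to parameter synthesis."""

    entries: List[CircleEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def _sorted_entries(entries: List[CircleEntry]) -> List[CircleEntry]:
    return sorted(entries, key=lambda e: e.model.as_tuple())


def knn_params(
    query: CircleModel, lib: CircleLibrary, k: int
) -> List[CircleEntry]:
    """Up to k nearest library entries to ``query`` in (a, b, r) space.

    Entries whose parameters coincide exactly with the query (in
    particular the query's own entry) are excluded.  Distances are
    unweighted Euclidean over (a, b, r); ties break by parameter order.
    """
    candidates = [
        e for e in _sorted_entries(lib.entries)
        if e.model.as_tuple() != query.as_tuple()
    ]
    if not candidates or k <= 0:
        return []
    coords = np.array([e.model.as_tuple() for e in candidates])
    tree = cKDTree(coords)
    k_eff = min(k, len(candidates))
    _, idx = tree.query(np.array(query.as_tuple()), k=k_eff)
    idx = np.atleast_1d(idx)
    return [candidates[int(i)] for i in idx]


def _best_merge(
    entry: CircleEntry, lib: CircleLibrary, params: DetectorParams
) -> Optional[Tuple[PointSet, CircleModel]]:
    best: Optional[Tuple[PointSet, CircleModel]] = None
    best_d = np.inf
    for nb in knn_params(entry.model, lib, params.knn):
        joint = entry.pts | nb.pts
        model = lsqv(joint, params)
        if model is None:
            continue
        d = segment_circle_distance(joint, model)
        if d < best_d:
            best, best_d = (joint, model), d
    return best


def cps(lib: CircleLibrary, params: DetectorParams) -> CircleLibrary:
    """Aggregate near-duplicate candidate circles until convergence.

    Each pass replaces every entry either by its best validated merge
    with one of its ``knn`` parameter-space neighbours (the joint fit
    with minimum maximum-radial-deviation) or, when no neighbour admits a
    valid joint fit, by itself unchanged; the pass output is then
    suppressed.  The loop repeats while any merge occurred.  The result
    is a fixed point: running the synthesis again returns it unchanged.
    """
    current = _sorted_entries(lib.entries)
    for _ in range(_MAX_LOOPS):
        changed = False
        out: List[CircleEntry] = []
        pool = CircleLibrary(current)
        for entry in current:
            merged = _best_merge(entry, pool, params)
            if merged is not None:
                out.append(CircleEntry(pts=merged[0], model=merged[1]))
                changed = True
            else:
                out.append(entry)
        out = nms(out, params)
        if not changed:
            return CircleLibrary(out)
        current = _sorted_entries(out)
    raise RuntimeError(
        f"circle parameter synthesis did not converge within {_MAX_LOOPS} passes"
    )
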