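"""Non-maximum suppression on point sets.

Overlapping patches (and the merge stages) produce near-duplicate
structures.  Suppression is defined on the *point sets*, not on model
parameters: iteratively keep the largest item and discard every item
whose points outside the survivor number at most K — i.e. items that add
fewer than K novel points carry no perceptually distinguishable extra
evidence.
"""

from __future__ import annotations

from typing import List, Sequence, TypeVar

from .params import DetectorParams

__all__ = ["nms"]

#: anything with a ``pts`` point-set attribute (Segment, circle entries…)
T = TypeVar("T")


def _selection_key(item) -> tuple:
    # larger point sets first; ties by the lexicographically smallest
    # (y, x) point for deterministic, input-order-independent output
    return (-len(item.pts), item.pts.min_point_yx())


def nms(items: Sequence[T], params: DetectorParams) -> List[T]:
    """Suppress near-duplicate structures by point-set difference.

    Repeatedly selects the item with the most points as a survivor and
    retains only items S with \\|S − S*\\| > K remaining points; survivors
    are returned in selection order.  Idempotent, and the largest input
    item always survives.
    """
    for it in items:
        if len(it.pts) == 0:
            raise ValueError("nms items must have nonempty point sets")
    pool = list(items)
    survivors: List[T] = []
    while pool:
        best = min(pool, key=_selection_key)
        survivors.append(best)
        pool = [
            s for s in pool
            if s is not best and len(s.pts - best.pts) > params.k_px
        ]
    return survivors
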