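"""Final validation by arc-length completion ratio.

A candidate circle of radius r supported by |S| edge points has
completion |S| / (2π·r·η), where η ≈ 0.9 is the ratio between the ideal
circumference and its digitized pixel count.  The required completion
decreases with radius — small circles are easy to hallucinate from short
arcs, so they must be nearly complete, while large, partially occluded
circles may pass on a fraction α of their circumference:

    TL(r) = max(tl_max − (tl_max − α) · r·λ/K,  α)

which sweeps from tl_max (as r → 0) down to α (for r ≥ K/λ, 60 px at the
defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .cps import CircleLibrary
from .geometry import CircleModel, PointSet
from .params import DetectorParams

__all__ = ["Detection", "completion_threshold", "filter_circles"]


@dataclass(frozen=True)
class Detection:
    """A validated circle with its support diagnostics."""

    model: CircleModel
    support: int
    completion: float
    threshold: float
    pts: PointSet

    def to_dict(self) -> dict:
        return {
            "a": round(self.model.a, 3),
            "b": round(self.model.b, 3),
            "r": round(self.model.r, 3),
            "support": self.support,
            "completion": round(self.completion, 4),
        }


def completion_threshold(r: float, params: DetectorParams) -> float:
    """Radius-dependent minimum arc-completion fraction.

    Decreasing in r, bounded in [α, tl_max].  The scale factor is
    r·λ/K; setting ``literal_completion`` switches to the alternative
    reading r·K/λ, under which the floor α binds for every radius above
    a pixel (kept only for comparison).
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    if params.literal_completion:
        scale = r * params.k_px / params.lambda_ratio
    else:
        scale = r * params.lambda_ratio / params.k_px
    return max(params.tl_max - (params.tl_max - params.alpha) * scale, params.alpha)


def filter_circles(
    lib: CircleLibrary, params: DetectorParams
) -> List[Detection]:
    """Keep candidates whose completion exceeds the radius-dependent bar."""
    out: List[Detection] = []
    for entry in lib.entries:
        r = entry.model.r
        completion = len(entry.pts) / (2.0 * np.pi * r * params.eta)
        tl = completion_threshold(r, params)
        if completion > tl:
            out.append(
                Detection(
                    model=entry.model,
                    support=len(entry.pts),
                    completion=float(completion),
                    threshold=float(tl),
                    pts=entry.pts,
                )
            )
    return out
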