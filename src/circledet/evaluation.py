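"""Detection scoring: disk IoU, one-to-one matching, PRF, noise sweeps.

A detection counts as a true positive when its disk intersection-over-
union with a ground-truth circle strictly exceeds the threshold (0.8 by
default); matching is one-to-one and greedy by descending IoU, so a
duplicate detection of an already-matched circle becomes a false
positive.  The noise protocol adds zero-mean Gaussian noise of standard
deviation σ (on the [0, 1] intensity scale, clipped back to [0, 1]),
re-runs the full detector, and averages Recall/Fscore over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .arc_filter import Detection
from .geometry import CircleModel
from .params import DetectorParams
from .synthetic import SyntheticScene, add_noise

__all__ = [
    "EvalReport",
    "MatchRecord",
    "circle_iou",
    "match",
    "noise_sweep",
    "summarize_sweep",
]


def _intersection_area(r1: float, r2: float, d: float) -> float:
    """Area of the lens where two disks of radii r1, r2 at distance d overlap."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rm = min(r1, r2)
        return np.pi * rm * rm
    # circular-segment decomposition of the lens
    d1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    d2 = d - d1
    seg1 = r1 * r1 * np.arccos(np.clip(d1 / r1, -1, 1)) - d1 * np.sqrt(
        max(r1 * r1 - d1 * d1, 0.0)
    )
    seg2 = r2 * r2 * np.arccos(np.clip(d2 / r2, -1, 1)) - d2 * np.sqrt(
        max(r2 * r2 - d2 * d2, 0.0)
    )
    return seg1 + seg2


def circle_iou(m1: CircleModel, m2: CircleModel) -> float:
    """Exact intersection-over-union of two disks (closed form).

    Symmetric, in [0, 1]; 1 iff the circles coincide, 0 iff the disks are
    disjoint.
    """
    d = float(np.hypot(m1.a - m2.a, m1.b - m2.b))
    inter = _intersection_area(m1.r, m2.r, d)
    union = np.pi * (m1.r**2 + m2.r**2) - inter
    return float(inter / union)


@dataclass(frozen=True)
class MatchRecord:
    detection: CircleModel
    matched_gt: Optional[CircleModel]
    iou: float


@dataclass
class EvalReport:
    """TP/FP/FN counts with precision, recall and Fscore."""

    tp: int
    fp: int
    fn: int
    matches: List[MatchRecord] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _as_model(obj) -> CircleModel:
    return obj.model if isinstance(obj, Detection) else obj


def match(
    dets: Sequence[Detection | CircleModel],
    gts: Sequence[CircleModel],
    iou_threshold: float = 0.8,
) -> EvalReport:
    """Greedy one-to-one matching of detections to ground-truth circles.

    Pairs are considered in order of descending IoU; a detection is a
    true positive when matched with IoU strictly above the threshold.
    Surplus detections of one circle are false positives; unmatched
    ground truths are false negatives.
    """
    if not (0 < iou_threshold < 1):
        raise ValueError("iou_threshold must be in (0, 1)")
    models = [_as_model(d) for d in dets]
    pairs = []
    for i, dm in enumerate(models):
        for j, g in enumerate(gts):
            iou = circle_iou(dm, g)
            if iou > iou_threshold:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    det_used = [False] * len(models)
    gt_used = [False] * len(gts)
    records: List[MatchRecord] = []
    for iou, i, j in pairs:
        if det_used[i] or gt_used[j]:
            continue
        det_used[i] = True
        gt_used[j] = True
        records.append(MatchRecord(models[i], gts[j], iou))
    for i, dm in enumerate(models):
        if not det_used[i]:
            best = max((circle_iou(dm, g) for g in gts), default=0.0)
            records.append(MatchRecord(dm, None, best))
    tp = sum(det_used)
    fp = len(models) - tp
    fn = len(gts) - sum(gt_used)
    return EvalReport(tp=tp, fp=fp, fn=fn, matches=records)


def noise_sweep(
    scene: SyntheticScene,
    params: DetectorParams,
    sigmas: Sequence[float],
    reps: int = 10,
) -> pd.DataFrame:
    """Noise-robustness protocol on one scene.

    For each noise level σ and repetition, adds zero-mean Gaussian noise
    (std σ on the [0, 1] scale, clipped), runs the full detector, and
    scores against the scene's ground truth.  Per-(σ, rep) noise and
    detector seeds derive from ``params.rng_seed`` and are independent of
    the number of repetitions requested, so rep k is reproducible on its
    own.  Returns one row per (σ, rep).
    """
    from .pipeline import detect_circles

    if reps < 1:
        raise ValueError("reps must be at least 1")
    rows = []
    for si, sigma in enumerate(sigmas):
        if not (0 <= sigma <= 1):
            raise ValueError("sigma values must be in [0, 1]")
        for rep in range(reps):
            ss = np.random.SeedSequence(
                [int(params.rng_seed), 7919, si, rep]
            )
            noise_seed, det_seed = ss.generate_state(2) % (2**31)
            noisy = add_noise(scene.image, sigma, int(noise_seed))
            dets = detect_circles(
                noisy, params.replace(rng_seed=int(det_seed))
            )
            report = match(dets, scene.gts, params.iou_threshold)
            rows.append(
                {
                    "sigma": sigma,
                    "rep": rep,
                    "tp": report.tp,
                    "fp": report.fp,
                    "fn": report.fn,
                    "precision": report.precision,
                    "recall": report.recall,
                    "fscore": report.fscore,
                }
            )
    return pd.DataFrame(rows)


def summarize_sweep(detail: pd.DataFrame) -> pd.DataFrame:
    """Per-σ means of recall and Fscore from a noise-sweep detail table."""
    return (
        detail.groupby("sigma", as_index=False)[["recall", "fscore"]]
        .mean()
        .rename(columns={"recall": "mean_recall", "fscore": "mean_fscore"})
    )
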