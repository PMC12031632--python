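"""End-to-end detector: edges → patch RANSAC → merging → synthesis → filter."""

from __future__ import annotations

import logging
import time
from typing import List, Optional

import numpy as np

from .arc_filter import Detection, filter_circles
from .cps import CircleEntry, CircleLibrary, cps
from .edges import EdgeMap, detect_edges, thin
from .hs import SegmentLibrary, hs
from .params import DetectorParams
from .prc import extract_structures, partition
from .suppression import nms

__all__ = ["detect_circles", "to_grayscale"]

logger = logging.getLogger("circledet")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Accept single-channel or RGB(A) rasters; return float luminance in [0, 1]."""
    img = np.asarray(image)
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[:, :, :3]
        img = img @ np.array([0.2125, 0.7154, 0.0721])
    img = img.astype(float)
    if img.size and img.max() > 1.0:
        img = img / 255.0
    return img


def detect_circles(
    image: Optional[np.ndarray],
    params: Optional[DetectorParams] = None,
    edge_map: Optional[np.ndarray | EdgeMap] = None,
) -> List[Detection]:
    """Detect circles in a grayscale image (or a precomputed edge map).

    Stages: edge extraction (skipped when ``edge_map`` is given; the
    supplied map is thinned), patch partitioning, per-patch RANSAC
    structure extraction with patch-local seeding, point-set suppression,
    hierarchical segment merging, circle-parameter synthesis, and the
    arc-completion filter.  Deterministic for fixed inputs and seed.
    """
    params = params or DetectorParams()
    t0 = time.perf_counter()
    if edge_map is None:
        if image is None:
            raise ValueError("either an image or an edge map is required")
        em = detect_edges(to_grayscale(image))
    else:
        em = thin(edge_map)
    logger.info("edges: %d points (%.3fs)", em.n_on, time.perf_counter() - t0)

    t0 = time.perf_counter()
    patches = partition(em, params)
    segments = []
    for p in patches:
        if len(p) > params.m_min:
            segments.extend(
                extract_structures(p, params, params.patch_rng(p.x0, p.y0))
            )
    logger.info(
        "prc: %d segments from %d patches (%.3fs)",
        len(segments), len(patches), time.perf_counter() - t0,
    )
    if not segments:
        return []

    t0 = time.perf_counter()
    segments = nms(segments, params)
    lib = hs(SegmentLibrary(segments), params)
    logger.info("hs: %d candidates (%.3fs)", len(lib), time.perf_counter() - t0)

    t0 = time.perf_counter()
    circle_lib = CircleLibrary(
        [CircleEntry(pts=s.pts, model=s.model) for s in lib.entries if s.model]
    )
    circle_lib = cps(circle_lib, params)
    detections = filter_circles(circle_lib, params)
    logger.info(
        "cps+filter: %d detections (%.3fs)",
        len(detections), time.perf_counter() - t0,
    )
    return detections
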