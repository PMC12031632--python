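"""Detector configuration.

Every tunable constant of the detector lives in :class:`DetectorParams`;
no other module hard-codes a numeric threshold.  The two *perceptual*
parameters are

``lambda_ratio``
    the minimum length-difference discrimination ratio λ: two structures
    whose lengths differ by less than a fraction λ are perceptually
    indistinguishable, which makes the circle-distance tolerance scale
    with radius,
``k_px``
    the minimum distinguishable pixel distance K: point pairs closer
    than K carry no independent geometric information.

All remaining constants (patch geometry, RANSAC confidence, arc-completion
bounds) are derived from, or calibrated against, these two and are stored
explicitly with their standard defaults.
"""

from __future__ import annotations

import dataclasses
import io
import pathlib
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import yaml

__all__ = ["DetectorParams", "ParameterError", "load_params"]


class ParameterError(ValueError):
    """A configuration value violates its documented range."""


@dataclass(frozen=True)
class DetectorParams:
    """Validated bundle of all detector constants.

    Parameters
    ----------
    lambda_ratio : float
        Perceptual length-difference discrimination ratio λ (dimensionless).
    k_px : float
        Minimum distinguishable distance K, in pixels.
    patch_size : int
        Side length L of the square patches tiling the edge map, pixels.
    patch_stride : int
        Stride S between patch origins, pixels.  The defaults give 50%
        overlap between adjacent patches.
    m_min : int
        Minimum number of support points for an accepted structure.
    p_f : float
        Desired probability that RANSAC finds a planted structure.
    t_dp : float
        Point-to-model inlier tolerance, pixels.
    alpha : float
        Minimum arc-completion threshold (floor of the radius-dependent
        completion requirement).
    tl_max : float
        Ceiling of the arc-completion threshold, approached as r → 0.
    eta : float
        Ratio between ideal and digitized circle circumferences.
    iou_threshold : float
        Disk IoU above which a detection matches a ground-truth circle.
    n_max : int
        Hard cap on the adaptive RANSAC iteration count.
    knn : int
        Number of nearest neighbours examined in circle-parameter space.
    literal_completion : bool
        Use the alternative completion-threshold reading r·K/λ instead of
        r·λ/K (see :func:`circledet.arc_filter.completion_threshold`).
    rng_seed : int
        Seed for all stochastic stages.
    """

    lambda_ratio: float = 0.05
    k_px: float = 3.0
    patch_size: int = 32
    patch_stride: int = 16
    m_min: int = 16
    p_f: float = 0.99
    t_dp: float = 1.0
    alpha: float = 0.3
    tl_max: float = 0.9
    eta: float = 0.9
    iou_threshold: float = 0.8
    n_max: int = 100_000
    knn: int = 5
    literal_completion: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.lambda_ratio < 1, "lambda_ratio", "must be in (0, 1)"),
            (self.k_px > 0, "k_px", "must be positive"),
            (0 < self.p_f < 1, "p_f", "must be in (0, 1)"),
            (0 < self.alpha <= self.tl_max, "alpha",
             "must be in (0, tl_max]"),
            (0 < self.tl_max <= 1, "tl_max", "must be in (0, 1]"),
            (0 < self.eta <= 1, "eta", "must be in (0, 1]"),
            (0 < self.iou_threshold < 1, "iou_threshold",
             "must be in (0, 1)"),
            (self.patch_stride > 0, "patch_stride", "must be positive"),
            (self.patch_stride <= self.patch_size, "patch_stride",
             "must not exceed patch_size"),
            (self.t_dp > 0, "t_dp", "must be positive"),
            (self.t_dp <= self.k_px, "t_dp",
             "must not exceed k_px (tolerance clamp must be ordered)"),
            (self.m_min >= 3, "m_min",
             "must be at least 3 (a circle needs three support points)"),
            (self.n_max >= 1, "n_max", "must be at least 1"),
            (self.knn >= 1, "knn", "must be at least 1"),
        ]
        for ok, field, msg in checks:
            if not ok:
                raise ParameterError(f"{field}: {msg} (got {getattr(self, field)!r})")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **overrides) -> "DetectorParams":
        return dataclasses.replace(self, **overrides)

    def rng(self) -> np.random.Generator:
        """Root random generator for a detector run."""
        return np.random.default_rng(self.rng_seed)

    def patch_rng(self, x0: int, y0: int) -> np.random.Generator:
        """Per-patch generator, reproducible independently of patch order."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.rng_seed), int(x0), int(y0)])
        )


ConfigSource = Union[None, str, pathlib.Path, Mapping, io.IOBase]

_FIELDS = {f.name: f for f in dataclasses.fields(DetectorParams)}


def load_params(config_source: ConfigSource = None, **overrides) -> DetectorParams:
    """Build a :class:`DetectorParams` from defaults plus optional overrides.

    ``config_source`` may be absent, a mapping, a YAML file path, or an
    open stream of flat ``key: value`` pairs.  Keyword overrides are
    applied after the config source.  Unknown keys and out-of-range
    values raise :class:`ParameterError`.
    """
    values: dict = {}
    if config_source is not None:
        if isinstance(config_source, Mapping):
            values.update(config_source)
        else:
            if isinstance(config_source, (str, pathlib.Path)):
                text = pathlib.Path(config_source).read_text()
            else:
                text = config_source.read()
            loaded = yaml.safe_load(text)
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, Mapping):
                raise ParameterError(
                    "config must be a flat mapping of parameter names to values"
                )
            values.update(loaded)
    values.update(overrides)

    kwargs = {}
    for key, raw in values.items():
        name = key.replace("-", "_")
        if name not in _FIELDS:
            raise ParameterError(f"unknown parameter {key!r}")
        target = _FIELDS[name].type
        try:
            if target == "int":
                coerced = int(raw)
            elif target == "float":
                coerced = float(raw)
            elif target == "bool":
                coerced = bool(raw)
            else:
                coerced = raw
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"{key}: not parseable as {target}: {raw!r}") from exc
        kwargs[name] = coerced
    return DetectorParams(**kwargs)
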