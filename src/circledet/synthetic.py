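"""Synthetic scenes with exactly known circle ground truth.

The generator emulates the kind of material the detector targets —
rasterized full and partial circles (radius ≈ 10–100 px) over a uniform
background, with occluding bars, straight-line clutter, varying contrast,
and additive Gaussian noise on a [0, 1] intensity scale.  Every rendered
circle is recorded in the ground-truth list, so precision/recall scoring
needs no manual annotation.

Rendering is anti-aliased by default (real edges are soft); a binary
switch produces exact midpoint rasterization for digitization-constant
checks.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import CircleModel

__all__ = [
    "SyntheticScene",
    "SceneGenerationError",
    "rasterize_circle",
    "render_scene",
    "add_noise",
    "default_fixture_suite",
    "save_scene",
]


class SceneGenerationError(RuntimeError):
    """Requested circles could not be placed without overlap."""


@dataclass
class SyntheticScene:
    """A rendered image plus its exact circle ground truth."""

    image: np.ndarray  # float in [0, 1], shape (H, W)
    gts: List[CircleModel]
    occluders: List[dict] = field(default_factory=list)
    seed: Optional[int] = None

    @property
    def shape(self) -> Tuple[int, int]:
        return self.image.shape


def rasterize_circle(a: int, b: int, r: int) -> np.ndarray:
    """Midpoint (Bresenham-style octant) rasterization of a circle perimeter.

    Returns the distinct perimeter pixels as an (n, 2) array of (x, y).
    The pixel count divided by the ideal circumference 2πr sits near 0.9
    for the radii of interest — the digitization constant η.
    """
    pts = set()
    x, y, d = 0, int(r), 1 - int(r)
    while x <= y:
        for px, py in ((x, y), (y, x)):
            for sx in (px, -px):
                for sy in (py, -py):
                    pts.add((a + sx, b + sy))
        x += 1
        if d < 0:
            d += 2 * x + 1
        else:
            y -= 1
            d += 2 * (x - y) + 1
    return np.array(sorted(pts), dtype=np.int64)


def _disk_alpha(h: int, w: int, a: float, b: float, r: float,
                antialias: bool) -> Tuple[slice, slice, np.ndarray]:
    """Coverage of a filled disk over its bounding box (soft 1-px edge)."""
    pad = 2
    x0, x1 = max(0, int(a - r) - pad), min(w, int(a + r) + pad + 1)
    y0, y1 = max(0, int(b - r) - pad), min(h, int(b + r) + pad + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xs - a, ys - b)
    if antialias:
        alpha = np.clip(r + 0.5 - d, 0.0, 1.0)
    else:
        alpha = (d <= r + 0.5).astype(float)
    return slice(y0, y1), slice(x0, x1), alpha


def _ring_alpha(h: int, w: int, a: float, b: float, r: float,
                antialias: bool) -> Tuple[slice, slice, np.ndarray]:
    """Coverage of a thin circular stroke (≈2 px wide) centred on radius r."""
    pad = 3
    x0, x1 = max(0, int(a - r) - pad), min(w, int(a + r) + pad + 1)
    y0, y1 = max(0, int(b - r) - pad), min(h, int(b + r) + pad + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xs - a, ys - b)
    if antialias:
        alpha = np.clip(1.0 - np.abs(d - r), 0.0, 1.0)
    else:
        alpha = (np.abs(d - r) <= 0.5).astype(float)
    return slice(y0, y1), slice(x0, x1), alpha


def _blend(image: np.ndarray, sl: Tuple[slice, slice], alpha: np.ndarray,
           value: float) -> None:
    region = image[sl]
    image[sl] = region * (1.0 - alpha) + value * alpha


def _paint_occluder(image: np.ndarray, circle: CircleModel, fraction: float,
                    angle: float, value: float) -> dict:
    """Cover ``fraction`` of the circle's circumference with a bar.

    The bar is the circular cap beyond the chord at angular half-width
    θ = π·fraction around direction ``angle``, padded by a small margin so
    the boundary underneath is fully hidden.
    """
    theta = np.pi * float(fraction)
    u = np.array([np.cos(angle), np.sin(angle)])
    v = np.array([-u[1], u[0]])
    margin = 3.0
    h, w = image.shape
    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - circle.a, ys - circle.b
    du = dx * u[0] + dy * u[1]
    dv = dx * v[0] + dy * v[1]
    r = circle.r
    mask = (
        (du >= r * np.cos(theta))
        & (du <= r + margin)
        & (np.abs(dv) <= r * np.sin(theta) + margin)
    )
    image[mask] = value
    return {
        "circle": circle.as_tuple(),
        "fraction": float(fraction),
        "angle": float(angle),
        "value": float(value),
    }


def _draw_line(image: np.ndarray, p0: Tuple[float, float],
               p1: Tuple[float, float], value: float,
               antialias: bool = True) -> None:
    from skimage.draw import line as _line, line_aa

    h, w = image.shape
    r0, c0 = int(round(p0[1])), int(round(p0[0]))
    r1, c1 = int(round(p1[1])), int(round(p1[0]))
    if antialias:
        rr, cc, val = line_aa(r0, c0, r1, c1)
    else:
        rr, cc = _line(r0, c0, r1, c1)
        val = np.ones(len(rr))
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc, val = rr[keep], cc[keep], val[keep]
    image[rr, cc] = image[rr, cc] * (1 - val) + value * val


def _place_circles(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    n_circles: int,
    radius_range: Tuple[float, float],
    min_gap: float = 8.0,
    max_attempts: int = 1000,
) -> List[CircleModel]:
    # circles are placed inside the detector's patch-covered field of
    # view: a border strip narrower than the patch stride can fall outside
    # every admissible patch, and a fixture circle leaking into it would
    # not be fully observable by construction
    from .params import DetectorParams
    from .prc import covered_extent

    h, w = covered_extent(shape, DetectorParams())
    placed: List[CircleModel] = []
    for _ in range(n_circles):
        for attempt in range(max_attempts):
            r = float(rng.uniform(*radius_range))
            margin = r + 4.0
            if 2 * margin >= min(h, w):
                continue
            a = float(rng.uniform(margin, w - margin))
            b = float(rng.uniform(margin, h - margin))
            if all(
                np.hypot(a - c.a, b - c.b) >= r + c.r + min_gap for c in placed
            ):
                placed.append(CircleModel(a, b, r))
                break
        else:
            raise SceneGenerationError(
                f"could not place circle {len(placed) + 1}/{n_circles}; "
                "try fewer or smaller circles"
            )
    return placed


def render_scene(
    shape: Tuple[int, int] = (300, 400),
    n_circles: int = 5,
    radius_range: Tuple[float, float] = (15.0, 60.0),
    rng: np.random.Generator | int | None = 0,
    style: str = "disk",  # "disk" (filled) or "ring" (stroked outline)
    background: float = 0.85,
    foreground: float = 0.15,
    occlusion: float = 0.0,
    occluder_value: float = 0.5,
    n_clutter_lines: int = 0,
    clutter_value: float = 0.35,
    concentric: int = 0,
    antialias: bool = True,
    circles: Optional[Sequence[CircleModel]] = None,
) -> SyntheticScene:
    """Render a scene of circles with exactly known ground truth.

    Parameters
    ----------
    shape : (height, width) of the image.
    n_circles : number of circles to place (ignored when ``circles`` given).
    radius_range : sampling range for radii, pixels.
    rng : seed or generator; identical seeds give byte-identical scenes.
    style : "disk" renders filled disks (one boundary edge per circle);
        "ring" renders a thin stroked outline.
    occlusion : fraction of each circle's circumference hidden by a bar.
    concentric : if > 0, each placed circle gains this many concentric
        rings (the scene is forced to ring style for the group).
    circles : explicit ground-truth circles, bypassing random placement.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h, w = shape
    image = np.full((h, w), float(background))

    if circles is not None:
        gts = list(circles)
    else:
        gts = _place_circles(gen, shape, n_circles, radius_range)

    # (circle, paint value) in render order; concentric groups become
    # nested filled disks of alternating intensity (each ground-truth
    # circle is then exactly one step edge, as in real ring structures)
    to_render = [(c, float(foreground)) for c in gts]
    if concentric > 0:
        nested = []
        for c, _ in to_render:
            for i in range(concentric):
                ri = c.r * (0.55 ** (i + 1))
                if ri >= 10.0:
                    value = background if i % 2 == 0 else foreground
                    nested.append((CircleModel(c.a, c.b, ri), float(value)))
        to_render = to_render + nested
        gts = [c for c, _ in to_render]

    for c, value in to_render:
        if style == "ring":
            sl_y, sl_x, alpha = _ring_alpha(h, w, c.a, c.b, c.r, antialias)
        else:
            sl_y, sl_x, alpha = _disk_alpha(h, w, c.a, c.b, c.r, antialias)
        _blend(image, (sl_y, sl_x), alpha, value)

    occluders: List[dict] = []
    if occlusion > 0:
        for c in gts:
            angle = float(gen.uniform(0, 2 * np.pi))
            occluders.append(
                _paint_occluder(image, c, occlusion, angle, occluder_value)
            )

    for _ in range(n_clutter_lines):
        p0 = (float(gen.uniform(0, w)), float(gen.uniform(0, h)))
        ang = float(gen.uniform(0, np.pi))
        length = float(gen.uniform(40, max(h, w)))
        p1 = (p0[0] + length * np.cos(ang), p0[1] + length * np.sin(ang))
        _draw_line(image, p0, p1, clutter_value, antialias)

    np.clip(image, 0.0, 1.0, out=image)
    return SyntheticScene(image=image, gts=gts, occluders=occluders, seed=seed)


def add_noise(image: np.ndarray, sigma: float,
              rng: np.random.Generator | int | None) -> np.ndarray:
    """Additive zero-mean Gaussian noise of std ``sigma``, clipped to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    noisy = image + gen.normal(0.0, sigma, size=image.shape) if sigma > 0 else image.copy()
    return np.clip(noisy, 0.0, 1.0)


def default_fixture_suite() -> List[SyntheticScene]:
    """Deterministic 12-scene suite covering the scene families of interest.

    Four clean multi-circle scenes, two occlusion scenes, two concentric
    ring scenes, two straight-line clutter scenes, and two low-contrast
    bright-disk scenes in the style of microscopy colonies/droplets.
    All scenes are 400×300 with radii in [15, 60].
    """
    scenes: List[SyntheticScene] = []
    # clean multi-circle
    for i, n in enumerate((3, 4, 6, 8)):
        scenes.append(render_scene(n_circles=n, rng=101 + i))
    # occlusion (large circles so the completion criterion still passes)
    for i in range(2):
        scenes.append(
            render_scene(
                n_circles=2, radius_range=(50.0, 60.0), occlusion=0.3,
                rng=201 + i,
            )
        )
    # concentric (nested annuli)
    for i in range(2):
        scenes.append(
            render_scene(
                n_circles=2, radius_range=(40.0, 60.0), concentric=1,
                rng=301 + i,
            )
        )
    # straight-line clutter
    for i in range(2):
        scenes.append(
            render_scene(n_circles=4, n_clutter_lines=6, rng=401 + i)
        )
    # microscopy flavour: bright low-contrast disks on a dark field
    for i in range(2):
        scenes.append(
            render_scene(
                n_circles=5, radius_range=(15.0, 40.0), background=0.2,
                foreground=0.5, rng=501 + i,
            )
        )
    return scenes


def save_scene(scene: SyntheticScene, png_path, json_path) -> None:
    """Write the image as 8-bit PNG and the ground truth as JSON."""
    from PIL import Image

    arr = np.round(scene.image * 255).astype(np.uint8)
    Image.fromarray(arr).save(pathlib.Path(png_path))
    payload = {
        "seed": scene.seed,
        "circles": [
            {"a": c.a, "b": c.b, "r": c.r} for c in scene.gts
        ],
        "occluders": scene.occluders,
    }
    pathlib.Path(json_path).write_text(json.dumps(payload, indent=2))
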