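import numpy as np
import pytest

from circledet import DetectorParams, detect_circles, render_scene
from circledet.geometry import PointSet
from circledet.synthetic import rasterize_circle


@pytest.fixture(scope="session")
def params():
    return DetectorParams(rng_seed=1)


@pytest.fixture(scope="session")
def clean_scene():
    """Five clean filled circles on a 400x300 canvas."""
    return render_scene(n_circles=5, rng=101)


@pytest.fixture(scope="session")
def clean_detections(clean_scene, params):
    return detect_circles(clean_scene.image, params)


def arc_points(a: float, b: float, r: float, theta0: float, theta1: float) -> PointSet:
    """Digitized arc: midpoint-rasterized circle restricted to [theta0, theta1]."""
    pts = rasterize_circle(int(round(a)), int(round(b)), int(round(r)))
    if theta1 - theta0 >= 2 * np.pi - 1e-9:
        return PointSet.from_array(pts)
    ang = np.mod(np.arctan2(pts[:, 1] - b, pts[:, 0] - a), 2 * np.pi)
    lo, hi = np.mod(theta0, 2 * np.pi), np.mod(theta1, 2 * np.pi)
    if lo <= hi:
        keep = (ang >= lo) & (ang <= hi)
    else:
        keep = (ang >= lo) | (ang <= hi)
    return PointSet.from_array(pts[keep])
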