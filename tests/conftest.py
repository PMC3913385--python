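import numpy as np
import pytest

from plaquantify import FluorescenceImage, PolygonROI


@pytest.fixture
def rng():
    return np.random.default_rng(20140105)


@pytest.fixture
def random_image(rng):
    def make(h=32, w=32, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return FluorescenceImage(r.integers(0, 256, (h, w, 3), dtype=np.uint8))

    return make


def star_polygon(rng, h, w, n_vertices=None, tooth_id="11"):
    """Random star-shaped (hence simple) polygon inside an h x w image."""
    n = n_vertices or int(rng.integers(4, 10))
    cx = rng.uniform(0.3 * w, 0.7 * w)
    cy = rng.uniform(0.3 * h, 0.7 * h)
    # jittered regular spacing keeps every angular gap below pi, which
    # guarantees the radial polygon is simple
    angles = (np.arange(n) + rng.uniform(0.05, 0.95, n)) * (2 * np.pi / n)
    radii = rng.uniform(0.1, 0.45) * min(h, w) * rng.uniform(0.4, 1.0, n)
    xs = np.clip(cx + radii * np.cos(angles), 0, w)
    ys = np.clip(cy + radii * np.sin(angles), 0, h)
    return PolygonROI(list(zip(xs, ys)), tooth_id=tooth_id)


def point_in_polygon(px, py, vertices):
    """Scalar even-odd (ray-crossing) point-in-polygon test: the
    independent oracle for rasterization."""
    inside = False
    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside
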