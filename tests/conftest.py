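"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest

from cardioflow import Contour, ImageStack


def point_in_polygon(x: float, y: float, verts: np.ndarray) -> bool:
    """Independent even-odd (crossing number) test with on-edge = inside.

    Deliberately written from scratch so the package's shapely-based
    rasterization can be checked against it.
    """
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
                return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xint:
                inside = not inside
    return inside


def brute_force_mask(contour: Contour, shape) -> np.ndarray:
    """Exhaustive pixel-center test over the whole image."""
    rows, cols = shape
    mask = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            mask[r, c] = point_in_polygon(c, r, contour.vertices)
    return mask


def random_star_polygon(rng, n_vertices=None, r_min=1.0, r_max=8.0,
                        center_box=(5.0, 25.0)) -> Contour:
    """A random star-shaped (hence simple) polygon."""
    n = n_vertices or int(rng.integers(4, 14))

    def gaps_ok(a):
        d = np.diff(np.append(a, a[0] + 2 * np.pi))
        # distinct angles, and no gap over pi (else the polygon need not be
        # star-shaped about the center and edges can cross)
        return d.min() > 1e-3 and d.max() < np.pi

    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    while not gaps_ok(angles):
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(r_min, r_max, n)
    cx, cy = rng.uniform(*center_box, 2)
    verts = np.stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)], axis=1)
    return Contour(verts)


def uniform_stack(value=0.5, shape=(16, 16), frames=1, **kw) -> ImageStack:
    vox = np.full(shape + (1, frames), value)
    kw.setdefault("pixel_spacing_mm", (1.0, 1.0))
    kw.setdefault("slice_thickness_mm", 8.0)
    if frames > 1:
        kw.setdefault("time_increment_s", 0.05)
    return ImageStack(vox, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
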