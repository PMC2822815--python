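"""Double-precision contour geometry.

Contours are closed polygons with sub-pixel vertices kept at full double
precision; all quantification (areas, masks, distances) happens on the
continuous polygon, and pixels are only involved where intensities live.
Vertices are ``(x, y)`` pairs in pixel units, ``x`` along columns and
``y`` along rows, matching the package-wide rule that a pixel's center is
at integer ``(row, col)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon

from .stack import ImageStack

__all__ = [
    "Contour",
    "PointPair",
    "AnnotationPoint",
    "polygon_area",
    "rasterize",
    "euclidean_distance",
    "resample",
    "mpr_slice",
]


@dataclass
class Contour:
    """An ordered, implicitly closed polygon at double precision.

    Orientation is normalized to counter-clockwise on construction and
    self-intersecting rings are rejected.
    """

    vertices: np.ndarray  # (n, 2) float64, columns (x, y)
    slice_index: int = 0
    frame_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a contour needs at least 3 (x, y) vertices")
        ring = _ShapelyPolygon(v)
        if not ring.is_valid:
            raise ValueError("contour is self-intersecting or degenerate")
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v

    @property
    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    # -- JSON round trip ---------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "slice": int(self.slice_index),
            "frame": int(self.frame_index),
            "vertices": self.vertices.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "Contour":
        return cls(
            vertices=np.asarray(d["vertices"], dtype=np.float64),
            slice_index=int(d.get("slice", 0)),
            frame_index=int(d.get("frame", 0)),
            label=d.get("label", ""),
        )

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + np.array([dx, dy]), self.slice_index,
                       self.frame_index, self.label)


@dataclass
class PointPair:
    """Two sub-pixel points for a linear measurement."""

    p1: tuple
    p2: tuple


@dataclass
class AnnotationPoint:
    """A labelled sub-pixel position, optionally time-resolved."""

    position: tuple  # (x, y, slice)
    frame: int | None = None
    label: str = ""


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(contour: Contour, pixel_spacing_mm=(1.0, 1.0)) -> float:
    """Shoelace polygon area in mm², with anisotropic pixel scaling.

    ``pixel_spacing_mm`` is ``(row, col)``: the y coordinate scales by the
    row spacing and x by the column spacing.
    """
    sy, sx = float(pixel_spacing_mm[0]), float(pixel_spacing_mm[1])
    v = contour.vertices * np.array([sx, sy])
    area = abs(_signed_area(v))
    if area <= 0:
        raise ValueError("polygon area is not strictly positive")
    return area


def rasterize(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose center lies inside the polygon.

    Pixel centers exactly on an edge count as inside (even-odd rule with
    inclusive boundary), which makes axis-aligned test shapes
    deterministic.
    """
    rows, cols = int(shape[0]), int(shape[1])
    mask = np.zeros((rows, cols), dtype=bool)
    v = contour.vertices
    r0 = max(int(np.floor(v[:, 1].min())), 0)
    r1 = min(int(np.ceil(v[:, 1].max())), rows - 1)
    c0 = max(int(np.floor(v[:, 0].min())), 0)
    c1 = min(int(np.ceil(v[:, 0].max())), cols - 1)
    if r1 < r0 or c1 < c0:
        warnings.warn("contour lies fully outside the image; mask is empty")
        return mask
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    poly = contour.polygon
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel()).reshape(rr.shape)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    if not mask.any():
        # Inside the image but no pixel center falls in the polygon.
        warnings.warn("contour encloses no pixel centers")
    return mask


def euclidean_distance(pair: PointPair, pixel_spacing_mm=(1.0, 1.0),
                       slice_step_mm: float = 0.0) -> float:
    """Physical L2 distance of a point pair, in-plane or across slices."""
    sy, sx = float(pixel_spacing_mm[0]), float(pixel_spacing_mm[1])
    p1 = np.asarray(pair.p1, dtype=np.float64)
    p2 = np.asarray(pair.p2, dtype=np.float64)
    if p1.shape != p2.shape:
        raise ValueError("points must have the same dimensionality")
    d = p2 - p1
    scale = np.array([sx, sy, slice_step_mm][: d.size])
    return float(np.linalg.norm(d * scale))


# -- resampling ------------------------------------------------------------

def _keys_weights(t: np.ndarray) -> np.ndarray:
    """Catmull-Rom (Keys, a = -1/2) cubic weights for the 4-tap stencil."""
    a = -0.5
    w = np.empty((4,) + t.shape)
    for k, off in enumerate((-1.0, 0.0, 1.0, 2.0)):
        s = np.abs(t - off)
        w[k] = np.where(
            s <= 1.0,
            (a + 2) * s**3 - (a + 3) * s**2 + 1,
            np.where(s < 2.0, a * s**3 - 5 * a * s**2 + 8 * a * s - 4 * a, 0.0),
        )
    return w


def _cubic_resample_axis(arr: np.ndarray, axis: int, n_out: int) -> np.ndarray:
    """Separable cubic resampling along one axis, endpoints aligned.

    The array is padded with two linearly extrapolated samples per side so
    the interpolator reproduces affine signals exactly up to and including
    the borders.
    """
    arr = np.moveaxis(arr, axis, 0)
    n_in = arr.shape[0]
    if n_in == 1:
        out = np.repeat(arr, n_out, axis=0)
        return np.moveaxis(out, 0, axis)
    u = np.linspace(0.0, n_in - 1.0, n_out)
    first = arr[0] + np.multiply.outer(np.array([-2.0, -1.0]), arr[1] - arr[0])
    last = arr[-1] + np.multiply.outer(np.array([1.0, 2.0]), arr[-1] - arr[-2])
    padded = np.concatenate([first, arr, last], axis=0)
    i0 = np.floor(u).astype(int)
    i0 = np.clip(i0, 0, n_in - 2)
    t = u - i0
    w = _keys_weights(t)  # (4, n_out)
    out = np.zeros((n_out,) + arr.shape[1:])
    for k in range(4):
        idx = i0 + k + 1  # +2 pad offset, -1 stencil start
        out += w[k].reshape((-1,) + (1,) * (arr.ndim - 1)) * padded[idx]
    return np.moveaxis(out, 0, axis)


def resample(stack: ImageStack, factor: float) -> ImageStack:
    """In-plane resampling by ``factor`` with bicubic interpolation.

    Upsampling uses a separable Keys bicubic kernel; downsampling first
    applies a Gaussian anti-alias filter with sigma = 0.5*(ratio - 1) per
    axis.  Pixel spacing is updated so the physical extent of the pixel
    -center grid is preserved exactly.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    n_r = int(round(stack.rows * factor))
    n_c = int(round(stack.cols * factor))
    if n_r < 2 or n_c < 2:
        raise ValueError("resampling would leave fewer than 2 samples along an axis")
    vox = stack.voxels
    if factor < 1.0:
        sigma = 0.5 * (1.0 / factor - 1.0)
        vox = ndimage.gaussian_filter(vox, sigma=(sigma, sigma, 0.0, 0.0), mode="nearest")
    vox = _cubic_resample_axis(vox, 0, n_r)
    vox = _cubic_resample_axis(vox, 1, n_c)
    if stack.image_type != "ct":
        vox = np.clip(vox, 0.0, 1.0)
    sy = stack.pixel_spacing_mm[0] * (stack.rows - 1) / (n_r - 1)
    sx = stack.pixel_spacing_mm[1] * (stack.cols - 1) / (n_c - 1)
    return ImageStack(
        voxels=vox,
        pixel_spacing_mm=(sy, sx),
        slice_thickness_mm=stack.slice_thickness_mm,
        slice_gap_mm=stack.slice_gap_mm,
        time_increment_s=stack.time_increment_s,
        image_type=stack.image_type,
        venc_cm_s=stack.venc_cm_s,
        origin_mm=stack.origin_mm,
        row_dir=stack.row_dir,
        col_dir=stack.col_dir,
        series_uid=stack.series_uid,
        stored_bits=stack.stored_bits,
    )


def mpr_slice(stack: ImageStack, plane_origin_mm, plane_axes_mm, out_shape,
              out_spacing_mm=(1.0, 1.0), frame: int = 0):
    """Multi-planar reconstruction: trilinear sampling on an oblique plane.

    Returns ``(image, valid)`` where ``valid`` marks samples that fell
    inside the volume; out-of-volume samples are 0.
    """
    axes = np.asarray(plane_axes_mm, dtype=np.float64)
    if axes.shape != (2, 3):
        raise ValueError("plane_axes_mm must be a 2x3 array of row vectors")
    if (abs(np.linalg.norm(axes[0]) - 1) > 1e-9
            or abs(np.linalg.norm(axes[1]) - 1) > 1e-9
            or abs(float(axes[0] @ axes[1])) > 1e-9):
        raise ValueError("plane axes must be orthonormal")
    n_u, n_v = int(out_shape[0]), int(out_shape[1])
    su, sv = float(out_spacing_mm[0]), float(out_spacing_mm[1])
    uu, vv = np.mgrid[0:n_u, 0:n_v]
    pts = (np.asarray(plane_origin_mm, dtype=np.float64)
           + uu[..., None] * su * axes[0]
           + vv[..., None] * sv * axes[1])
    idx = stack.patient_to_index(pts.reshape(-1, 3)).reshape(n_u, n_v, 3)
    r, c, s = idx[..., 0], idx[..., 1], idx[..., 2]
    eps = 1e-9
    valid = ((r >= -eps) & (r <= stack.rows - 1 + eps)
             & (c >= -eps) & (c <= stack.cols - 1 + eps)
             & (s >= -eps) & (s <= stack.slices - 1 + eps))
    vol = stack.voxels[:, :, :, frame]
    img = ndimage.map_coordinates(vol, [r.ravel(), c.ravel(), s.ravel()],
                                  order=1, mode="constant", cval=0.0)
    img = img.reshape(n_u, n_v)
    img[~valid] = 0.0
    return img, valid
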