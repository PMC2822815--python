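"""ROI statistics, time-curve features and the pixel-sampling error study.

Areas are measured on the continuous polygon, but signal statistics are
necessarily computed over the discrete pixels whose centers fall inside
the ROI.  The gap between the two — the sampling error of pixel counting
— is quantified by :func:`sampling_error_study` for circular ROIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import Contour, polygon_area, rasterize
from .stack import ImageStack

__all__ = [
    "RoiStatistics",
    "CurveFeatures",
    "SamplingErrorTable",
    "roi_statistics",
    "intensity_histogram",
    "time_curve",
    "smooth_normalized_averaging",
    "curve_features",
    "sampling_error_study",
]


@dataclass
class RoiStatistics:
    mean: float
    sd: float
    min: float
    max: float
    n_pixels: int
    area_polygon_mm2: float
    area_pixelcount_mm2: float


@dataclass
class CurveFeatures:
    max_value: float
    min_value: float
    fwhm_s: float | None
    fwhm_reason: str | None
    max_derivative: float
    min_derivative: float
    smoothing_sigma_s: float = 0.0


@dataclass
class SamplingErrorTable:
    """Mean/SD of the pixel-count area error per pixel size, from a seed."""

    pixel_sizes_mm: list
    mean_error_mm2: list
    sd_error_mm2: list
    n_rois: int
    seed: int
    area_range_mm2: tuple = (0.0, 100.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pixel_sizes_mm": list(self.pixel_sizes_mm),
                "mean_error_mm2": list(self.mean_error_mm2),
                "sd_error_mm2": list(self.sd_error_mm2),
                "n_rois": self.n_rois,
                "seed": self.seed,
                "area_range_mm2": list(self.area_range_mm2),
            },
            indent=1,
        )


def _masked_values(stack: ImageStack, contour: Contour, frame: int) -> np.ndarray:
    mask = rasterize(contour, (stack.rows, stack.cols))
    if not mask.any():
        v = contour.vertices
        in_bounds = (
            v[:, 0].max() >= 0 and v[:, 0].min() <= stack.cols - 1
            and v[:, 1].max() >= 0 and v[:, 1].min() <= stack.rows - 1
        )
        if in_bounds:
            raise ValueError("ROI is thinner than the pixel grid: no pixel center inside")
        raise ValueError("ROI lies outside the image")
    return mask, stack.voxels[:, :, contour.slice_index, frame][mask]


def roi_statistics(stack: ImageStack, contour: Contour, frame: int = 0) -> RoiStatistics:
    """Intensity statistics over pixel centers inside the polygon.

    The standard deviation is the population SD (divide by n): the ROI's
    pixels are the full population, not a sample.
    """
    mask, vals = _masked_values(stack, contour, frame)
    pixel_area = stack.pixel_spacing_mm[0] * stack.pixel_spacing_mm[1]
    n = int(mask.sum())
    return RoiStatistics(
        mean=float(vals.mean()),
        sd=float(vals.std()),
        min=float(vals.min()),
        max=float(vals.max()),
        n_pixels=n,
        area_polygon_mm2=polygon_area(contour, stack.pixel_spacing_mm),
        area_pixelcount_mm2=n * pixel_area,
    )


def intensity_histogram(stack: ImageStack, contour: Contour, frame: int = 0,
                        n_bins: int = 32):
    """Histogram of pixel intensities inside the ROI; edges span [min, max]."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    _, vals = _masked_values(stack, contour, frame)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        hi = lo + 1e-12
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return edges, counts


def time_curve(stack: ImageStack, contours_per_frame) -> np.ndarray:
    """Per-frame mean ROI intensity; returns an (n_frames, 2) array (t, mean).

    ``contours_per_frame`` is either one contour applied to every frame or
    a mapping/sequence with one contour per frame.
    """
    if isinstance(contours_per_frame, Contour):
        contours = {f: contours_per_frame for f in range(stack.frames)}
    elif isinstance(contours_per_frame, dict):
        contours = contours_per_frame
    else:
        contours = dict(enumerate(contours_per_frame))
    missing = [f for f in range(stack.frames) if f not in contours]
    if missing:
        raise ValueError(f"missing contour on frames {missing}")
    out = np.empty((stack.frames, 2))
    for f in range(stack.frames):
        out[f, 0] = stack.frame_time_s(f)
        out[f, 1] = roi_statistics(stack, contours[f], f).mean
    return out


def smooth_normalized_averaging(signal, certainty=None, sigma_samples: float = 1.0):
    """Gaussian smoothing by normalized averaging.

    Dividing the Gaussian-filtered signal*certainty by the filtered
    certainty compensates the truncated kernel mass at the signal
    boundaries, so constants pass through exactly, endpoints included.
    The kernel is truncated at ±4 sigma.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or signal.size < 1:
        raise ValueError("signal must be a non-empty 1D array")
    if sigma_samples < 0:
        raise ValueError("sigma must be non-negative")
    if certainty is None:
        certainty = np.ones_like(signal)
    certainty = np.asarray(certainty, dtype=np.float64)
    if certainty.shape != signal.shape:
        raise ValueError("certainty must match the signal shape")
    if not np.any(certainty > 0):
        raise ValueError("certainty is zero everywhere")
    if sigma_samples == 0:
        return signal.copy()
    half = max(1, int(np.ceil(4.0 * sigma_samples)))
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma_samples) ** 2)
    g /= g.sum()
    num = np.convolve(signal * certainty, g, mode="same")
    den = np.convolve(certainty, g, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = 0.0
    return out


def curve_features(series, smoothing_sigma_s: float = 0.0) -> CurveFeatures:
    """Extrema, FWHM and temporal derivatives of a (t, value) series.

    The half-maximum level is min + (max - min)/2; the crossing times on
    each flank are located by linear interpolation between samples.
    Derivatives use central differences (one-sided at the ends) after
    optional normalized-averaging smoothing.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2 or series.shape[1] != 2 or series.shape[0] < 3:
        raise ValueError("series must be (n >= 3, 2) of (t, value)")
    t, y = series[:, 0], series[:, 1].copy()
    dt = float(np.median(np.diff(t)))
    if smoothing_sigma_s > 0:
        y = smooth_normalized_averaging(y, sigma_samples=smoothing_sigma_s / dt)
    ymax, ymin = float(y.max()), float(y.min())
    half = ymin + 0.5 * (ymax - ymin)
    imax = int(np.argmax(y))

    def _crossing(indices, rising: bool):
        for i in indices:
            y0, y1 = y[i], y[i + 1]
            if (y0 < half <= y1) if rising else (y0 >= half > y1):
                if y1 == y0:
                    return t[i]
                return t[i] + (half - y0) / (y1 - y0) * (t[i + 1] - t[i])
        return None

    left = _crossing(range(imax - 1, -1, -1), rising=True) if imax > 0 else None
    right = _crossing(range(imax, len(y) - 1), rising=False)
    if left is None or right is None:
        fwhm, reason = None, "curve does not cross half-maximum on %s side" % (
            "the left" if left is None else "the right")
    else:
        fwhm, reason = float(right - left), None
    deriv = np.gradient(y, t)
    return CurveFeatures(
        max_value=ymax,
        min_value=ymin,
        fwhm_s=fwhm,
        fwhm_reason=reason,
        max_derivative=float(deriv.max()),
        min_derivative=float(deriv.min()),
        smoothing_sigma_s=smoothing_sigma_s,
    )


def circle_pixel_count(radius: float, cx: float, cy: float, h: float) -> int:
    """Number of pixel centers (spacing ``h``, at integer multiples of
    ``h``) inside a circle; centers exactly on the rim count as inside."""
    xs = np.arange(np.floor((cx - radius) / h), np.ceil((cx + radius) / h) + 1) * h
    ys = np.arange(np.floor((cy - radius) / h), np.ceil((cy + radius) / h) + 1) * h
    d2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    return int(np.count_nonzero(d2 <= radius * radius))


def sampling_error_study(pixel_sizes_mm=(1.0, 0.5, 0.25), n_rois: int = 5000,
                         area_range_mm2=(0.0, 100.0), seed: int = 0) -> SamplingErrorTable:
    """Pixel-counting area error for randomly placed circular ROIs.

    For each pixel size ``h``: draw ``n_rois`` circles with true areas
    uniform on the given range and centers uniformly jittered within one
    pixel cell; the measured area is ``h^2`` times the number of pixel
    centers inside the circle.  Reports mean and SD of measured - true.
    """
    if n_rois < 100:
        raise ValueError("n_rois must be >= 100 for a stable estimate")
    lo, hi = float(area_range_mm2[0]), float(area_range_mm2[1])
    means, sds = [], []
    for j, h in enumerate(pixel_sizes_mm):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), j]))
        areas = rng.uniform(lo, hi, n_rois)
        radii = np.sqrt(areas / np.pi)
        cx = rng.uniform(0.0, h, n_rois)
        cy = rng.uniform(0.0, h, n_rois)
        err = np.empty(n_rois)
        for i in range(n_rois):
            err[i] = h * h * circle_pixel_count(radii[i], cx[i], cy[i], h) - areas[i]
        means.append(float(err.mean()))
        sds.append(float(err.std()))
    return SamplingErrorTable(
        pixel_sizes_mm=list(pixel_sizes_mm),
        mean_error_mm2=means,
        sd_error_mm2=sds,
        n_rois=n_rois,
        seed=seed,
        area_range_mm2=(lo, hi),
    )
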