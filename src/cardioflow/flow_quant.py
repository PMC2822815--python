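"""Velocity-encoded phase-contrast flow quantification.

Pipeline: phase image -> velocity map (``v = (2p - 1) * venc``) ->
stationary-tissue detection -> polynomial eddy-current background
correction -> temporal phase unwrapping -> vessel tracking ->
per-frame flow rates and per-beat volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Polygon as _ShapelyPolygon

from .geometry import Contour, polygon_area, rasterize
from .stack import ImageStack

__all__ = [
    "VelocityField",
    "BackgroundSurface",
    "FlowResult",
    "RecoveryStats",
    "phase_to_velocity",
    "velocity_to_phase",
    "detect_stationary",
    "fit_background",
    "correct_background",
    "unwrap_temporal",
    "track_vessel",
    "compute_flow",
    "flow_recovery_study",
    "flow_profile_frames",
]


@dataclass
class VelocityField:
    """Per-pixel through-plane velocities, (row, col, frame), cm/s."""

    velocity_cm_s: np.ndarray
    venc_cm_s: float
    pixel_spacing_mm: tuple = (1.0, 1.0)
    time_increment_s: float = 0.0
    unwrap_flagged: np.ndarray | None = None  # pixels with unpaired jumps

    def __post_init__(self):
        self.velocity_cm_s = np.asarray(self.velocity_cm_s, dtype=np.float64)
        if self.velocity_cm_s.ndim != 3:
            raise ValueError("velocity must be (row, col, frame)")

    @property
    def frames(self) -> int:
        return self.velocity_cm_s.shape[2]


@dataclass
class BackgroundSurface:
    """2D polynomial offset surface fitted over stationary tissue.

    Coefficients multiply ``x^i * y^j`` (i + j <= order) with x, y pixel
    coordinates centered on the image center for conditioning.
    """

    order: int
    exponents: list  # [(i, j), ...]
    coefficients: np.ndarray  # cm/s per pixel^(i+j)
    shape: tuple
    stationary_mask: np.ndarray
    residual_rms_cm_s: float

    def evaluate(self) -> np.ndarray:
        rows, cols = self.shape
        y, x = np.mgrid[0:rows, 0:cols].astype(np.float64)
        x -= (cols - 1) / 2.0
        y -= (rows - 1) / 2.0
        out = np.zeros((rows, cols))
        for (i, j), c in zip(self.exponents, self.coefficients):
            out += c * x**i * y**j
        return out


@dataclass
class FlowResult:
    time_s: np.ndarray
    flow_ml_s: np.ndarray
    area_mm2: np.ndarray
    net_volume_ml: float
    positive_volume_ml: float
    negative_volume_ml: float
    tracking_failed: bool = False
    failure_reason: str = ""


@dataclass
class RecoveryStats:
    slope: float
    intercept_ml: float
    r_squared: float


# -- phase <-> velocity ----------------------------------------------------

def phase_to_velocity(stack: ImageStack, venc_cm_s: float | None = None) -> VelocityField:
    """Map [0, 1] phase intensities to velocities: 0 -> -venc, 1 -> +venc."""
    if stack.image_type != "phase":
        raise ValueError("phase_to_velocity requires a phase stack")
    venc = float(venc_cm_s if venc_cm_s is not None else stack.venc_cm_s)
    if venc <= 0:
        raise ValueError("venc must be positive")
    v = (2.0 * stack.voxels[:, :, 0, :] - 1.0) * venc
    return VelocityField(v, venc, stack.pixel_spacing_mm, stack.time_increment_s)


def velocity_to_phase(v_cm_s: np.ndarray, venc_cm_s: float, wrap: bool = False) -> np.ndarray:
    """Inverse map to [0, 1] phase units; optionally alias by modular wrap."""
    p = (np.asarray(v_cm_s, dtype=np.float64) / venc_cm_s + 1.0) / 2.0
    if wrap:
        p = np.mod(p, 1.0)
    elif np.any((p < 0) | (p > 1)):
        raise ValueError(
            "velocities exceed the representable +/-venc range; enable wrapping"
        )
    return p


# -- background correction -------------------------------------------------

def detect_stationary(v: VelocityField, sd_threshold_cm_s: float | None = None,
                      magnitude: ImageStack | None = None,
                      magnitude_floor: float | None = None,
                      exclude_contours=None, exclude_dilate_px: int = 2) -> np.ndarray:
    """Stationary-tissue mask from the temporal SD of the velocity.

    A pixel is stationary when its velocity SD over time is below the
    threshold (default 2% of venc) and, when a magnitude stack is given,
    its time-mean magnitude is above the floor (default 10% of the
    magnitude maximum) — this excludes air, where phase is pure noise.
    ``exclude_contours`` (e.g. the vessel ROIs being quantified) are
    rasterized, dilated and removed: slowly and steadily flowing blood
    near a vessel wall is indistinguishable from static tissue by
    temporal SD alone, so measured vessels are never stationary
    candidates.  This is the manual-ROI override of the automatic
    detection.
    """
    if v.frames < 3:
        raise ValueError("need at least 3 frames to estimate the temporal SD")
    if sd_threshold_cm_s is None:
        sd_threshold_cm_s = 0.02 * v.venc_cm_s
    sd = v.velocity_cm_s.std(axis=2)
    mask = sd < sd_threshold_cm_s
    if magnitude is not None:
        mag = magnitude.voxels[:, :, 0, :].mean(axis=2)
        if magnitude_floor is None:
            magnitude_floor = 0.1 * float(mag.max())
        mask &= mag > magnitude_floor
    if exclude_contours is not None:
        if isinstance(exclude_contours, Contour):
            exclude_contours = [exclude_contours]
        for c in exclude_contours:
            vessel = rasterize(c, mask.shape)
            mask &= ~ndimage.binary_dilation(vessel, iterations=exclude_dilate_px)
    if not mask.any():
        raise ValueError(
            "no stationary pixels found; raise sd_threshold_cm_s or lower the magnitude floor"
        )
    return mask


def _poly_terms(order: int):
    return [(i, j) for total in range(order + 1)
            for i in range(total + 1) for j in [total - i]]


def fit_background(v: VelocityField, mask: np.ndarray, order: int = 1) -> BackgroundSurface:
    """Least-squares polynomial fit to the time-mean velocity over a mask."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    terms = _poly_terms(order)
    n_coef = len(terms)
    if int(mask.sum()) < 3 * n_coef:
        raise ValueError(f"need at least {3 * n_coef} mask pixels for an order-{order} fit")
    rows, cols = mask.shape
    vm = v.velocity_cm_s.mean(axis=2)
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    xx -= (cols - 1) / 2.0
    yy -= (rows - 1) / 2.0
    x, y = xx[mask], yy[mask]
    design = np.stack([x**i * y**j for i, j in terms], axis=1)
    coef, _, rank, _ = np.linalg.lstsq(design, vm[mask], rcond=None)
    if rank < n_coef:
        raise ValueError("rank-deficient background fit (collinear stationary mask)")
    resid = design @ coef - vm[mask]
    return BackgroundSurface(
        order=order,
        exponents=terms,
        coefficients=coef,
        shape=(rows, cols),
        stationary_mask=mask,
        residual_rms_cm_s=float(np.sqrt(np.mean(resid**2))),
    )


def correct_background(v: VelocityField, surface: BackgroundSurface) -> VelocityField:
    """Subtract the static offset surface from every frame."""
    if tuple(surface.shape) != v.velocity_cm_s.shape[:2]:
        raise ValueError("background surface grid does not match the velocity field")
    corrected = v.velocity_cm_s - surface.evaluate()[:, :, None]
    return VelocityField(corrected, v.venc_cm_s, v.pixel_spacing_mm,
                         v.time_increment_s, v.unwrap_flagged)


# -- temporal unwrapping ---------------------------------------------------

def unwrap_temporal(v: VelocityField) -> VelocityField:
    """Undo velocity aliasing from temporal phase-jump pairs.

    Per pixel, frame-to-frame differences larger than venc in magnitude
    mark wrap events; a pair of opposite-signed events brackets a wrapped
    interval and ``2 * venc`` (signed against the entering jump) is added
    across it.  Pixels with unpaired events are left unchanged and
    flagged.
    """
    if v.frames < 3:
        raise ValueError("need at least 3 frames for temporal unwrapping")
    venc = v.venc_cm_s
    vel = v.velocity_cm_s.copy()
    d = np.diff(vel, axis=2)
    jumpy = np.abs(d) > venc
    flagged = np.zeros(vel.shape[:2], dtype=bool)
    for r, c in zip(*np.nonzero(jumpy.any(axis=2))):
        series = vel[r, c, :]
        events = [(k, -1 if d[r, c, k] > 0 else 1) for k in np.nonzero(jumpy[r, c])[0]]
        corrections = []
        pending = None
        unpaired = False
        for k, sign in events:
            if pending is None:
                pending = (k, sign)
            elif sign == -pending[1]:
                corrections.append((pending[0], k, pending[1]))
                pending = None
            else:
                unpaired = True
                pending = (k, sign)
        if pending is not None:
            unpaired = True
        if unpaired:
            flagged[r, c] = True
            continue
        for k0, k1, sign in corrections:
            series[k0 + 1 : k1 + 1] += sign * 2.0 * venc
    return VelocityField(vel, venc, v.pixel_spacing_mm, v.time_increment_s, flagged)


# -- vessel tracking -------------------------------------------------------

_N_RAYS = 64
_SMOOTH_WINDOW = 5


def _radius_profile(poly: _ShapelyPolygon, center: np.ndarray, angles: np.ndarray,
                    reach: float) -> np.ndarray:
    """Distance from center to the polygon boundary along each angle."""
    radii = np.full(angles.shape, np.nan)
    boundary = poly.exterior
    for k, a in enumerate(angles):
        ray = LineString([center, center + reach * np.array([np.cos(a), np.sin(a)])])
        hit = ray.intersection(boundary)
        if hit.is_empty:
            continue
        pts = [hit] if hit.geom_type == "Point" else list(getattr(hit, "geoms", []))
        ds = [np.hypot(p.x - center[0], p.y - center[1]) for p in pts if p.geom_type == "Point"]
        if ds:
            radii[k] = min(ds)
    return radii


def track_vessel(magnitude: ImageStack, contour_frame0: Contour,
                 gradient_floor: float = 0.02):
    """Propagate a frame-0 vessel contour across all time frames.

    For each subsequent frame: recenter on the intensity-weighted centroid
    of the magnitude inside the previous contour (dilated by 2 px), cast
    64 rays and place the new radius at the strongest radial gradient
    within +/-30% of the previous radius, then smooth the radii with a
    circular 5-tap moving average.  The failure flag is raised when the
    polygon area changes by more than 50% between frames or the gradient
    search fails on more than 25% of the rays.

    Returns ``(contours, failed, reason)``.
    """
    rows, cols = magnitude.rows, magnitude.cols
    v = contour_frame0.vertices
    if (v < -0.5).any() or (v[:, 0] > cols - 0.5).any() or (v[:, 1] > rows - 0.5).any():
        raise ValueError("initial contour lies outside the image")
    angles = np.linspace(0.0, 2 * np.pi, _N_RAYS, endpoint=False)
    contours = [contour_frame0]
    failed, reason = False, ""
    prev = contour_frame0
    for f in range(1, magnitude.frames):
        img = magnitude.voxels[:, :, 0, f]
        mask = rasterize(prev, (rows, cols))
        mask = ndimage.binary_dilation(mask, iterations=2)
        weights = img * mask
        total = weights.sum()
        if total <= 0:
            failed, reason = True, f"zero intensity inside search region at frame {f}"
            contours.extend([prev] * (magnitude.frames - f))
            break
        rr, cc = np.mgrid[0:rows, 0:cols]
        center = np.array([(cc * weights).sum() / total, (rr * weights).sum() / total])
        prev_r = _radius_profile(prev.polygon, center, angles, reach=2.0 * max(rows, cols))
        prev_r = np.where(np.isfinite(prev_r), prev_r, np.nanmedian(prev_r))
        new_r = prev_r.copy()
        n_failed_rays = 0
        for k, a in enumerate(angles):
            r_lo, r_hi = 0.7 * prev_r[k], 1.3 * prev_r[k]
            rs = np.linspace(r_lo, r_hi, max(8, int(np.ceil((r_hi - r_lo) / 0.1))))
            xs = center[0] + rs * np.cos(a)
            ys = center[1] + rs * np.sin(a)
            prof = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
            grad = np.gradient(prof, rs)
            mag_g = np.abs(grad)
            peak = int(np.argmax(mag_g))
            if mag_g[peak] < gradient_floor:
                n_failed_rays += 1
                continue
            # sub-sample localization: the gradient of a sharp edge forms a
            # plateau under bilinear sampling, so argmax alone is biased to
            # the plateau's first sample; use the gradient-magnitude centroid
            # over the contiguous half-peak region instead
            lo = peak
            while lo > 0 and mag_g[lo - 1] >= 0.5 * mag_g[peak]:
                lo -= 1
            hi = peak
            while hi < len(rs) - 1 and mag_g[hi + 1] >= 0.5 * mag_g[peak]:
                hi += 1
            w_seg = mag_g[lo : hi + 1]
            new_r[k] = float(np.sum(rs[lo : hi + 1] * w_seg) / np.sum(w_seg))
        kernel = np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW
        padded = np.concatenate([new_r[-2:], new_r, new_r[:2]])
        new_r = np.convolve(padded, kernel, mode="valid")
        verts = np.stack([center[0] + new_r * np.cos(angles),
                          center[1] + new_r * np.sin(angles)], axis=1)
        cont = Contour(verts, slice_index=prev.slice_index, frame_index=f,
                       label=prev.label)
        area_prev = polygon_area(prev, magnitude.pixel_spacing_mm)
        area_new = polygon_area(cont, magnitude.pixel_spacing_mm)
        if n_failed_rays > 0.25 * _N_RAYS:
            failed, reason = True, (
                f"gradient search failed on {n_failed_rays}/{_N_RAYS} rays at frame {f}")
        elif abs(area_new - area_prev) > 0.5 * area_prev:
            failed, reason = True, f"area changed by more than 50% at frame {f}"
        if failed:
            contours.extend([prev] * (magnitude.frames - f))
            break
        contours.append(cont)
        prev = cont
    return contours, failed, reason


# -- flow ------------------------------------------------------------------

def compute_flow(v: VelocityField, contours, time_increment_s: float | None = None,
                 pixel_spacing_mm=None) -> FlowResult:
    """Flow rate per frame and per-beat volumes inside the vessel ROI.

    ``flow(t) = sum of pixel velocities [cm/s] * pixel area [cm^2]`` over
    pixel centers inside the frame's contour; the net volume is the time
    integral over the beat, split into positive and negative parts.
    """
    dt = float(time_increment_s if time_increment_s is not None else v.time_increment_s)
    sy, sx = pixel_spacing_mm if pixel_spacing_mm is not None else v.pixel_spacing_mm
    if dt <= 0:
        raise ValueError("time increment must be positive")
    if isinstance(contours, Contour):
        contours = {f: contours for f in range(v.frames)}
    elif not isinstance(contours, dict):
        contours = dict(enumerate(contours))
    pixel_area_cm2 = (sy / 10.0) * (sx / 10.0)
    shape = v.velocity_cm_s.shape[:2]
    flow = np.empty(v.frames)
    area = np.empty(v.frames)
    for f in range(v.frames):
        if f not in contours:
            raise ValueError(f"no contour for frame {f}")
        mask = rasterize(contours[f], shape)
        if not mask.any():
            raise ValueError(f"empty vessel mask on frame {f}")
        flow[f] = v.velocity_cm_s[:, :, f][mask].sum() * pixel_area_cm2
        area[f] = polygon_area(contours[f], (sy, sx))
    pos = float(np.sum(np.maximum(flow, 0.0)) * dt)
    neg = float(np.sum(np.minimum(flow, 0.0)) * dt)
    return FlowResult(
        time_s=np.arange(v.frames) * dt,
        flow_ml_s=flow,
        area_mm2=area,
        net_volume_ml=pos + neg,
        positive_volume_ml=pos,
        negative_volume_ml=neg,
    )


def flow_recovery_study(true_volumes_ml, measured_volumes_ml) -> RecoveryStats:
    """OLS regression of measured against true per-beat volumes."""
    x = np.asarray(true_volumes_ml, dtype=np.float64)
    y = np.asarray(measured_volumes_ml, dtype=np.float64)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 matched (true, measured) volumes")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return RecoveryStats(slope=float(slope), intercept_ml=float(intercept), r_squared=r2)


def flow_profile_frames(v: VelocityField, contours) -> list:
    """Masked per-frame velocity surfaces for flow-profile rendering."""
    if isinstance(contours, Contour):
        contours = {f: contours for f in range(v.frames)}
    elif not isinstance(contours, dict):
        contours = dict(enumerate(contours))
    shape = v.velocity_cm_s.shape[:2]
    out = []
    for f in range(v.frames):
        mask = rasterize(contours[f], shape)
        out.append(np.ma.masked_array(v.velocity_cm_s[:, :, f], mask=~mask))
    return out
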