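"""Ventricular volumetry, mass, regional wall measures and AHA polar maps.

Volumes come from slice summation (Simpson's rule on short-axis
contours), mass from the epi-endo shell times a myocardial density of
1.05 g/ml, and regional wall thickness from radial profiles between the
endo- and epicardial contours.  Regional values are pooled into the AHA
17-segment bullseye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .geometry import Contour, polygon_area

__all__ = [
    "VentricularContours",
    "VolumeCurve",
    "WallMeasures",
    "PolarMap",
    "slice_summation_volume",
    "lv_mass",
    "wall_thickness",
    "wall_thickening",
    "polar_map_17",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class VentricularContours:
    """Endo- (and optionally epi-) cardial contours per (slice, frame).

    Slices are indexed base -> apex.  Where both contours exist on a
    slice the epicardium must enclose the endocardium.
    """

    endo: dict  # (slice, frame) -> Contour
    epi: dict | None = None
    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 0.0
    pixel_spacing_mm: tuple = (1.0, 1.0)
    time_increment_s: float = 0.0

    def __post_init__(self):
        if self.epi:
            for key, epi_c in self.epi.items():
                endo_c = self.endo.get(key)
                if endo_c is None:
                    continue
                epi_poly = epi_c.polygon
                if not all(epi_poly.covers(Point(x, y)) for x, y in endo_c.vertices):
                    raise ValueError(f"epicardium does not enclose endocardium at {key}")

    def frames(self) -> list:
        return sorted({f for (_, f) in self.endo})

    def slices(self, frame: int) -> list:
        return sorted({s for (s, f) in self.endo if f == frame})


@dataclass
class VolumeCurve:
    frames: list
    volume_ml: np.ndarray
    edv_ml: float
    esv_ml: float
    lvm_g: float | None = None

    @property
    def ed_frame(self) -> int:
        return self.frames[int(np.argmax(self.volume_ml))]

    @property
    def es_frame(self) -> int:
        return self.frames[int(np.argmin(self.volume_ml))]


@dataclass
class WallMeasures:
    """Per-sector wall thickness (mm) for one slice/frame contour pair."""

    thickness_mm: np.ndarray  # (n_sectors,), NaN where the ray found no crossing
    angles_rad: np.ndarray
    thickening_mm: np.ndarray | None = None
    fractional_thickening: np.ndarray | None = None


@dataclass
class PolarMap:
    """AHA 17-segment values: 1-6 basal, 7-12 mid, 13-16 apical, 17 apex."""

    values: np.ndarray  # (17,)
    counts: np.ndarray  # (17,)
    reference_angle_rad: float = 0.0


def slice_summation_volume(vc: VentricularContours, which: str = "endo") -> VolumeCurve:
    """Simpson slice-summation volume per frame, in ml.

    Each delineated slice contributes polygon area times the slice step
    (thickness + gap); no partial-slice correction is applied at the base
    or apex.
    """
    contours = vc.endo if which == "endo" else vc.epi
    if contours is None:
        raise ValueError(f"no {which} contours present")
    step = vc.slice_thickness_mm + vc.slice_gap_mm
    frames, volumes = [], []
    for f in sorted({f for (_, f) in contours}):
        areas = [polygon_area(c, vc.pixel_spacing_mm)
                 for (s, ff), c in contours.items() if ff == f]
        if not areas:
            warnings.warn(f"frame {f} has no contours and was omitted")
            continue
        frames.append(f)
        volumes.append(sum(areas) * step / 1000.0)
    volumes = np.asarray(volumes)
    return VolumeCurve(frames=frames, volume_ml=volumes,
                       edv_ml=float(volumes.max()), esv_ml=float(volumes.min()))


def lv_mass(vc: VentricularContours, frame: int | None = None) -> float:
    """Myocardial mass in grams: 1.05 g/ml times the epi-endo shell volume."""
    if vc.epi is None:
        raise ValueError("lv_mass requires epicardial contours")
    if frame is None:
        frame = vc.frames()[0]
    step = vc.slice_thickness_mm + vc.slice_gap_mm
    shell_mm3 = 0.0
    for s in vc.slices(frame):
        endo_c = vc.endo.get((s, frame))
        epi_c = (vc.epi or {}).get((s, frame))
        if epi_c is None:
            continue
        a_epi = polygon_area(epi_c, vc.pixel_spacing_mm)
        a_endo = polygon_area(endo_c, vc.pixel_spacing_mm) if endo_c else 0.0
        if a_endo > a_epi:
            raise ValueError(f"endocardial area exceeds epicardial area on slice {s}")
        shell_mm3 += (a_epi - a_endo) * step
    return shell_mm3 / 1000.0 * MYOCARDIAL_DENSITY_G_PER_ML


def _ray_crossing(boundary, center_mm, angle, reach) -> float:
    ray = LineString([center_mm,
                      center_mm + reach * np.array([np.cos(angle), np.sin(angle)])])
    hit = ray.intersection(boundary)
    if hit.is_empty:
        return np.nan
    pts = [hit] if hit.geom_type == "Point" else list(getattr(hit, "geoms", []))
    ds = [np.hypot(p.x - center_mm[0], p.y - center_mm[1])
          for p in pts if p.geom_type == "Point"]
    return min(ds) if ds else np.nan


def wall_thickness(endo: Contour, epi: Contour, n_sectors: int = 24,
                   reference_angle_rad: float = 0.0,
                   pixel_spacing_mm=(1.0, 1.0)) -> WallMeasures:
    """Radial wall thickness between endo- and epicardial contours.

    Rays start at the endocardial centroid at ``n_sectors`` equally spaced
    angles from the reference angle; the thickness is the mm distance
    between the endo and epi crossings along each ray.  Sectors whose ray
    misses a contour are NaN (invalid), not zero.
    """
    sy, sx = float(pixel_spacing_mm[0]), float(pixel_spacing_mm[1])
    scale = np.array([sx, sy])
    endo_mm = Contour(endo.vertices * scale)
    epi_mm = Contour(epi.vertices * scale)
    centroid = np.array(endo_mm.polygon.centroid.coords[0])
    angles = reference_angle_rad + np.arange(n_sectors) * 2 * np.pi / n_sectors
    reach = 4.0 * max(np.ptp(epi_mm.vertices[:, 0]), np.ptp(epi_mm.vertices[:, 1]))
    thickness = np.empty(n_sectors)
    for k, a in enumerate(angles):
        r_endo = _ray_crossing(endo_mm.polygon.exterior, centroid, a, reach)
        r_epi = _ray_crossing(epi_mm.polygon.exterior, centroid, a, reach)
        thickness[k] = r_epi - r_endo if np.isfinite(r_endo) and np.isfinite(r_epi) else np.nan
    return WallMeasures(thickness_mm=thickness, angles_rad=angles)


def wall_thickening(ed: WallMeasures, es: WallMeasures) -> WallMeasures:
    """Per-sector wall thickening between ED and ES: absolute and fractional."""
    if ed.thickness_mm.shape != es.thickness_mm.shape:
        raise ValueError("ED and ES measures must share the sector layout")
    thickening = es.thickness_mm - ed.thickness_mm
    with np.errstate(invalid="ignore", divide="ignore"):
        fractional = np.where(ed.thickness_mm > 0,
                              thickening / ed.thickness_mm, np.nan)
    return WallMeasures(thickness_mm=ed.thickness_mm, angles_rad=ed.angles_rad,
                        thickening_mm=thickening, fractional_thickening=fractional)


def polar_map_17(values: np.ndarray, reference_angle_rad: float = 0.0) -> PolarMap:
    """Pool (slice, sector) samples into the AHA 17-segment model.

    ``values`` is (n_slices, n_sectors) with slices ordered base -> apex
    and sector k spanning angles ``[k, k+1) * 360/n_sectors`` from the
    reference angle.  Slices are split into basal/mid/apical thirds
    (remainder slices go apically); basal and mid rings form 6 x 60
    degree segments, the apical ring 4 x 90 degrees, and segment 17 is
    the mean of the most apical slice.  Each segment value is the mean of
    its contributing samples (NaN samples are excluded).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("values must be (n_slices, n_sectors)")
    n_slices, n_sectors = values.shape
    if n_slices < 3:
        raise ValueError("need at least 3 slices to form basal/mid/apical rings")
    third = n_slices // 3
    rings = [range(0, third), range(third, 2 * third), range(2 * third, n_slices)]
    sector_centers = (np.arange(n_sectors) + 0.5) * 2 * np.pi / n_sectors

    seg_values = np.full(17, np.nan)
    seg_counts = np.zeros(17, dtype=int)
    seg = 0
    for ring, n_seg in zip(rings, (6, 6, 4)):
        width = 2 * np.pi / n_seg
        bins = np.floor(sector_centers / width).astype(int) % n_seg
        for b in range(n_seg):
            samples = values[np.ix_(list(ring), np.nonzero(bins == b)[0])].ravel()
            samples = samples[np.isfinite(samples)]
            seg_counts[seg] = samples.size
            if samples.size:
                seg_values[seg] = samples.mean()
            seg += 1
    apex = values[-1][np.isfinite(values[-1])]
    seg_counts[16] = apex.size
    if apex.size:
        seg_values[16] = apex.mean()
    return PolarMap(values=seg_values, counts=seg_counts,
                    reference_angle_rad=reference_angle_rad)
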