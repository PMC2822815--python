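"""Synthetic phantoms with exact ground truth.

The flow phantom emulates a gravity-driven rig: a stationary gel block
with two parallel circular channels 26 mm in diameter, imaged by a
phase-contrast sequence at several flow rates.  Corruptions seen on real
scanners — eddy-current offset planes, velocity aliasing, noise — can be
injected with known parameters, so every stage of the flow pipeline can
be verified against stored truth.  A cine LV phantom and a DICOM fixture
writer cover volumetry and the loader.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .flow_quant import velocity_to_phase, _poly_terms
from .geometry import Contour
from .stack import ImageStack

__all__ = [
    "FlowPhantomConfig",
    "LvPhantomConfig",
    "FlowPhantomTruth",
    "gen_flow_phantom",
    "gen_cine_lv_phantom",
    "write_dicom_fixture",
    "circle_contour",
]

#: Channel diameter of the physical flow rig being emulated, mm.
CHANNEL_DIAMETER_MM = 26.0

#: Default per-beat volumes spanning the rig's five flow rates, ml.
DEFAULT_RATES_ML = (20.0, 40.0, 60.0, 80.0, 100.0)


def circle_contour(cx: float, cy: float, radius: float, n_vertices: int = 128,
                   slice_index: int = 0, frame_index: int = 0, label: str = "") -> Contour:
    """A regular n-gon inscribed in the circle (pixel units)."""
    a = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.stack([cx + radius * np.cos(a), cy + radius * np.sin(a)], axis=1)
    return Contour(verts, slice_index=slice_index, frame_index=frame_index, label=label)


@dataclass
class FlowPhantomConfig:
    shape: tuple = (96, 96)
    pixel_spacing_mm: tuple = (1.0, 1.0)
    channel_diameters_mm: tuple = (CHANNEL_DIAMETER_MM, CHANNEL_DIAMETER_MM)
    volumes_ml_per_beat: tuple = DEFAULT_RATES_ML
    venc_cm_s: float = 200.0
    profile: str = "poiseuille"  # or "uniform"
    background_offset: tuple = (0.0, 0.0, 0.0)  # (v0, a, b): v0 + a*x + b*y, centered px
    wrap_inducing: bool = False
    pulsatility: float = 0.0  # waveform w(t) = 1 + p*sin(2*pi*t/beat)
    noise_snr: float | None = None
    frames: int = 20
    time_increment_s: float = 0.05
    air_border_px: int = 6
    seed: int = 0

    @classmethod
    def from_json(cls, text: str) -> "FlowPhantomConfig":
        d = json.loads(text)
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class FlowPhantomTruth:
    """Everything downstream quantification can be checked against."""

    true_net_volume_ml: float           # per channel, analytic
    channel_centers_px: list            # [(cx, cy), ...]
    channel_radii_px: list
    contours: list                      # one Contour per channel
    peak_velocity_cm_s: float
    true_velocity_cm_s: np.ndarray      # pre-offset, pre-wrap, pre-noise
    offset_coefficients: np.ndarray     # matching _poly_terms(1) ordering
    region_map: np.ndarray              # 0 gel, 1.. channels, -1 air
    wrapped_pixels: np.ndarray          # bool (row, col): aliased at some frame


def _waveform(frames: int, pulsatility: float) -> np.ndarray:
    t = np.arange(frames)
    return 1.0 + pulsatility * np.sin(2 * np.pi * t / frames)


def gen_flow_phantom(config: FlowPhantomConfig, rate_ml: float | None = None):
    """Build magnitude + phase stacks for one flow rate.

    Both channels carry the same configured per-beat volume (the first of
    ``volumes_ml_per_beat`` unless ``rate_ml`` selects another).  The
    analytic per-beat integral of the assigned profile equals the
    requested volume exactly; the stored truth keeps the pre-corruption
    velocity field, offset coefficients and aliasing locations.
    """
    rows, cols = config.shape
    if rate_ml is None:
        rate_ml = config.volumes_ml_per_beat[0]
    rng = np.random.default_rng(config.seed)
    beat_s = config.frames * config.time_increment_s
    q_mean_ml_s = rate_ml / beat_s
    w = _waveform(config.frames, config.pulsatility)

    sy, sx = config.pixel_spacing_mm
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    n_ch = len(config.channel_diameters_mm)
    gap = cols / (n_ch + 1)
    centers = [(gap * (k + 1), rows / 2.0) for k in range(n_ch)]

    v_true = np.zeros((rows, cols, config.frames))
    region = np.zeros((rows, cols), dtype=np.int8)
    contours, radii_px = [], []
    peak = 0.0
    for k, (diam, (cx, cy)) in enumerate(zip(config.channel_diameters_mm, centers)):
        r_mm = diam / 2.0
        r_px = r_mm / sx  # isotropic spacing assumed for circular channels
        radii_px.append(r_px)
        d2 = ((xx - cx) * sx) ** 2 + ((yy - cy) * sy) ** 2
        inside = d2 <= r_mm**2
        region[inside] = k + 1
        area_cm2 = np.pi * (r_mm / 10.0) ** 2
        if config.profile == "poiseuille":
            vmax = 2.0 * q_mean_ml_s / area_cm2
            prof = np.where(inside, vmax * (1.0 - d2 / r_mm**2), 0.0)
        elif config.profile == "uniform":
            vmax = q_mean_ml_s / area_cm2
            prof = np.where(inside, vmax, 0.0)
        else:
            raise ValueError(f"unknown profile {config.profile!r}")
        peak = max(peak, vmax * w.max())
        v_true += prof[:, :, None] * w[None, None, :]
        contours.append(circle_contour(cx, cy, r_px, label=f"channel_{k + 1}"))

    if config.air_border_px > 0:
        b = config.air_border_px
        air = np.zeros((rows, cols), dtype=bool)
        air[:b, :] = air[-b:, :] = air[:, :b] = air[:, -b:] = True
        region[air] = -1

    v0, a, b_coef = config.background_offset
    xc = xx - (cols - 1) / 2.0
    yc = yy - (rows - 1) / 2.0
    offset = v0 + a * xc + b_coef * yc
    v_total = v_true + offset[:, :, None]

    wrapped = np.abs(v_total) > config.venc_cm_s
    phase = velocity_to_phase(v_total, config.venc_cm_s, wrap=config.wrap_inducing)

    mag = np.where(region > 0, 0.9, 0.5)
    mag[region == -1] = 0.02
    mag = np.repeat(mag[:, :, None], config.frames, axis=2)
    if config.noise_snr is not None:
        phase = phase + rng.normal(0.0, 0.5 / config.noise_snr, phase.shape)
        phase = np.clip(phase, 0.0, 1.0)
        mag = np.clip(mag + rng.normal(0.0, 0.9 / config.noise_snr, mag.shape), 0.0, 1.0)

    common = dict(
        pixel_spacing_mm=config.pixel_spacing_mm,
        slice_thickness_mm=8.0,
        time_increment_s=config.time_increment_s,
    )
    mag_stack = ImageStack(mag[:, :, None, :], image_type="magnitude",
                           series_uid="phantom-flow-mag", **common)
    phase_stack = ImageStack(phase[:, :, None, :], image_type="phase",
                             venc_cm_s=config.venc_cm_s,
                             series_uid="phantom-flow-phase", **common)
    coef = {(0, 0): v0, (1, 0): a, (0, 1): b_coef}
    truth = FlowPhantomTruth(
        true_net_volume_ml=float(rate_ml),
        channel_centers_px=centers,
        channel_radii_px=radii_px,
        contours=contours,
        peak_velocity_cm_s=float(peak),
        true_velocity_cm_s=v_true,
        offset_coefficients=np.array([coef[t] for t in _poly_terms(1)]),
        region_map=region,
        wrapped_pixels=wrapped.any(axis=2),
    )
    return mag_stack, phase_stack, truth


@dataclass
class LvPhantomConfig:
    edv_ml: float = 150.0
    esv_ml: float = 60.0
    slices: int = 8
    frames: int = 20
    shape: tuple = (96, 96)
    pixel_spacing_mm: tuple = (1.0, 1.0)
    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 0.0
    time_increment_s: float = 0.05
    wall_thickness_ed_mm: float = 8.0
    wall_thickness_es_mm: float = 12.0
    noise_sd: float = 0.0
    seed: int = 0

    @classmethod
    def from_json(cls, text: str) -> "LvPhantomConfig":
        d = json.loads(text)
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def gen_cine_lv_phantom(config: LvPhantomConfig):
    """Cine short-axis LV phantom: a stack of contracting cylinders.

    The cavity volume follows a raised-cosine cycle from EDV (frame 0)
    to ESV (mid-cycle) and back; the wall thickens in antiphase.  Returns
    the rendered image stack and the exact endo/epi contours.
    """
    from .cardiac_metrics import VentricularContours

    if config.esv_ml > config.edv_ml:
        raise ValueError("esv_ml must not exceed edv_ml")
    if config.esv_ml <= 0:
        raise ValueError("esv_ml must be positive")
    rows, cols = config.shape
    sy, sx = config.pixel_spacing_mm
    rng = np.random.default_rng(config.seed)
    dz = config.slice_thickness_mm + config.slice_gap_mm
    phase01 = (1.0 + np.cos(2 * np.pi * np.arange(config.frames) / config.frames)) / 2.0
    vol_t = config.esv_ml + (config.edv_ml - config.esv_ml) * phase01
    th_t = config.wall_thickness_es_mm + (
        config.wall_thickness_ed_mm - config.wall_thickness_es_mm) * phase01

    cx, cy = cols / 2.0, rows / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    d_mm = np.sqrt(((xx - cx) * sx) ** 2 + ((yy - cy) * sy) ** 2)

    voxels = np.empty((rows, cols, config.slices, config.frames))
    endo, epi = {}, {}
    for f in range(config.frames):
        r_endo_mm = np.sqrt(vol_t[f] * 1000.0 / (np.pi * config.slices * dz))
        r_epi_mm = r_endo_mm + th_t[f]
        img = np.full((rows, cols), 0.1)
        img[d_mm <= r_epi_mm] = 0.5
        img[d_mm <= r_endo_mm] = 0.9
        if config.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, config.noise_sd, img.shape), 0.0, 1.0)
        img = np.round(img * 4095.0) / 4095.0  # 12-bit grid, matches DICOM storage
        for s in range(config.slices):
            voxels[:, :, s, f] = img
            endo[(s, f)] = circle_contour(cx, cy, r_endo_mm / sx, n_vertices=96,
                                          slice_index=s, frame_index=f, label="endo")
            epi[(s, f)] = circle_contour(cx, cy, r_epi_mm / sx, n_vertices=96,
                                         slice_index=s, frame_index=f, label="epi")
    stack = ImageStack(voxels, pixel_spacing_mm=config.pixel_spacing_mm,
                       slice_thickness_mm=config.slice_thickness_mm,
                       slice_gap_mm=config.slice_gap_mm,
                       time_increment_s=config.time_increment_s,
                       series_uid="phantom-cine-lv")
    contours = VentricularContours(endo=endo, epi=epi,
                                   slice_thickness_mm=config.slice_thickness_mm,
                                   slice_gap_mm=config.slice_gap_mm,
                                   pixel_spacing_mm=config.pixel_spacing_mm,
                                   time_increment_s=config.time_increment_s)
    return stack, contours


# -- DICOM fixtures --------------------------------------------------------

def write_dicom_fixture(stacks, directory, shuffle_seed: int = 0,
                        corrupt: str | None = None):
    """Write minimal standard-conformant DICOM files in shuffled order.

    One file per (slice, frame); intensities are quantized to the stack's
    stored bit depth, so a write -> load round trip is bit-exact for
    grid-valued stacks.  ``corrupt='missing_pixel_spacing'`` drops the
    PixelSpacing tag from the first written file (for negative tests).
    Returns the intended (series, slice, frame) order of the files.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if isinstance(stacks, ImageStack):
        stacks = [stacks]
    os.makedirs(directory, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise OSError(f"directory {directory!r} is not writable")
    study_uid = generate_uid(entropy_srcs=["cardioflow-study", str(shuffle_seed)])
    entries = []
    for si, stack in enumerate(stacks):
        series_uid = generate_uid(entropy_srcs=["cardioflow-series", str(si)])
        top = (1 << stack.stored_bits) - 1
        normal = stack.slice_normal
        for s in range(stack.slices):
            for f in range(stack.frames):
                ds = Dataset()
                ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.4"  # MR Image Storage
                ds.SOPInstanceUID = generate_uid(
                    entropy_srcs=["cardioflow-sop", str(si), str(s), str(f)])
                ds.StudyInstanceUID = study_uid
                ds.SeriesInstanceUID = series_uid
                ds.Modality = "MR"
                ds.SeriesDescription = f"{stack.image_type} series {si}"
                ds.ImageType = ["ORIGINAL", "PRIMARY",
                                "P" if stack.image_type == "phase" else "M"]
                ds.Rows, ds.Columns = stack.rows, stack.cols
                ds.PixelSpacing = [str(stack.pixel_spacing_mm[0]),
                                   str(stack.pixel_spacing_mm[1])]
                ds.SliceThickness = str(stack.slice_thickness_mm)
                ds.SpacingBetweenSlices = str(stack.slice_step_mm)
                ipp = stack.origin_mm + s * stack.slice_step_mm * normal
                ds.ImagePositionPatient = [f"{x:.10g}" for x in ipp]
                iop = list(stack.col_dir) + list(stack.row_dir)
                ds.ImageOrientationPatient = [f"{x:.10g}" for x in iop]
                ds.TriggerTime = f"{f * stack.time_increment_s * 1000.0:.6f}"
                ds.InstanceNumber = s * stack.frames + f + 1
                ds.SamplesPerPixel = 1
                ds.PhotometricInterpretation = "MONOCHROME2"
                ds.BitsAllocated = 16
                ds.BitsStored = stack.stored_bits
                ds.HighBit = stack.stored_bits - 1
                ds.PixelRepresentation = 0
                ds.RescaleSlope = "1"
                ds.RescaleIntercept = "0"
                raw = np.round(stack.voxels[:, :, s, f] * top).astype(np.uint16)
                ds.PixelData = raw.tobytes()
                entries.append((ds, si, s, f))
    rng = np.random.default_rng(shuffle_seed)
    order = rng.permutation(len(entries))
    written = [None] * len(entries)
    for pos, idx in enumerate(order):
        ds, si, s, f = entries[idx]
        if corrupt == "missing_pixel_spacing" and pos == 0:
            del ds.PixelSpacing
        fname = os.path.join(directory, f"IM_{pos:04d}.dcm")
        meta = Dataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        fds = FileDataset(fname, ds, file_meta=meta, preamble=b"\x00" * 128)
        fds.save_as(fname, enforce_file_format=True)
        written[pos] = (fname, si, s, f)
    return written
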