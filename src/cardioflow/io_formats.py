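"""DICOM loading, the internal exam archive, and CSV export.

The archive (``.sgx``) is a zip container holding a JSON manifest plus
one raw little-endian binary blob per voxel array, so a complete
analysis — images, contours, measurements, annotations — round-trips
bit-for-bit and stays inspectable with standard tools (documented in
``docs/format.md``).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pydicom

from .geometry import AnnotationPoint, Contour
from .stack import ImageStack

__all__ = [
    "ExamArchive",
    "load_dicom_series",
    "save_exam",
    "load_exam",
    "export_csv",
]

ARCHIVE_VERSION = "1.0"
_SPACING_TOL_MM = 1e-3


@dataclass
class ExamArchive:
    """A complete examination: image stacks plus all derived objects."""

    stacks: list = field(default_factory=list)
    contours: list = field(default_factory=list)
    measurements: dict = field(default_factory=dict)
    annotations: list = field(default_factory=list)


# -- DICOM loading ---------------------------------------------------------

def _require(ds, attr: str, fname: str):
    if not hasattr(ds, attr):
        raise ValueError(f"DICOM file {fname!r} is missing required attribute {attr}")
    return getattr(ds, attr)


def load_dicom_series(directory, venc_cm_s: float | None = None) -> list:
    """Read every DICOM file under ``directory`` into sorted image stacks.

    Files are grouped by SeriesInstanceUID; slices are ordered by the
    projection of ImagePositionPatient onto the slice normal and frames
    by TriggerTime.  Missing geometry tags, inconsistent slice spacing
    and duplicate positions are hard errors.  Phase series (ImageType
    third value ``P``) need ``venc_cm_s``.
    """
    import os

    paths = sorted(
        os.path.join(directory, f) for f in os.listdir(directory)
        if os.path.isfile(os.path.join(directory, f))
    )
    datasets = []
    for p in paths:
        try:
            datasets.append((p, pydicom.dcmread(p)))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory!r}")

    series: dict[str, list] = {}
    for p, ds in datasets:
        series.setdefault(str(_require(ds, "SeriesInstanceUID", p)), []).append((p, ds))

    stacks = []
    for uid in sorted(series):
        items = series[uid]
        p0, ds0 = items[0]
        spacing = _require(ds0, "PixelSpacing", p0)
        iop = np.array([float(x) for x in _require(ds0, "ImageOrientationPatient", p0)])
        col_dir, row_dir = iop[:3], iop[3:]
        normal = np.cross(row_dir, col_dir)

        keyed = {}
        for p, ds in items:
            _require(ds, "PixelSpacing", p)
            ipp = np.array([float(x) for x in _require(ds, "ImagePositionPatient", p)])
            pos = float(ipp @ normal)
            t = float(getattr(ds, "TriggerTime", 0.0))
            if (pos, t) in keyed:
                raise ValueError(
                    f"duplicate slice position/time in series {uid}: {pos} mm, {t} ms")
            keyed[(pos, t)] = (p, ds, ipp)

        positions = sorted({pos for pos, _ in keyed})
        times = sorted({t for _, t in keyed})
        if len(keyed) != len(positions) * len(times):
            raise ValueError(
                f"series {uid} has an incomplete slice/frame grid "
                f"({len(keyed)} files for {len(positions)} positions x {len(times)} times)")
        if len(positions) > 1:
            steps = np.diff(positions)
            if np.ptp(steps) > _SPACING_TOL_MM:
                raise ValueError(
                    f"inconsistent slice spacing in series {uid}: "
                    f"measured steps {steps.tolist()} mm")

        bits = int(getattr(ds0, "BitsStored", 16))
        rows, cols = int(ds0.Rows), int(ds0.Columns)
        voxels = np.empty((rows, cols, len(positions), len(times)))
        for si, pos in enumerate(positions):
            for fi, t in enumerate(times):
                p, ds, _ = keyed[(pos, t)]
                raw = ds.pixel_array.astype(np.float64)
                slope = float(getattr(ds, "RescaleSlope", 1.0))
                intercept = float(getattr(ds, "RescaleIntercept", 0.0))
                voxels[:, :, si, fi] = (raw * slope + intercept) / ((1 << bits) - 1)

        image_type = "magnitude"
        itype = getattr(ds0, "ImageType", None)
        if itype is not None and len(itype) > 2 and str(itype[2]).upper().startswith("P"):
            image_type = "phase"
            if venc_cm_s is None:
                raise ValueError(
                    f"series {uid} is a phase series; pass venc_cm_s to load it")
        origin = keyed[(positions[0], times[0])][2]
        if len(positions) > 1:
            slice_step = float(np.mean(np.diff(positions)))
        else:
            slice_step = float(getattr(ds0, "SpacingBetweenSlices",
                                       getattr(ds0, "SliceThickness", 1.0)))
        thickness = float(getattr(ds0, "SliceThickness", slice_step))
        stacks.append(ImageStack(
            voxels=voxels,
            pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
            slice_thickness_mm=thickness,
            slice_gap_mm=max(0.0, slice_step - thickness),
            time_increment_s=(times[1] - times[0]) / 1000.0 if len(times) > 1 else 0.0,
            image_type=image_type,
            venc_cm_s=venc_cm_s if image_type == "phase" else None,
            origin_mm=origin,
            row_dir=row_dir,
            col_dir=col_dir,
            series_uid=uid,
            stored_bits=bits,
        ))
    return stacks


# -- exam archive ----------------------------------------------------------

def _stack_meta(stack: ImageStack, blob: str) -> dict:
    return {
        "blob": blob,
        "dtype": "<f8",
        "shape": list(stack.voxels.shape),
        "pixel_spacing_mm": list(stack.pixel_spacing_mm),
        "slice_thickness_mm": stack.slice_thickness_mm,
        "slice_gap_mm": stack.slice_gap_mm,
        "time_increment_s": stack.time_increment_s,
        "image_type": stack.image_type,
        "venc_cm_s": stack.venc_cm_s,
        "origin_mm": stack.origin_mm.tolist(),
        "row_dir": stack.row_dir.tolist(),
        "col_dir": stack.col_dir.tolist(),
        "series_uid": stack.series_uid,
        "stored_bits": stack.stored_bits,
    }


def save_exam(archive: ExamArchive, path) -> None:
    """Write a complete exam to a ``.sgx`` zip archive."""
    manifest = {
        "format": "cardioflow-exam",
        "version": ARCHIVE_VERSION,
        "stacks": [],
        "contours": [c.to_json_dict() for c in archive.contours],
        "measurements": archive.measurements,
        "annotations": [
            {"position": list(a.position), "frame": a.frame, "label": a.label}
            for a in archive.annotations
        ],
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for i, stack in enumerate(archive.stacks):
            blob = f"stack_{i}.f8"
            manifest["stacks"].append(_stack_meta(stack, blob))
            zf.writestr(blob, np.ascontiguousarray(stack.voxels, dtype="<f8").tobytes())
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))


def load_exam(path) -> ExamArchive:
    """Read a ``.sgx`` archive; bit-for-bit inverse of :func:`save_exam`."""
    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as exc:
        raise ValueError(f"archive {path!r} is truncated or not a zip file") from exc
    with zf:
        if zf.testzip() is not None:
            raise ValueError(f"archive {path!r} failed its integrity check")
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("version") != ARCHIVE_VERSION:
            raise ValueError(
                f"unsupported archive version {manifest.get('version')!r}; "
                f"this build reads version {ARCHIVE_VERSION}")
        stacks = []
        for meta in manifest["stacks"]:
            raw = np.frombuffer(zf.read(meta["blob"]), dtype=meta["dtype"])
            stacks.append(ImageStack(
                voxels=raw.reshape(meta["shape"]).copy(),
                pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
                slice_thickness_mm=meta["slice_thickness_mm"],
                slice_gap_mm=meta["slice_gap_mm"],
                time_increment_s=meta["time_increment_s"],
                image_type=meta["image_type"],
                venc_cm_s=meta["venc_cm_s"],
                origin_mm=np.array(meta["origin_mm"]),
                row_dir=np.array(meta["row_dir"]),
                col_dir=np.array(meta["col_dir"]),
                series_uid=meta["series_uid"],
                stored_bits=meta["stored_bits"],
            ))
    return ExamArchive(
        stacks=stacks,
        contours=[Contour.from_json_dict(d) for d in manifest["contours"]],
        measurements=manifest["measurements"],
        annotations=[
            AnnotationPoint(position=tuple(a["position"]), frame=a["frame"],
                            label=a["label"])
            for a in manifest["annotations"]
        ],
    )


# -- CSV export ------------------------------------------------------------

def export_csv(table, path) -> None:
    """Write a rectangular table of named columns as RFC-4180 CSV.

    Floats are written with 17 significant digits so a re-parse
    reproduces them exactly.
    """
    if isinstance(table, dict):
        lengths = {k: len(v) for k, v in table.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"ragged columns: {lengths}")
        table = pd.DataFrame(table)
    if not isinstance(table, pd.DataFrame):
        raise TypeError("table must be a dict of columns or a DataFrame")
    table.to_csv(path, index=False, float_format="%.17g", lineterminator="\r\n")
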