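"""Image stack container with patient-space geometry.

An :class:`ImageStack` holds a 2D / 2D+T / 3D / 3D+T voxel block together
with the geometry metadata needed to map voxel indices to patient
coordinates.  MR intensities are kept as doubles scaled into ``[0, 1]``
(the stored integer range is remembered so the scaling is invertible);
CT voxels are signed Hounsfield units converted to float before any
arithmetic.

Coordinate convention (used package-wide): indices are 0-based, a pixel's
center sits at integer ``(row, col)``, and continuous in-plane coordinates
are in pixel units unless the name carries an ``_mm`` suffix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]

_ORTHO_TOL = 1e-6


@dataclass
class ImageStack:
    """A voxel block indexed ``(row, col, slice, frame)`` plus geometry.

    Parameters
    ----------
    voxels:
        Array of shape ``(rows, cols, slices, frames)``.  MR data must lie
        in ``[0, 1]``; CT data are Hounsfield units.
    pixel_spacing_mm:
        In-plane spacing ``(row, col)`` in millimetres.
    slice_thickness_mm, slice_gap_mm:
        Through-plane geometry; slice centers are ``thickness + gap`` apart.
    time_increment_s:
        Time between frames; required positive when there is more than one
        frame.
    image_type:
        One of ``"magnitude"``, ``"phase"``, ``"ct"``.
    venc_cm_s:
        Velocity-encoding limit; required for phase stacks.
    origin_mm, row_dir, col_dir:
        Patient-space position of voxel ``(0, 0, 0)`` and unit direction
        cosines along increasing row / column index.
    stored_bits:
        Bit depth of the integer representation the ``[0, 1]`` scaling
        refers to (lossless round trip to ``2**stored_bits - 1`` levels).
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    slice_gap_mm: float = 0.0
    time_increment_s: float = 0.0
    image_type: str = "magnitude"
    venc_cm_s: float | None = None
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    row_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    col_dir: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    series_uid: str = ""
    stored_bits: int = 12

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[:, :, None, None]
        elif self.voxels.ndim == 3:
            self.voxels = self.voxels[:, :, :, None]
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 2D, 3D or 4D (row, col, slice, frame)")
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        self.row_dir = np.asarray(self.row_dir, dtype=np.float64)
        self.col_dir = np.asarray(self.col_dir, dtype=np.float64)
        self.pixel_spacing_mm = (float(self.pixel_spacing_mm[0]), float(self.pixel_spacing_mm[1]))

        if self.image_type not in ("magnitude", "phase", "ct"):
            raise ValueError(f"unknown image_type {self.image_type!r}")
        if self.image_type == "phase":
            if self.venc_cm_s is None or self.venc_cm_s <= 0:
                raise ValueError("phase stacks require a positive venc_cm_s")
        if self.image_type != "ct":
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1e-12 or hi > 1 + 1e-12:
                raise ValueError(
                    f"MR intensities must lie in [0, 1]; got range [{lo:g}, {hi:g}]"
                )
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")
        if self.frames > 1 and self.time_increment_s <= 0:
            raise ValueError("time_increment_s must be positive for multi-frame stacks")
        for name, v in (("row_dir", self.row_dir), ("col_dir", self.col_dir)):
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise ValueError(f"{name} must be unit length")
        if abs(float(np.dot(self.row_dir, self.col_dir))) > _ORTHO_TOL:
            raise ValueError("row_dir and col_dir must be orthogonal")

    # -- shape accessors ---------------------------------------------------
    @property
    def rows(self) -> int:
        return self.voxels.shape[0]

    @property
    def cols(self) -> int:
        return self.voxels.shape[1]

    @property
    def slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def frames(self) -> int:
        return self.voxels.shape[3]

    @property
    def slice_step_mm(self) -> float:
        """Center-to-center slice distance."""
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def slice_normal(self) -> np.ndarray:
        return np.cross(self.row_dir, self.col_dir)

    # -- geometry ----------------------------------------------------------
    def index_to_patient_mm(self, row, col, slc=0.0) -> np.ndarray:
        """Map (possibly fractional) voxel indices to patient coordinates."""
        row = np.asarray(row, dtype=np.float64)
        col = np.asarray(col, dtype=np.float64)
        slc = np.asarray(slc, dtype=np.float64)
        dr, dc = self.pixel_spacing_mm
        return (
            self.origin_mm
            + np.multiply.outer(row * dr, self.row_dir)
            + np.multiply.outer(col * dc, self.col_dir)
            + np.multiply.outer(slc * self.slice_step_mm, self.slice_normal)
        )

    def patient_to_index(self, point_mm) -> np.ndarray:
        """Inverse of :meth:`index_to_patient_mm`; returns (row, col, slice)."""
        p = np.asarray(point_mm, dtype=np.float64) - self.origin_mm
        dr, dc = self.pixel_spacing_mm
        basis = np.stack(
            [self.row_dir * dr, self.col_dir * dc, self.slice_normal * self.slice_step_mm],
            axis=1,
        )
        return np.linalg.solve(basis, p.T).T

    # -- intensity scaling -------------------------------------------------
    def to_stored_integers(self) -> np.ndarray:
        """Invert the [0, 1] scaling back to the stored integer range."""
        if self.image_type == "ct":
            return np.round(self.voxels).astype(np.int16)
        top = (1 << self.stored_bits) - 1
        return np.round(self.voxels * top).astype(np.int32)

    @staticmethod
    def scale_stored(raw: np.ndarray, stored_bits: int) -> np.ndarray:
        """Scale stored unsigned integers into the [0, 1] MR range."""
        top = (1 << stored_bits) - 1
        return np.asarray(raw, dtype=np.float64) / top

    def frame_time_s(self, frame: int) -> float:
        return frame * self.time_increment_s
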