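"""Core in-memory containers for 4D BOLD data and motion parameters.

A :class:`VolumeSeries` is the unit every voxelwise stage consumes and
produces: a masked 4D scalar field together with the repetition time and
the voxel-to-world affine. Motion parameters are the realignment output of
a scanner session: three translations (mm) and three rotations (degrees)
per retained timepoint.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries", "MotionParams"]


@dataclass
class VolumeSeries:
    """A 4D BOLD series (x, y, z, t) with acquisition metadata.

    Parameters
    ----------
    data:
        4D array, arbitrary signal units.
    tr:
        Repetition time in seconds.
    affine:
        4x4 invertible voxel-to-world map (mm).
    mask:
        3D boolean analysis mask; defaults to all-true.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least two timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must equal spatial shape")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm, from the affine columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "VolumeSeries":
        return replace(self, data=np.asarray(data, dtype=float))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = tuple(self.voxel_size_mm) + (self.tr,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        tr: float | None = None,
        mask: np.ndarray | None = None,
    ) -> "VolumeSeries":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        if tr is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or zooms[3] <= 0:
                raise ValueError("TR not stored in header; pass tr explicitly")
            tr = float(zooms[3])
        return cls(data=data, tr=tr, affine=img.affine, mask=mask)


@dataclass
class MotionParams:
    """T x 6 realignment parameters: translations x/y/z (mm), rotations (deg)."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.atleast_2d(np.asarray(self.table, dtype=float))
        if self.table.shape[0] == 0 or self.table.shape[1] != 6:
            raise ValueError("motion table must be non-empty with 6 columns")

    @property
    def n_timepoints(self) -> int:
        return self.table.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.table[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.table[:, 3:]

    def mean_framewise_displacement(self, head_radius_mm: float = 50.0) -> float:
        """Mean Power-style framewise displacement.

        Sum of absolute frame-to-frame translation changes plus rotation
        changes converted to arc length on a sphere of ``head_radius_mm``.
        """
        d_trans = np.abs(np.diff(self.translations_mm, axis=0))
        d_rot = np.abs(np.diff(np.deg2rad(self.rotations_deg), axis=0)) * head_radius_mm
        fd = d_trans.sum(axis=1) + d_rot.sum(axis=1)
        return float(fd.mean()) if fd.size else 0.0

    def save(self, path: str | Path) -> None:
        np.savetxt(str(path), self.table, fmt="%.6f")

    @classmethod
    def load(cls, path: str | Path) -> "MotionParams":
        return cls(np.loadtxt(str(path)))
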