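"""Geometry-aware image volumes and DICOM series I/O.

Array convention
----------------
Voxel arrays are stored with shape ``(n0, n1, n2)`` where axis 0 runs along
the slice normal, axis 1 along image rows and axis 2 along image columns
(the usual slice/row/column layout of a DICOM stack).  All voxel *index*
vectors in this package follow the same ``(i0, i1, i2)`` array order.  World
coordinates are the DICOM patient coordinates ``(x, y, z)`` in millimeters.

Index ``(0, 0, 0)`` refers to the CENTER of the first voxel, and fractional
indices are meaningful everywhere: all sub-voxel sphere centers are either
fractional indices or millimeter world points.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom

from .errors import (
    IrregularSeriesError,
    MalformedSeriesError,
    NonOrthogonalSlicesError,
)

__all__ = [
    "ImageVolume",
    "RigidTransform",
    "load_series",
    "check_orthogonal",
    "dicom_isometry",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid isometry ``x -> rotation @ x + translation`` in mm.

    ``label`` distinguishes the three isometries the pipeline works with:
    ``DICOM`` (header-derived), ``ESTIMATE`` (initial three-point fit) and
    ``OPTIMAL`` (result of the six-degree-of-freedom search).
    """

    rotation: np.ndarray
    translation: np.ndarray
    label: str = "ESTIMATE"

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal to 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1 (improper isometry)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, label: str = "DICOM") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), label=label)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point or an ``(n, 3)`` stack of points (mm)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points)

    def inverse(self, label: str | None = None) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, label=label or self.label)

    def compose(self, other: "RigidTransform", label: str | None = None) -> "RigidTransform":
        """Return ``self after other``: ``x -> self(other(x))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            label=label or self.label,
        )


@dataclass
class ImageVolume:
    """A single-modality scalar volume with its acquisition geometry.

    ``orientation`` has the world direction of array axis ``a`` in column
    ``a`` (column 0 = slice normal, column 1 = row direction, column 2 =
    column direction).  ``origin`` is the world position (mm) of the center
    of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray
    modality: str = "CT"
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxel grid must be a non-empty 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("all voxel spacings must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        M = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if not np.allclose(M.T @ M, np.eye(3), atol=1e-6):
            raise ValueError("orientation columns must be orthonormal")
        self.orientation = M

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def voxel_to_world(self, index) -> np.ndarray:
        """World position (mm) of a fractional voxel index (array order)."""
        idx = np.asarray(index, dtype=float)
        return (idx * self.spacing) @ self.orientation.T + self.origin

    def world_to_voxel(self, point) -> np.ndarray:
        """Exact inverse of :meth:`voxel_to_world` (fractional indices)."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.orientation) / self.spacing

    def contains_index(self, index) -> bool:
        idx = np.asarray(index, dtype=float)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.shape) - 1))


def check_orthogonal(volume: ImageVolume, tol: float = 1e-6) -> bool:
    """Verify slices are orthogonal to the patient axes.

    The row and column direction cosines (the entries a DICOM header stores
    in Image Orientation Patient) must each be one of {-1, 0, +1}.  On
    failure a :class:`NonOrthogonalSlicesError` is raised so the pipeline
    can report and terminate, matching the original algorithm's behaviour.
    """
    inplane = volume.orientation[:, 1:]
    nearest = np.round(inplane)
    ok = np.all(np.abs(inplane - nearest) <= tol) and np.all(np.abs(nearest) <= 1)
    if not ok:
        raise NonOrthogonalSlicesError(inplane.T.tolist())
    return True


def dicom_isometry(ct: ImageVolume, pet: ImageVolume) -> RigidTransform:
    """Header-derived CT-world -> PET-world isometry (``Phi_DICOM``).

    Both series are assumed to share a DICOM frame of reference, in which
    case the patient coordinate systems coincide and the header isometry is
    the identity on world coordinates; any header misalignment is expressed
    through each series' own origin/orientation.
    """
    return RigidTransform.identity(label="DICOM")


_REQUIRED_TAGS = ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing")


def _series_files(path) -> list:
    if isinstance(path, (str, os.PathLike)):
        p = Path(path)
        if p.is_dir():
            files = sorted(f for f in p.iterdir() if f.is_file() and f.suffix.lower() in {".dcm", ".ima", ""})
            if not files:
                files = sorted(f for f in p.iterdir() if f.is_file())
            return list(files)
        return [p]
    return [Path(f) for f in path]


def load_series(path) -> ImageVolume:
    """Read a single-modality DICOM series into an :class:`ImageVolume`.

    Slices are sorted by the projection of Image Position (Patient) onto
    the slice normal (robust to renumbered or shuffled exports).  Vendor
    rescale slope/intercept are applied, so CT voxels come back in HU and
    PET voxels in the stored activity-proportional units.

    Raises
    ------
    MalformedSeriesError
        if geometry tags are missing or inconsistent within the series.
    IrregularSeriesError
        if inter-slice spacing varies by more than 1%.
    """
    files = _series_files(path)
    if not files:
        raise MalformedSeriesError(f"no DICOM files found under {path!r}")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:  # pragma: no cover - passthrough detail
            raise MalformedSeriesError(f"cannot read {f}: {exc}") from exc
        for tag in _REQUIRED_TAGS:
            if getattr(ds, tag, None) is None:
                raise MalformedSeriesError(f"{f} is missing {tag}: malformed series")
        datasets.append(ds)

    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    for ds in datasets[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float), iop, atol=1e-6):
            raise MalformedSeriesError("inconsistent orientation across slices: malformed series")
    row_dir = iop[:3]   # direction of increasing column index
    col_dir = iop[3:]   # direction of increasing row index
    normal = np.cross(row_dir, col_dir)

    positions = np.array([np.asarray(ds.ImagePositionPatient, dtype=float) for ds in datasets])
    zkeys = positions @ normal
    order = np.argsort(zkeys, kind="stable")
    datasets = [datasets[i] for i in order]
    positions = positions[order]
    zkeys = zkeys[order]

    ps = np.asarray(datasets[0].PixelSpacing, dtype=float)  # (row spacing, col spacing)
    for ds in datasets[1:]:
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float), ps, atol=1e-6):
            raise MalformedSeriesError("inconsistent pixel spacing: malformed series")

    if len(datasets) > 1:
        dz = np.diff(zkeys)
        if np.any(dz <= 0):
            raise IrregularSeriesError("duplicate or non-increasing slice positions: irregular series")
        mean_dz = float(np.mean(dz))
        if np.any(np.abs(dz - mean_dz) > 0.01 * mean_dz):
            raise IrregularSeriesError(
                f"inter-slice spacing varies beyond 1% (found steps {dz.min():.4g}..{dz.max():.4g} mm): "
                "irregular series"
            )
        slice_spacing = mean_dz
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)

    orientation = np.column_stack([normal, col_dir, row_dir])
    spacing = np.array([slice_spacing, ps[0], ps[1]])
    modality = str(getattr(datasets[0], "Modality", "CT") or "CT")
    if modality == "PT":
        modality = "PET"
    return ImageVolume(
        voxels=voxels,
        spacing=spacing,
        origin=positions[0],
        orientation=orientation,
        modality=modality,
    )
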