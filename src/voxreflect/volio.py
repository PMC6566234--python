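"""Volumetric MRI containers and I/O.

A :class:`Volume3D` is a 3D scalar signal grid with full physical geometry:
voxel index ``(i, j, k)`` maps to the physical point (mm)

    p = origin + direction @ (spacing * index)

with ``direction`` an orthonormal 3x3 cosine matrix.  Invalid voxels (outside
a resampling domain, flagged by upstream stages) are carried as an explicit
boolean ``valid`` mask, never as magic numbers, so that they can be excluded
from the reflectivity sums downstream.

NIfTI round trips go through nibabel; DICOM series through pydicom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "read_nifti",
    "write_nifti",
    "read_dicom_series",
    "write_dicom_series",
    "normalize_by_water",
]

_ORTHO_TOL = 1e-6


@dataclass
class Volume3D:
    """A 3D scalar MRI signal field with physical geometry and metadata."""

    values: np.ndarray
    spacing: np.ndarray  # mm, shape (3,)
    origin: np.ndarray = None  # mm, shape (3,)
    direction: np.ndarray = None  # 3x3 orthonormal
    meta: dict = field(default_factory=dict)
    valid: np.ndarray | None = None  # bool mask; None means all valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("grid needs at least 1 voxel per axis")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float).reshape(3)
        )
        self.direction = (
            np.eye(3) if self.direction is None else np.asarray(self.direction, dtype=float).reshape(3, 3)
        )
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix must be orthonormal within 1e-6")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape must match values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of usable voxels (finite and not flagged invalid)."""
        m = np.isfinite(self.values)
        if self.valid is not None:
            m &= self.valid
        return m

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to physical mm."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return ((pts - self.origin) @ self.direction) / self.spacing

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.index_to_physical(idx)

    def copy(self) -> "Volume3D":
        return Volume3D(
            self.values.copy(),
            self.spacing.copy(),
            self.origin.copy(),
            self.direction.copy(),
            dict(self.meta),
            None if self.valid is None else self.valid.copy(),
        )

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-physical affine (NIfTI convention)."""
        A = np.eye(4)
        A[:3, :3] = self.direction @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A


def _decompose_affine(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    M = A[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate affine: zero-length column")
    direction = M / spacing
    return spacing, A[:3, 3].copy(), direction


def write_nifti(volume: Volume3D, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values, volume.affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got ndim={data.ndim}: {path}")
    spacing, origin, direction = _decompose_affine(img.affine)
    return Volume3D(data, spacing, origin, direction, meta={"source": str(path)})


# --------------------------------------------------------------------------
# DICOM single-frame series
# --------------------------------------------------------------------------

_MR_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.4"


def write_dicom_series(
    volume: Volume3D,
    directory: str | Path,
    series_description: str = "voxreflect",
) -> list[Path]:
    """Write a volume as a single-frame DICOM series, one file per k-slice.

    Integer-valued data in [0, 65535] is stored losslessly with rescale
    slope 1; other data is linearly quantized to 16 bits with the rescale
    slope/intercept recording the mapping.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vals = volume.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("cannot write non-finite voxel values to DICOM")
    integral = np.all(vals == np.round(vals)) and vals.min() >= 0 and vals.max() <= 65535
    if integral:
        slope, intercept = 1.0, 0.0
        stored = np.round(vals).astype(np.uint16)
    else:
        lo, hi = float(vals.min()), float(vals.max())
        slope = (hi - lo) / 65535.0 if hi > lo else 1.0
        intercept = lo
        stored = np.round((vals - intercept) / slope).astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    row_dir = volume.direction[:, 0]  # along increasing column index i
    col_dir = volume.direction[:, 1]  # along increasing row index j
    paths = []
    for k in range(volume.shape[2]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = _MR_SOP_CLASS
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = _MR_SOP_CLASS
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.SeriesDescription = series_description
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [*map(float, row_dir), *map(float, col_dir)]
        ds.ImagePositionPatient = [float(x) for x in volume.index_to_physical([0, 0, k])]
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[0])]
        ds.SliceThickness = float(volume.spacing[2])
        ds.SpacingBetweenSlices = float(volume.spacing[2])
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        if "tr_ms" in volume.meta:
            ds.RepetitionTime = float(volume.meta["tr_ms"])
        if "te_ms" in volume.meta:
            ds.EchoTime = float(volume.meta["te_ms"])
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        p = directory / f"slice_{k:04d}.dcm"
        pydicom.dcmwrite(str(p), ds, enforce_file_format=True)
        paths.append(p)
    return paths


def read_dicom_series(path: str | Path) -> Volume3D:
    """Read one single-frame DICOM series from a directory.

    Slices are sorted by their position along the slice normal (so the file
    order on disk is irrelevant), rescale slope/intercept is applied, and the
    geometry (spacing, origin, direction) is taken from the header.  TR/TE
    are captured into ``meta`` when present.
    """
    import pydicom

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM image files found in {path}")
    uids = {str(getattr(ds, "SeriesInstanceUID", "<missing>")) for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"directory contains multiple series UIDs: {sorted(uids)}")
    for tag in ("ImageOrientationPatient", "ImagePositionPatient", "PixelSpacing"):
        missing = [i for i, ds in enumerate(datasets) if not hasattr(ds, tag)]
        if missing:
            raise ValueError(f"missing spatial tag {tag} in {len(missing)} slice(s)")

    iop = np.array(datasets[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, float), normal)))

    positions = np.array([ds.ImagePositionPatient for ds in datasets], dtype=float)
    if len(datasets) > 1:
        steps = np.diff(positions @ normal)
        dz = float(np.mean(steps))
        if dz <= 0 or np.ptp(steps) > 1e-3 * abs(dz):
            raise ValueError("inconsistent slice spacing along the series normal")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    ps = np.array(datasets[0].PixelSpacing, dtype=float)  # [row, col]
    spacing = np.array([ps[1], ps[0], dz])
    direction = np.column_stack([row_dir, col_dir, normal])

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # pixel_array is (Rows, Cols) = (j, i); internal order is (i, j, k)
    values = np.stack([s.T for s in slices], axis=2)

    meta: dict = {"source": str(path)}
    if hasattr(datasets[0], "RepetitionTime"):
        meta["tr_ms"] = float(datasets[0].RepetitionTime)
    if hasattr(datasets[0], "EchoTime"):
        meta["te_ms"] = float(datasets[0].EchoTime)
    if hasattr(datasets[0], "SeriesDescription"):
        meta["series_description"] = str(datasets[0].SeriesDescription)
    return Volume3D(values, spacing, positions[0], direction, meta=meta)


# --------------------------------------------------------------------------
# Water normalization
# --------------------------------------------------------------------------


def normalize_by_water(volume: Volume3D, water_mask: np.ndarray) -> Volume3D:
    """Divide every voxel by the mean signal inside the water-tube mask.

    Each scan carries one tube of pure water; dividing by its mean signal
    puts scans acquired with different receiver gains on a common scale.
    The water mean is recorded in the result's provenance metadata.
    """
    mask = np.asarray(getattr(water_mask, "mask", water_mask), dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("water mask shape does not match volume")
    usable = mask & volume.valid_mask()
    if not usable.any():
        raise ValueError("water mask is empty (or fully invalid)")
    water_mean = float(volume.values[usable].mean())
    if not water_mean > 0:
        raise ValueError(f"water mean signal must be positive, got {water_mean}")
    out = volume.copy()
    out.values = out.values / water_mean
    out.meta["water_mean"] = water_mean
    return out
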