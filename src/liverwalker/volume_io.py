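"""Reading and writing CT volumes and label masks.

A CT series (DICOM directory or NIfTI file) is loaded into a canonical
:class:`CTVolume`: a ``(slice, row, col)`` stack of Hounsfield-unit
intensities with the slices ordered superior -> inferior, plus voxel
spacing in millimetres.  Display windowing maps HU to ``[0, 1]`` with the
usual clamped linear ramp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pydicom


class VolumeLoadError(Exception):
    """Raised when a CT series cannot be read into a canonical volume."""


@dataclass
class CTVolume:
    """Axial CT stack in Hounsfield units.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Intensities in HU; slice 0 is the most superior.
    spacing : tuple of float
        (slice thickness, row spacing, col spacing) in mm; all positive.
    superior_to_inferior : bool
        True once slices are in canonical order (loaders re-sort).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    superior_to_inferior: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (slice, row, col) array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class WindowSettings:
    """CT display window (level/width, HU).  Default: abdominal 40/400."""

    level: float = 40.0
    width: float = 400.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")


def apply_window(volume: CTVolume | np.ndarray, window: WindowSettings) -> np.ndarray:
    """Map HU to display intensities in [0, 1] with a clamped linear ramp.

    Values at or below ``level - width/2`` map to 0, at or above
    ``level + width/2`` map to 1, linear in between.  Monotone
    non-decreasing in HU.
    """
    hu = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    lo = window.level - window.width / 2.0
    out = (hu.astype(np.float64) - lo) / window.width
    return np.clip(out, 0.0, 1.0)


def _load_nifti(path: str) -> CTVolume:
    img = nib.load(path)
    img = nib.as_closest_canonical(img)  # RAS+: axes (x=L->R, y=P->A, z=I->S)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeLoadError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # canonical stack: slice axis first, superior first -> reverse z
    voxels = np.transpose(data, (2, 1, 0))[::-1].copy()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels=voxels, spacing=spacing)


def _load_dicom_dir(path: str) -> CTVolume:
    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    if not files:
        raise VolumeLoadError(f"{path}: no files in DICOM directory")
    slices = []
    series_uid = None
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:  # non-DICOM stray file
            raise VolumeLoadError(f"{f}: not readable as DICOM ({exc})") from exc
        uid = getattr(ds, "SeriesInstanceUID", None)
        if series_uid is None:
            series_uid = uid
        elif uid != series_uid:
            raise VolumeLoadError(f"{f}: belongs to a different series ({uid})")
        orient = getattr(ds, "ImageOrientationPatient", None)
        if orient is not None:
            normal = np.cross(np.asarray(orient[:3], float), np.asarray(orient[3:], float))
            if abs(normal[2]) < 0.99:
                raise VolumeLoadError(f"{f}: non-axial acquisition is unsupported")
        slices.append((f, ds))
    # sort superior -> inferior: descending z position (fallback: InstanceNumber)
    def sort_key(item):
        ds = item[1]
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return -float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    arrays = []
    for f, ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise VolumeLoadError(f"{path}: slices have mixed in-plane shapes {shapes}")
    ds0 = slices[0][1]
    px = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    if len(slices) > 1:
        try:
            z0 = float(slices[0][1].ImagePositionPatient[2])
            z1 = float(slices[1][1].ImagePositionPatient[2])
            dz = abs(z0 - z1) or float(getattr(ds0, "SliceThickness", 1.0))
        except AttributeError:
            dz = float(getattr(ds0, "SliceThickness", 1.0))
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    return CTVolume(
        voxels=np.stack(arrays),
        spacing=(dz, float(px[0]), float(px[1])),
    )


def load_ct_series(path: str, format: str | None = None) -> CTVolume:
    """Load a CT series into a canonical HU volume.

    Parameters
    ----------
    path : str
        NIfTI file (``.nii``/``.nii.gz``) or a directory of DICOM slices
        from a single series.
    format : {"dicom-dir", "nifti"}, optional
        Forced format; inferred from ``path`` when omitted.
    """
    if not os.path.exists(path):
        raise VolumeLoadError(f"{path}: does not exist")
    if format is None:
        format = "dicom-dir" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom-dir":
        return _load_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}; expected 'dicom-dir' or 'nifti'")


def _reference_affine(reference: CTVolume) -> np.ndarray:
    dz, dr, dc = reference.spacing
    # inverse of the canonical (slice,row,col) <- RAS+ transpose/flip
    affine = np.diag([dc, dr, dz, 1.0])
    return affine


def write_mask(mask: np.ndarray, reference: CTVolume, path: str) -> None:
    """Write a label volume as NIfTI in the reference geometry.

    Round-trips through :func:`load_ct_series` bit-exactly for integer
    labels.
    """
    mask = np.asarray(mask)
    if mask.shape != reference.shape:
        raise ValueError(f"mask shape {mask.shape} != reference shape {reference.shape}")
    dtype = np.uint8 if mask.max(initial=0) < 256 and mask.min(initial=0) >= 0 else np.uint16
    # undo the canonical transform: (slice,row,col), superior-first -> RAS+
    data = np.transpose(mask[::-1], (2, 1, 0)).astype(dtype)
    img = nib.Nifti1Image(data, _reference_affine(reference))
    img.header.set_zooms((reference.spacing[2], reference.spacing[1], reference.spacing[0]))
    nib.save(img, path)


def write_volume(volume: CTVolume, path: str) -> None:
    """Write a HU volume as NIfTI (float32), canonical geometry."""
    data = np.transpose(volume.voxels[::-1], (2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(data, _reference_affine(volume))
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, path)
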