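"""Reading and writing CT volumes and label volumes.

NIfTI (``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``) go through
SimpleITK; DICOM series directories are read with pydicom so that slice
sorting and consistency checking can be reported precisely.  Everything is
converted into the package's internal ``(x, y, z)`` axis order (see
:mod:`pelviseg.volumes`) and rescaled to Hounsfield units on read.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk

from .errors import FormatError
from .volumes import BinaryMask, CTVolume, LabelVolume

_SITK_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    raise FormatError(f"cannot infer image format from '{path}'")


def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume from NIfTI, MetaImage or a DICOM series directory.

    Parameters
    ----------
    path:
        File path (NIfTI/MetaImage) or directory (DICOM series).
    format:
        One of ``nifti``, ``metaimage``, ``dicom_dir``; inferred from the
        path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    fmt = format or _infer_format(path)
    if fmt == "dicom_dir":
        return _read_dicom_dir(path)
    if fmt in ("nifti", "metaimage"):
        return _read_sitk(path)
    raise FormatError(f"unknown format '{fmt}'")


def _read_sitk(path: Path) -> CTVolume:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D image, got {img.GetDimension()}D in {path}")
    # sitk arrays are indexed (z, y, x); transpose to internal (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return CTVolume(data.astype(np.float32), tuple(img.GetSpacing()),
                    tuple(img.GetOrigin()), direction)


def _read_dicom_dir(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:  # non-DICOM files in the directory are skipped
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no DICOM images found in {path}")

    first = datasets[0]
    rows, cols = int(first.Rows), int(first.Columns)
    pix_spacing = [float(v) for v in first.PixelSpacing]  # (row=y, col=x)
    orientation = [float(v) for v in first.ImageOrientationPatient]
    for ds in datasets[1:]:
        if (int(ds.Rows), int(ds.Columns)) != (rows, cols):
            raise FormatError("inconsistent DICOM series: mixed Rows/Columns")
        if not np.allclose([float(v) for v in ds.PixelSpacing], pix_spacing, atol=1e-5):
            raise FormatError("inconsistent DICOM series: mixed PixelSpacing")
        if not np.allclose([float(v) for v in ds.ImageOrientationPatient], orientation,
                           atol=1e-5):
            raise FormatError("inconsistent DICOM series: mixed ImageOrientationPatient")

    row_dir = np.asarray(orientation[:3])
    col_dir = np.asarray(orientation[3:])
    normal = np.cross(row_dir, col_dir)
    # sort slices by position along the slice normal
    datasets.sort(key=lambda ds: float(np.dot(normal, [float(v) for v in
                                                       ds.ImagePositionPatient])))
    positions = np.array([np.dot(normal, [float(v) for v in ds.ImagePositionPatient])
                          for ds in datasets])
    if len(datasets) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0):
            raise FormatError("inconsistent DICOM series: duplicate slice positions")
        if not np.allclose(steps, steps[0], atol=1e-3):
            raise FormatError("inconsistent DICOM series: non-uniform slice spacing")
        z_step = float(steps[0])
    else:
        z_step = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        slices.append(arr * slope + intercept)  # rows=y, cols=x
    # stack to (z, y, x) then transpose to (x, y, z)
    data = np.stack(slices, axis=0).transpose(2, 1, 0)

    spacing = (pix_spacing[1], pix_spacing[0], z_step)
    origin = tuple(float(v) for v in datasets[0].ImagePositionPatient)
    direction = np.column_stack([row_dir, col_dir, normal])
    return CTVolume(data, spacing, origin, direction)


def write_volume(vol: CTVolume | LabelVolume | BinaryMask, path: str | os.PathLike,
                 format: str | None = None) -> None:
    """Write a volume to NIfTI or MetaImage.

    Label volumes and masks are written as unsigned 8-bit integers; CT
    volumes as 32-bit floats.  Geometry metadata is preserved.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    fmt = format or _infer_format(path)
    if fmt not in ("nifti", "metaimage"):
        raise FormatError(f"unsupported output format '{fmt}'")

    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.uint8)
    elif isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)

    img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(np.asarray(vol.direction, dtype=float).ravel()))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    """Read a label volume (codes 0/1/2) written by :func:`write_volume`."""
    vol = read_volume(path)
    return LabelVolume(np.rint(vol.data).astype(np.uint8), vol.spacing, vol.origin,
                       vol.direction)
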