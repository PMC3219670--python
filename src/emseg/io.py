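"""Containers and readers/writers for intensity images and label volumes.

Volumes are handled as NIfTI (``.nii`` / ``.nii.gz``) through nibabel; 2-D
slices additionally as PNG/TIFF through imageio.  Axis order is
``(slice, row, column)`` for 3-D data and ``(row, column)`` for 2-D, with
0-based voxel indexing throughout.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import yaml


class FormatError(ValueError):
    """Raised when a file cannot be read or written in a supported format."""


_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def _suffix(path: pathlib.Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


@dataclass
class ImageVolume:
    """A 2-D or 3-D single-channel intensity array with acquisition metadata.

    ``value_range`` records the raw intensity range before any normalization
    so that fitted parameters can be reported on the original scale.
    """

    data: np.ndarray
    spacing: Optional[tuple] = None
    source_format: str = "array"
    value_range: Optional[tuple] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"image must be 2-D or 3-D, got shape {self.data.shape}")
        if self.data.size == 0:
            raise ValueError("image is empty")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("image contains NaN or Inf values")
        if self.value_range is None:
            self.value_range = (float(self.data.min()), float(self.data.max()))

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer class assignment per pixel with a registry of class ids."""

    labels: np.ndarray
    class_ids: Optional[Sequence[int]] = None
    background_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        present = np.unique(self.labels)
        if self.class_ids is None:
            self.class_ids = [int(c) for c in present]
        else:
            self.class_ids = [int(c) for c in self.class_ids]
            missing = set(present.tolist()) - set(self.class_ids)
            if missing:
                raise ValueError(f"labels contain ids not in class_ids: {sorted(missing)}")

    @property
    def shape(self) -> tuple:
        return self.labels.shape


def normalize_intensity(data: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max normalize intensities to [0, 1]; returns the affine record.

    Constant images map to all-zeros (the range is degenerate and recorded
    as such, so the map is still invertible by convention).
    """
    data = np.asarray(data, dtype=float)
    vmin = float(data.min())
    vmax = float(data.max())
    if vmax > vmin:
        out = (data - vmin) / (vmax - vmin)
    else:
        out = np.zeros_like(data)
    return out, (vmin, vmax)


def read_volume(path, format_hint: Optional[str] = None) -> ImageVolume:
    """Read an intensity image/volume from NIfTI, PNG or TIFF.

    Orientation metadata (the NIfTI affine) is preserved for round-trip
    writing.  Multichannel 2-D images are accepted only when all channels are
    identical (grayscale stored as RGB).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    fmt = format_hint or _suffix(path)
    if fmt in _NIFTI_SUFFIXES:
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises a zoo of types
            raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        vol = ImageVolume(data, spacing=spacing, source_format="nifti",
                          affine=np.asarray(img.affine))
        return vol
    if fmt in _IMAGE_SUFFIXES:
        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise FormatError(f"{path}: not a readable image ({exc})") from exc
        arr = np.asarray(arr)
        if arr.ndim == 3:
            if arr.shape[2] in (3, 4) and all(
                np.array_equal(arr[..., 0], arr[..., c]) for c in range(1, 3)
            ):
                arr = arr[..., 0]
            else:
                raise FormatError(f"{path}: multichannel image is not grayscale")
        return ImageVolume(arr.astype(float), source_format=fmt.lstrip("."))
    raise FormatError(f"{path}: unsupported format {fmt!r}")


def write_volume(path, volume, affine: Optional[np.ndarray] = None) -> None:
    """Write an intensity or label array to NIfTI, PNG or TIFF.

    NIfTI preserves floating-point data exactly.  PNG/TIFF accept integer
    arrays only (use them for labels or pre-quantized images).
    """
    path = pathlib.Path(path)
    if isinstance(volume, ImageVolume):
        data = volume.data
        affine = volume.affine if affine is None else affine
    elif isinstance(volume, LabelVolume):
        data = volume.labels
    else:
        data = np.asarray(volume)
    fmt = _suffix(path)
    if fmt in _NIFTI_SUFFIXES:
        if affine is None:
            affine = np.eye(4)
        out = data
        if np.issubdtype(out.dtype, np.integer):
            out = out.astype(np.int16)
        img = nib.Nifti1Image(out, affine)
        nib.save(img, str(path))
        return
    if fmt in _IMAGE_SUFFIXES:
        if data.ndim != 2:
            raise FormatError(f"{path}: PNG/TIFF writing requires 2-D data")
        if not np.issubdtype(data.dtype, np.integer):
            raise FormatError(
                f"{path}: PNG/TIFF writing requires integer data; use NIfTI for floats"
            )
        if data.min() < 0 or data.max() > 65535:
            raise FormatError(f"{path}: integer data out of uint16 range")
        dtype = np.uint8 if data.max() <= 255 else np.uint16
        iio.imwrite(path, data.astype(dtype))
        return
    raise FormatError(f"{path}: unsupported format {fmt!r}")


def read_labels(path) -> LabelVolume:
    """Read a label volume; values must be non-negative integers."""
    vol = read_volume(path)
    data = vol.data
    if not np.all(data == np.round(data)):
        raise FormatError(f"{path}: label file contains non-integer values")
    return LabelVolume(data.astype(np.int32))


def write_sidecar(path, params: dict) -> None:
    """Write a YAML sidecar recording generation parameters."""
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
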