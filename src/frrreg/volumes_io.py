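"""Reading, writing and preprocessing of 3D scalar volumes.

Volumes are held in ``(z, y, x)`` axis order with 0-based voxel indices.  The
canonical preprocessing pipeline center-crops to the largest cube fitting the
in-plane field of view, resamples trilinearly to a cubic grid (default
96x96x96) and affinely normalizes a Hounsfield-unit window to ``[0, 1]``.  The
window is kept on the :class:`Volume` so that error metrics can be reported in
HU after registration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
import SimpleITK as sitk
import nibabel as nib


class VolumeIOError(Exception):
    """A volume file could not be read or written."""


class UnsupportedFormatError(VolumeIOError):
    """File extension is not NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""


class NotA3DVolumeError(VolumeIOError):
    """The image on disk is not a 3D scalar volume."""


class MissingWindowError(ValueError):
    """Operation requires an intensity window but the volume carries none."""


@dataclass(frozen=True)
class IntensityWindow:
    """Affine intensity window: ``lo_hu`` maps to 0 and ``hi_hu`` to 1."""

    lo_hu: float
    hi_hu: float

    def __post_init__(self):
        if not self.lo_hu < self.hi_hu:
            raise ValueError(f"degenerate window: lo_hu={self.lo_hu} must be < hi_hu={self.hi_hu}")

    def normalize(self, hu: np.ndarray) -> np.ndarray:
        clipped = np.clip(hu, self.lo_hu, self.hi_hu)
        return (clipped - self.lo_hu) / (self.hi_hu - self.lo_hu)

    def denormalize(self, unit: np.ndarray) -> np.ndarray:
        return unit * (self.hi_hu - self.lo_hu) + self.lo_hu


#: default CT soft-tissue-to-bone window used when none is given
DEFAULT_WINDOW = IntensityWindow(-1000.0, 1000.0)
DEFAULT_SHAPE = (96, 96, 96)


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing and an optional intensity window.

    ``data`` is indexed ``(z, y, x)``; ``spacing`` is per-axis physical voxel
    size in mm in the same order.  After :func:`preprocess`, ``data`` lies in
    ``[0, 1]`` and ``window`` records the affine HU map used.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    window: IntensityWindow | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NotA3DVolumeError(f"not a 3D volume: got {self.data.ndim} dimensions")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


_SITK_EXTS = (".nii", ".nii.gz", ".mha", ".mhd")


def _extension(path: str) -> str:
    name = os.fspath(path).lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(name)[1]


def load_volume(path) -> Volume:
    """Read a 3D NIfTI or MetaImage volume; intensities and spacing untouched."""
    ext = _extension(path)
    if ext not in _SITK_EXTS:
        raise UnsupportedFormatError(f"unsupported volume format {ext!r}: {path}")
    try:
        img = sitk.ReadImage(os.fspath(path))
    except Exception as exc:  # noqa: BLE001 — SimpleITK raises bare RuntimeError
        raise VolumeIOError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise NotA3DVolumeError(f"not a 3D volume: {path} has dimension {img.GetDimension()}")
    data = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))  # sitk gives (x, y, z)
    return Volume(data=data, spacing=spacing)


def save_volume(vol: Volume, path) -> None:
    """Write a volume as NIfTI or MetaImage (the window is not persisted)."""
    ext = _extension(path)
    if ext not in _SITK_EXTS:
        raise UnsupportedFormatError(f"unsupported volume format {ext!r}: {path}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    img.SetSpacing(tuple(reversed(vol.spacing)))
    try:
        sitk.WriteImage(img, os.fspath(path))
    except Exception as exc:  # noqa: BLE001
        raise VolumeIOError(f"could not write volume {path}: {exc}") from exc


def _center_crop_cube(data: np.ndarray) -> np.ndarray:
    """Center crop to the largest cube fitting the in-plane (y, x) extent."""
    d, h, w = data.shape
    side = min(h, w)
    zs = min(d, side)
    z0 = (d - zs) // 2
    y0 = (h - side) // 2
    x0 = (w - side) // 2
    return data[z0:z0 + zs, y0:y0 + side, x0:x0 + side]


def _resample(data: np.ndarray, target_shape) -> np.ndarray:
    """Trilinear resample to an exact target shape."""
    if tuple(data.shape) == tuple(target_shape):
        return data
    grids = [np.linspace(0.0, n - 1.0, t) for n, t in zip(data.shape, target_shape)]
    coords = np.meshgrid(*grids, indexing="ij")
    return ndimage.map_coordinates(data, coords, order=1, mode="nearest")


def preprocess(raw: Volume, target_shape=DEFAULT_SHAPE,
               window: IntensityWindow = DEFAULT_WINDOW, crop: bool = True) -> Volume:
    """Crop, resample and window-normalize a raw volume to the canonical grid.

    Intensities are clipped to ``[window.lo_hu, window.hi_hu]`` and mapped
    affinely onto ``[0, 1]``; the window is stored on the result so
    :func:`to_hu` can invert the map.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 2 for t in target_shape):
        raise ValueError(f"target_shape components must be >= 2, got {target_shape}")
    data = _center_crop_cube(raw.data) if crop else raw.data
    pre_shape = data.shape
    data = _resample(data, target_shape)
    data = window.normalize(data)
    new_spacing = tuple(s * n / t for s, n, t in zip(raw.spacing, pre_shape, target_shape))
    return Volume(data=data, spacing=new_spacing, window=window)


def to_hu(v: Volume) -> np.ndarray:
    """Invert the normalization affine map, returning intensities in HU."""
    if v.window is None:
        raise MissingWindowError("volume carries no intensity window; cannot map to HU")
    return v.window.denormalize(v.data)


def with_data(v: Volume, data: np.ndarray) -> Volume:
    """A copy of ``v`` carrying new voxel data (same spacing and window)."""
    return replace(v, data=np.asarray(data))


# -- displacement-field persistence ------------------------------------------

_FIELD_DESCRIP = b"displacement field, voxel units, components (z,y,x)"


def save_displacement_field(phi: np.ndarray, path) -> None:
    """Persist a ``(3, D, H, W)`` displacement field as a 4D NIfTI."""
    phi = np.asarray(phi)
    if phi.ndim != 4 or phi.shape[0] != 3:
        raise ValueError(f"expected a (3, D, H, W) field, got shape {phi.shape}")
    arr = np.moveaxis(phi, 0, -1)  # (D, H, W, 3)
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    img.header["descrip"] = _FIELD_DESCRIP
    nib.save(img, os.fspath(path))


def load_displacement_field(path) -> np.ndarray:
    """Read a displacement field written by :func:`save_displacement_field`."""
    img = nib.load(os.fspath(path))
    arr = np.asarray(img.get_fdata(), dtype=np.float64)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise VolumeIOError(f"not a displacement field: {path} has shape {arr.shape}")
    return np.moveaxis(arr, -1, 0)
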