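"""3D volume and mask data model with medical-image container I/O.

Volumes are scalar intensity grids on a HU-like scale (contrast-enhanced CT
shows the vessel lumen bright against soft tissue).  The internal axis order
is always (x, y, z); readers normalise from the on-disk layout.  Supported
containers: NIfTI (.nii/.nii.gz), NRRD (.nrrd), MetaImage (.mha/.mhd).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .errors import BoundsError, DimensionalityError, FormatError

logger = logging.getLogger(__name__)

_KNOWN_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".mha", ".mhd")


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and physical origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities, HU scale.  All three dimensions must be >= 3.
    spacing : tuple of float
        Per-axis voxel size in mm, all components > 0.  Defaults to
        isotropic 1.0 (metrics are then in voxel units).
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume data must be 3D, got {self.data.ndim}D"
            )
        if min(self.data.shape) < 3:
            raise DimensionalityError(
                f"every dimension must be >= 3, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Mask:
    """A binary voxel set aligned with a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"mask data must be 3D, got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def to_volume(self) -> Volume:
        """Mask as a 0/1 uint8 volume (the on-disk representation)."""
        return Volume(self.data.astype(np.uint8), self.spacing, self.origin)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned region of interest, 0-based half-open [lower, upper)."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise BoundsError("ROI bounds must have three components")
        if any(lo >= hi for lo, hi in zip(self.lower, self.upper)):
            raise BoundsError(f"ROI lower {self.lower} not < upper {self.upper}")
        if any(lo < 0 for lo in self.lower):
            raise BoundsError(f"ROI lower {self.lower} has negative components")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.lower, self.upper))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))

    def compose(self, inner: "ROI") -> "ROI":
        """The ROI in outer-volume coordinates equivalent to cropping by
        ``self`` and then by ``inner``."""
        lower = tuple(a + b for a, b in zip(self.lower, inner.lower))
        upper = tuple(a + b for a, b in zip(self.lower, inner.upper))
        return ROI(lower, upper)


def _check_suffix(path: str) -> None:
    name = str(path).lower()
    if not any(name.endswith(s) for s in _KNOWN_SUFFIXES):
        raise FormatError(
            f"unrecognised container {path!r}; expected one of {_KNOWN_SUFFIXES}"
        )


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D volume from a NIfTI / NRRD / MetaImage file.

    The on-disk (z, y, x) array layout is transposed to the internal
    (x, y, z) convention; spacing and origin are taken from the container
    metadata.  Missing spacing falls back to isotropic 1.0 with a warning.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # SimpleITK wraps all read failures
        raise FormatError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path} holds {img.GetDimension()}D data, expected 3D"
        )
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        logger.warning("%s: non-positive spacing %s, assuming (1,1,1)", path, spacing)
        spacing = (1.0, 1.0, 1.0)
    return Volume(data, spacing, img.GetOrigin())


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume to a NIfTI / NRRD / MetaImage file (round-trip safe)."""
    path = os.fspath(path)
    _check_suffix(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise OSError(f"directory not writable: {parent}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    sitk.WriteImage(img, path)


def read_mask(path: str | os.PathLike) -> Mask:
    """Read a binary mask stored as a 0/1 integer volume."""
    v = read_volume(path)
    return Mask(v.data > 0, v.spacing, v.origin)


def write_mask(m: Mask, path: str | os.PathLike) -> None:
    """Write a mask as an unsigned 8-bit 0/1 volume."""
    write_volume(m.to_volume(), path)


def crop(v: Volume, roi: ROI) -> Volume:
    """Extract the sub-volume covered by ``roi``.

    The origin shifts by ``lower * spacing`` so physical coordinates are
    preserved.  Working on a cropped ROI around the aneurysm is the intended
    workflow: it bounds the cost of the level-set evolutions and gives the
    threshold model a meaningful background population.
    """
    if any(hi > dim for hi, dim in zip(roi.upper, v.data.shape)):
        raise BoundsError(f"ROI {roi} exceeds volume shape {v.data.shape}")
    data = v.data[roi.slices()].copy()
    origin = tuple(
        o + lo * s for o, lo, s in zip(v.origin, roi.lower, v.spacing)
    )
    return Volume(data, v.spacing, origin)


def crop_mask(m: Mask, roi: ROI) -> Mask:
    if any(hi > dim for hi, dim in zip(roi.upper, m.data.shape)):
        raise BoundsError(f"ROI {roi} exceeds mask shape {m.data.shape}")
    origin = tuple(
        o + lo * s for o, lo, s in zip(m.origin, roi.lower, m.spacing)
    )
    return Mask(m.data[roi.slices()].copy(), m.spacing, origin)
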