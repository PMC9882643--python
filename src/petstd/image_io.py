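"""PET volume and mask I/O, scan metadata, and the AC -> SUV conversion.

A PET scanner reconstructs a 3-D map of radiotracer activity concentration
(AC), conventionally reported in Bq/mL.  Dividing the activity concentration
(in MBq/mL) by the injected dose per unit body weight yields the standardized
uptake value (SUV), which is unitless under the usual assumption that soft
tissue has a mass density of 1 g/mL (so 1 g of body weight occupies 1 mL).

This module defines the in-memory containers used throughout the package --
:class:`VolumeImage`, :class:`Mask` and :class:`ScanMeta` -- and reads/writes
them as NIfTI files through nibabel.  AC volumes are stored in Bq/mL (the unit
in which typical clinical value ranges are quoted) and converted to MBq/mL
internally when computing SUV.

Axis and spacing convention: voxel arrays are indexed (z, y, x) and spacing is
the matching tuple ``(dz, dy, dx)`` in millimetres.  The NIfTI affine written
by :func:`write_volume` is a plain diagonal scaling -- anatomical orientation
is not meaningful for the synthetic phantoms this package processes.
"""

from __future__ import annotations

import dataclasses
import enum
import os
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

from .exceptions import DataError, ModalityError

__all__ = [
    "Modality",
    "VolumeImage",
    "Mask",
    "ScanMeta",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "ac_to_suv",
]

#: scale factor from stored AC units (Bq/mL) to the MBq/mL used in the SUV formula
BQ_PER_MBQ = 1.0e6


class Modality(str, enum.Enum):
    """Intensity meaning of a volume: raw or standardized AC / SUV."""

    AC = "AC"
    SUV = "SUV"
    STD_AC = "STD_AC"
    STD_SUV = "STD_SUV"

    @property
    def base(self) -> "Modality":
        """The underlying physical modality (AC or SUV)."""
        return Modality.AC if self in (Modality.AC, Modality.STD_AC) else Modality.SUV

    @property
    def standardized(self) -> "Modality":
        """The standardized counterpart of this modality."""
        return Modality.STD_AC if self.base is Modality.AC else Modality.STD_SUV

    @property
    def is_standardized(self) -> bool:
        return self in (Modality.STD_AC, Modality.STD_SUV)


_DEFAULT_UNITS = {
    Modality.AC: "Bq/mL",
    Modality.SUV: "",
    Modality.STD_AC: "Bq/mL",
    Modality.STD_SUV: "",
}


@dataclasses.dataclass
class VolumeImage:
    """A 3-D scalar PET volume.

    Parameters
    ----------
    voxels:
        3-D array of finite reals, indexed (z, y, x).
    spacing:
        Voxel size ``(dz, dy, dx)`` in mm; strictly positive.
    modality:
        One of :class:`Modality` (or its string value).
    units:
        Physical units of the voxel values; derived from the modality when
        omitted ("Bq/mL" for AC, "" for SUV).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: Modality = Modality.AC
    units: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise DataError(f"volume must be 3-D, got non-3D data of shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise DataError("volume contains non-finite voxel values (NaN or inf)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing components must be strictly positive, got {self.spacing}")
        self.modality = Modality(self.modality)
        if self.units is None:
            self.units = _DEFAULT_UNITS[self.modality]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray, modality: Modality | None = None,
                    units: str | None = None) -> "VolumeImage":
        """A copy of this image carrying new voxel data (same grid)."""
        return VolumeImage(
            voxels=voxels,
            spacing=self.spacing,
            modality=self.modality if modality is None else modality,
            units=units,
        )


@dataclasses.dataclass
class Mask:
    """A binary region on the same grid as a companion :class:`VolumeImage`.

    ``kind`` names what the region is: "body", "liver", "spleen", "lesion"
    or "other".
    """

    voxels: np.ndarray
    kind: str = "other"

    _KINDS = ("body", "liver", "spleen", "lesion", "other")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise DataError(f"mask must be 3-D, got shape {self.voxels.shape}")
        if self.kind not in self._KINDS:
            raise DataError(f"unknown mask kind {self.kind!r}; expected one of {self._KINDS}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, volume: VolumeImage) -> None:
        if self.voxels.shape != volume.voxels.shape:
            raise DataError(
                f"mask grid {self.voxels.shape} does not match volume grid {volume.voxels.shape}"
            )


@dataclasses.dataclass
class ScanMeta:
    """Per-scan metadata needed for the SUV conversion."""

    injected_dose_mbq: float
    body_weight_g: float
    subject_id: str = ""
    scanner_id: str = ""

    def __post_init__(self) -> None:
        self.injected_dose_mbq = float(self.injected_dose_mbq)
        self.body_weight_g = float(self.body_weight_g)
        if self.injected_dose_mbq <= 0:
            raise DataError(f"injected dose must be positive, got {self.injected_dose_mbq}")
        if self.body_weight_g <= 0:
            raise DataError(f"body weight must be positive, got {self.body_weight_g}")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "ScanMeta":
        return cls(
            injected_dose_mbq=d["dose_MBq"],
            body_weight_g=d["weight_g"],
            subject_id=str(d.get("subject_id", "")),
            scanner_id=str(d.get("scanner_id", "")),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ScanMeta":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def read_volume(path: str | os.PathLike, modality: Modality | str,
                require_nonneg: bool = True) -> VolumeImage:
    """Read a 3-D NIfTI volume.

    PET activity is non-negative, so negative voxel values are rejected by
    default; pass ``require_nonneg=False`` only for derived images (e.g.
    Z-score normalized volumes) that legitimately contain negatives.
    """
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise DataError(f"non-3D data in {path}: shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise DataError(f"non-finite voxel values in {path}")
    if require_nonneg and float(data.min()) < 0:
        raise DataError(
            f"negative voxel values in {path} (min {data.min():g}); "
            "PET activity is non-negative"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(voxels=data, spacing=spacing, modality=Modality(modality))


def write_volume(volume: VolumeImage, path: str | os.PathLike) -> None:
    """Write a volume as 32-bit float NIfTI.

    Values representable in float32 round-trip bit-exactly; the finite-value
    invariant of :class:`VolumeImage` guarantees no NaN reaches the disk.
    """
    data = volume.voxels.astype(np.float32)
    if not np.all(np.isfinite(data)):  # float32 overflow would introduce inf
        raise DataError("voxel values not representable as finite float32")
    dz, dy, dx = volume.spacing
    affine = np.diag([dz, dy, dx, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path: str | os.PathLike, kind: str = "other") -> Mask:
    """Read a 0/1 NIfTI volume as a binary mask."""
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DataError(f"non-3D mask in {path}: shape {data.shape}")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise DataError(f"mask {path} is not binary (values {vals[:5]}...)")
    return Mask(voxels=data.astype(bool), kind=kind)


def write_mask(mask: Mask, path: str | os.PathLike,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    dz, dy, dx = spacing
    affine = np.diag([dz, dy, dx, 1.0])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


def ac_to_suv(volume: VolumeImage, meta: ScanMeta) -> VolumeImage:
    """Convert an activity-concentration volume (Bq/mL) to SUV.

    SUV(v) = AC(v)[MBq/mL] / (injected dose [MBq] / body weight [g]),
    with body mass density taken as 1 g/mL so the result is unitless.
    Standardized AC input yields a (plain) SUV image; the standardization can
    then be re-applied on the SUV side if desired.
    """
    if volume.modality.base is not Modality.AC:
        raise ModalityError(f"ac_to_suv requires an AC volume, got {volume.modality.value}")
    dose_per_weight = meta.injected_dose_mbq / meta.body_weight_g  # MBq/g == MBq/mL
    suv = (volume.voxels / BQ_PER_MBQ) / dose_per_weight
    return VolumeImage(voxels=suv, spacing=volume.spacing, modality=Modality.SUV)
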