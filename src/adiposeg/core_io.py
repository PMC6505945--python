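"""Data model and I/O plumbing shared by the whole pipeline.

Volumes and masks are 3-D grids indexed ``(slice, row, col)`` with the slice
axis running inferior->superior.  On disk everything is NIfTI; images with a
different header orientation are reoriented to the canonical (RAS) frame on
load so the rest of the package can assume a single convention.  Header
scale/intercept is applied on load, so thresholds always operate on physical
intensities.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

logger = logging.getLogger("adiposeg")

PathLike = Union[str, Path]

VOLUME_LABELS = ("in_phase", "opposed_phase", "fat_only", "water_only", "other")
REGION_LABELS = ("body", "fat", "SAT", "VAT", "TAT", "cavity", "custom")


def configure_logging(verbose: bool = False) -> None:
    """Route package logging to stderr; ``verbose`` enables DEBUG output."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class AdiposegError(Exception):
    """Base class for all package errors."""


class GeometryError(AdiposegError):
    """Voxel geometry invalid or inconsistent between grids."""


class FormatError(AdiposegError):
    """File is not a readable 3-D NIfTI image."""


class MaskValueError(AdiposegError):
    """A binary mask contains values outside {0, 1}."""


class VolumeValidationError(AdiposegError):
    """Fat volumes violate the VAT+SAT <= TAT <= abdominal ordering."""


class BoundsError(AdiposegError):
    """A slice range does not fit inside the available volume."""


class SegmentationFailure(AdiposegError):
    """A segmentation stage produced an empty result where one is required."""


class InsufficientDataError(AdiposegError):
    """Too few observations for the requested statistic."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel spacing in mm and slice count of a transverse volume."""

    dx: float
    dy: float
    dz: float
    n_slices: int

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise GeometryError(
                f"voxel sizes must be positive, got ({self.dx}, {self.dy}, {self.dz})"
            )
        if self.n_slices < 1:
            raise GeometryError(f"n_slices must be >= 1, got {self.n_slices}")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz

    def with_slices(self, n_slices: int) -> "VoxelGeometry":
        return VoxelGeometry(self.dx, self.dy, self.dz, n_slices)


@dataclass
class ImageVolume:
    """A 3-D scalar image: ``data[slice, row, col]`` plus voxel geometry."""

    data: np.ndarray
    geometry: VoxelGeometry
    label: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if self.data.shape[0] != self.geometry.n_slices:
            raise GeometryError(
                f"grid has {self.data.shape[0]} slices but geometry says "
                f"{self.geometry.n_slices}"
            )
        if self.label not in VOLUME_LABELS:
            raise ValueError(f"unknown volume label {self.label!r}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("image intensities must be finite")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class Mask:
    """A binary 3-D grid aligned with an :class:`ImageVolume`."""

    data: np.ndarray
    geometry: VoxelGeometry
    region_label: str = "custom"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"expected a 3-D mask, got ndim={arr.ndim}")
        if arr.dtype != bool:
            if not np.isin(arr, (0, 1)).all():
                raise MaskValueError(
                    f"mask values must be in {{0,1}}; region={self.region_label!r}"
                )
            arr = arr.astype(bool)
        self.data = arr
        if arr.shape[0] != self.geometry.n_slices:
            raise GeometryError(
                f"mask has {arr.shape[0]} slices but geometry says "
                f"{self.geometry.n_slices}"
            )
        if self.region_label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.region_label!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        return self.voxel_count() * self.geometry.voxel_volume_mm3 / 1000.0


def check_same_geometry(a, b) -> None:
    """Raise :class:`GeometryError` unless two volumes/masks are aligned."""
    if a.data.shape != b.data.shape:
        raise GeometryError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    ga, gb = a.geometry, b.geometry
    if (ga.dx, ga.dy, ga.dz, ga.n_slices) != (gb.dx, gb.dy, gb.dz, gb.n_slices):
        raise GeometryError(f"voxel geometry mismatch: {ga} vs {gb}")


@dataclass
class FatVolumes:
    """Per-subject adipose volumes (mL) over the central slab, plus ratios.

    Ratios are per-subject (VAT/SAT and VAT/TAT of the same subject), with
    the 0/0 -> 0 convention; cohort summaries should average the per-subject
    ratios rather than taking a ratio of means.
    """

    vat_ml: float
    sat_ml: float
    tat_ml: float
    abdominal_ml: float
    vat_sat_ratio: float = field(default=None)  # type: ignore[assignment]
    vat_tat_ratio: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = (self.vat_ml, self.sat_ml, self.tat_ml, self.abdominal_ml)
        if not all(np.isfinite(v) for v in vals):
            raise VolumeValidationError(f"volumes must be finite, got {vals}")
        if min(vals) < 0:
            raise VolumeValidationError(f"volumes must be non-negative, got {vals}")
        tol = 1e-9 * max(1.0, self.abdominal_ml)
        if self.vat_ml + self.sat_ml > self.tat_ml + tol:
            raise VolumeValidationError(
                f"VAT+SAT ({self.vat_ml + self.sat_ml:.3f}) exceeds TAT "
                f"({self.tat_ml:.3f})"
            )
        if self.tat_ml > self.abdominal_ml + tol:
            raise VolumeValidationError(
                f"TAT ({self.tat_ml:.3f}) exceeds abdominal volume "
                f"({self.abdominal_ml:.3f})"
            )
        if self.vat_sat_ratio is None:
            self.vat_sat_ratio = safe_ratio(self.vat_ml, self.sat_ml)
        if self.vat_tat_ratio is None:
            self.vat_tat_ratio = safe_ratio(self.vat_ml, self.tat_ml)


def safe_ratio(num: float, den: float) -> float:
    """Ratio with the 0/0 -> 0 convention used throughout the package."""
    if den == 0:
        return 0.0
    return float(num) / float(den)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _geometry_from_img(img) -> VoxelGeometry:
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise GeometryError(f"non-positive voxel sizes in header: {zooms}")
    return VoxelGeometry(float(zooms[0]), float(zooms[1]), float(zooms[2]),
                         int(img.shape[2]))


def read_volume(path: PathLike, label: str = "other") -> ImageVolume:
    """Read a 3-D NIfTI file into an :class:`ImageVolume`.

    The image is reoriented to the canonical RAS frame so the third spatial
    axis is inferior->superior; that axis becomes the (0-based) slice axis.
    Header scl_slope/scl_inter are applied.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types here
        raise FormatError(f"{path} is not a readable NIfTI image: {exc}") from exc
    if len(img.shape) != 3:
        raise FormatError(f"{path} has shape {img.shape}; expected a 3-D image")
    img = nib.as_closest_canonical(img)
    geom = _geometry_from_img(img)
    data = np.transpose(np.asarray(img.get_fdata()), (2, 1, 0))
    return ImageVolume(data=data, geometry=geom, label=label)


def _to_nifti(data: np.ndarray, geometry: VoxelGeometry):
    affine = np.diag([geometry.dx, geometry.dy, geometry.dz, 1.0])
    return nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)


def write_volume(volume: ImageVolume, path: PathLike) -> None:
    """Write an :class:`ImageVolume` to NIfTI (float64 grid)."""
    img = _to_nifti(np.asarray(volume.data, dtype=np.float64), volume.geometry)
    nib.save(img, str(path))


def write_mask(mask: Mask, path: PathLike) -> None:
    """Write a binary mask to NIfTI with values {0, 1}."""
    img = _to_nifti(mask.data.astype(np.uint8), mask.geometry)
    nib.save(img, str(path))


def read_mask(path: PathLike, region_label: str = "custom") -> Mask:
    vol = read_volume(path)
    return Mask(data=vol.data, geometry=vol.geometry, region_label=region_label)


# ---------------------------------------------------------------------------
# Reporting and configuration
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("VAT_mL", "SAT_mL", "TAT_mL", "abdominal_mL",
                  "VAT_SAT_ratio", "VAT_TAT_ratio")


def write_report(volumes: FatVolumes, path: PathLike) -> None:
    """Write a one-row CSV of the per-subject fat volumes and ratios.

    Volumes are printed to 1 decimal (mL) and ratios to 2 decimals; the
    ratios are recomputed from the supplied volumes.
    """
    row = {
        "VAT_mL": f"{volumes.vat_ml:.1f}",
        "SAT_mL": f"{volumes.sat_ml:.1f}",
        "TAT_mL": f"{volumes.tat_ml:.1f}",
        "abdominal_mL": f"{volumes.abdominal_ml:.1f}",
        "VAT_SAT_ratio": f"{safe_ratio(volumes.vat_ml, volumes.sat_ml):.2f}",
        "VAT_TAT_ratio": f"{safe_ratio(volumes.vat_ml, volumes.tat_ml):.2f}",
    }
    import pandas as pd

    pd.DataFrame([row], columns=list(REPORT_COLUMNS)).to_csv(path, index=False)


def load_config(path: PathLike) -> dict:
    """Load a JSON configuration of thresholds/morphology parameters."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a JSON object")
    return cfg
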