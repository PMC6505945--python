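"""L4/L5-anchored abdominal adipose tissue segmentation.

The semi-automatic procedure, stage by stage:

1.  The operator marks the L4/L5 intervertebral disc; 25 slices above and
    below it form a 51-slice region of interest (:func:`select_roi`).
2.  A per-slice Otsu threshold on the in-phase image, followed by
    morphological closing, hole filling and largest-component selection,
    yields the total body mask (:func:`build_body_mask`), which also provides
    the abdominal volume.
3.  A threshold on the fat-only image inside the body mask gives the fat
    (TAT) mask (:func:`build_fat_mask`).
4.  Positional priors -- no training data -- separate subcutaneous from
    visceral fat (:func:`split_sat_vat`): fat connected to the body-boundary
    shell is subcutaneous; fat inside the largest interior cavity component
    is visceral; fat in neither (e.g. vertebral marrow) counts only towards
    total adipose tissue.
5.  Volumes are reported from the central 30 slices of the region of
    interest (:func:`compute_volumes`).

All morphology is 2-D per slice with 8-connectivity by default: the acquired
slices are thick (6 mm acquired, 3 mm reconstructed) relative to the in-plane
resolution, so 3-D connectivity across slices is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as sk_closing
from skimage.morphology import disk
from skimage.morphology import erosion as sk_erosion
from skimage.morphology import opening as sk_opening

from .core_io import (
    BoundsError,
    FatVolumes,
    GeometryError,
    ImageVolume,
    Mask,
    SegmentationFailure,
    VoxelGeometry,
    check_same_geometry,
    logger,
    safe_ratio,
)

# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiSpec:
    """Slice window around the operator-marked L4/L5 disc.

    ``half_width`` slices are taken above and below the anchor (51 slices at
    the default 25); final volumes use only the ``central_count`` central
    slices (default 30).
    """

    l4l5_index: int
    half_width: int = 25
    central_count: int = 30

    def __post_init__(self) -> None:
        # half_width 0 is allowed as the degenerate single-slice window
        if self.half_width < 0:
            raise ValueError(f"half_width must be >= 0, got {self.half_width}")
        if not 1 <= self.central_count <= 2 * self.half_width + 1:
            raise ValueError(
                f"central_count must be in [1, {2 * self.half_width + 1}], "
                f"got {self.central_count}"
            )

    @property
    def n_slices(self) -> int:
        return 2 * self.half_width + 1


@dataclass(frozen=True)
class ThresholdSpec:
    """Fat threshold: automatic (Otsu over in-body voxels) or operator-fixed."""

    method: str = "otsu"
    value: Optional[float] = None
    per_slice: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ValueError(f"method must be 'otsu' or 'fixed', got {self.method!r}")
        if self.method == "fixed":
            if self.value is None or self.value < 0:
                raise ValueError("fixed threshold requires a value >= 0")
        elif self.value is not None:
            raise ValueError("value is only meaningful with method='fixed'")


@dataclass(frozen=True)
class SegmentationParams:
    """Morphology parameters of the segmentation stages (units: voxels)."""

    body_close_radius: int = 3
    body_fill_holes: bool = True
    shell_depth: int = 2
    fat_open_radius: int = 1
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.body_close_radius < 0 or self.shell_depth < 0 or self.fat_open_radius < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")

    @property
    def skimage_connectivity(self) -> int:
        return 2 if self.connectivity == 8 else 1


@dataclass
class SegmentationResult:
    """All masks produced by one segmentation run (ROI-cropped grids)."""

    body: Mask
    fat: Mask
    sat: Mask
    vat: Mask
    cavity: Mask
    roi: RoiSpec
    params: SegmentationParams

    def validate(self) -> None:
        """Assert the partition invariants; raised on every pipeline run."""
        if np.logical_and(self.sat.data, self.vat.data).any():
            raise SegmentationFailure("SAT and VAT masks overlap")
        inside_fat = self.sat.data | self.vat.data
        if np.logical_and(inside_fat, ~self.fat.data).any():
            raise SegmentationFailure("SAT u VAT is not contained in the fat mask")
        if np.logical_and(self.fat.data, ~self.body.data).any():
            raise SegmentationFailure("fat mask is not contained in the body mask")
        if np.logical_and(self.cavity.data, ~self.body.data).any():
            raise SegmentationFailure("cavity is not contained in the body mask")


# ---------------------------------------------------------------------------
# Stage 1: region of interest
# ---------------------------------------------------------------------------


def roi_bounds(roi: RoiSpec, n_slices: int) -> tuple[int, int]:
    """Half-open absolute slice range of the ROI; raises on deficit."""
    lo = roi.l4l5_index - roi.half_width
    hi = roi.l4l5_index + roi.half_width + 1
    if lo < 0:
        raise BoundsError(
            f"ROI needs {roi.half_width} slices below slice {roi.l4l5_index} "
            f"but only {roi.l4l5_index} exist ({-lo} missing)"
        )
    if hi > n_slices:
        raise BoundsError(
            f"ROI needs {roi.half_width} slices above slice {roi.l4l5_index} "
            f"but only {n_slices - 1 - roi.l4l5_index} exist "
            f"({hi - n_slices} missing)"
        )
    return lo, hi


def select_roi(volume: ImageVolume, roi: RoiSpec) -> ImageVolume:
    """Crop the 2*half_width+1 slice window centred on the L4/L5 slice."""
    lo, hi = roi_bounds(roi, volume.geometry.n_slices)
    data = np.asarray(volume.data)[lo:hi]
    return ImageVolume(
        data=data,
        geometry=volume.geometry.with_slices(hi - lo),
        label=volume.label,
    )


def crop_mask_to_roi(mask: Mask, roi: RoiSpec) -> Mask:
    """ROI-crop a full-volume mask (e.g. phantom ground truth)."""
    lo, hi = roi_bounds(roi, mask.geometry.n_slices)
    return Mask(
        data=mask.data[lo:hi],
        geometry=mask.geometry.with_slices(hi - lo),
        region_label=mask.region_label,
    )


def central_slab(center: int, count: int) -> tuple[int, int]:
    """Half-open slice range of ``count`` slices centred on ``center``.

    For even counts the extra slice goes above the centre:
    ``[center - ceil(k/2) + 1, center + floor(k/2) + 1)``.
    """
    lo = center - (count + 1) // 2 + 1
    hi = center + count // 2 + 1
    return lo, hi


# ---------------------------------------------------------------------------
# Stage 2: body mask
# ---------------------------------------------------------------------------


def _largest_component(bw: np.ndarray, connectivity: int) -> np.ndarray:
    lab = cc_label(bw, connectivity=connectivity)
    if lab.max() == 0:
        return np.zeros_like(bw, dtype=bool)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def build_body_mask(in_phase: ImageVolume, params: SegmentationParams) -> Mask:
    """Total body mask of an ROI-cropped in-phase (or water+fat) volume.

    Per slice: Otsu threshold, morphological closing, hole filling, largest
    connected component.  Because the subcutaneous fat ring reaches the skin,
    hole filling recovers the full cross-section even when the trimodal
    air/lean/fat histogram makes Otsu cut above the lean-tissue class.
    """
    data = np.asarray(in_phase.data, dtype=float)
    out = np.zeros(data.shape, dtype=bool)
    selem = disk(params.body_close_radius) if params.body_close_radius > 0 else None
    for k in range(data.shape[0]):
        sl = data[k]
        if sl.max() == sl.min():
            raise SegmentationFailure(f"slice {k}: constant intensity, no body found")
        bw = sl > threshold_otsu(sl)
        if selem is not None:
            bw = sk_closing(bw, selem).astype(bool)
        if params.body_fill_holes:
            bw = binary_fill_holes(bw)
        bw = _largest_component(bw, params.skimage_connectivity)
        if not bw.any():
            raise SegmentationFailure(f"slice {k}: empty body mask")
        out[k] = bw
    return Mask(data=out, geometry=in_phase.geometry, region_label="body")


# ---------------------------------------------------------------------------
# Stage 3: fat mask
# ---------------------------------------------------------------------------


def _background_mode(values: np.ndarray) -> float:
    hist, edges = np.histogram(values, bins=256)
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def build_fat_mask(
    fat: ImageVolume,
    body: Mask,
    thr: ThresholdSpec = ThresholdSpec(),
    params: SegmentationParams = SegmentationParams(),
) -> Mask:
    """Threshold the fat-only image inside the body mask.

    ``fat >= threshold`` within the body, then a small morphological opening
    to break single-voxel bridges between depots.  The Otsu threshold is
    computed over in-body voxels, per volume by default or per slice on
    request.
    """
    check_same_geometry(fat, body)
    data = np.asarray(fat.data, dtype=float)
    inside = body.data
    out = np.zeros(data.shape, dtype=bool)

    if thr.method == "fixed":
        mode = _background_mode(data[inside]) if inside.any() else 0.0
        if thr.value < mode:
            logger.warning(
                "fixed fat threshold %.3g is below the background intensity "
                "mode %.3g; the fat mask will leak into lean tissue",
                thr.value, mode,
            )
        out = (data >= thr.value) & inside
    elif thr.per_slice:
        for k in range(data.shape[0]):
            vals = data[k][inside[k]]
            if vals.size == 0 or vals.max() == vals.min():
                continue
            out[k] = (data[k] >= threshold_otsu(vals)) & inside[k]
    else:
        vals = data[inside]
        if vals.size and vals.max() > vals.min():
            out = (data >= threshold_otsu(vals)) & inside

    if params.fat_open_radius > 0:
        selem = disk(params.fat_open_radius)
        for k in range(out.shape[0]):
            out[k] = sk_opening(out[k], selem).astype(bool)

    if not out.any():
        logger.warning("fat mask is empty")
    return Mask(data=out, geometry=fat.geometry, region_label="fat")


# ---------------------------------------------------------------------------
# Stage 4: SAT/VAT separation by positional priors
# ---------------------------------------------------------------------------


def split_sat_vat(
    fat_mask: Mask,
    body: Mask,
    params: SegmentationParams = SegmentationParams(),
    roi: Optional[RoiSpec] = None,
) -> SegmentationResult:
    """Separate subcutaneous from visceral fat, slice by slice.

    1. boundary shell = body minus its erosion by ``shell_depth``;
    2. SAT = fat connected components that touch the shell;
    3. cavity = largest connected component of body \\ (SAT u shell),
       hole-filled;
    4. VAT = fat inside the cavity.

    Fat in neither SAT nor the cavity (vertebral marrow, intermuscular fat)
    remains in the total-fat mask only, so TAT can exceed VAT + SAT.
    """
    check_same_geometry(fat_mask, body)
    if np.logical_and(fat_mask.data, ~body.data).any():
        raise SegmentationFailure("fat mask must be contained in the body mask")

    n = fat_mask.geometry.n_slices
    sat = np.zeros(fat_mask.shape, dtype=bool)
    vat = np.zeros(fat_mask.shape, dtype=bool)
    cavity = np.zeros(fat_mask.shape, dtype=bool)
    conn = params.skimage_connectivity
    shell_selem = disk(params.shell_depth) if params.shell_depth > 0 else None

    empty_sat_slices = []
    empty_cavity_slices = []
    for k in range(n):
        body_k = body.data[k]
        fat_k = fat_mask.data[k]
        if shell_selem is not None:
            shell = body_k & ~sk_erosion(body_k, shell_selem).astype(bool)
        else:
            shell = np.zeros_like(body_k)

        lab = cc_label(fat_k, connectivity=conn)
        touching = np.unique(lab[shell & fat_k])
        touching = touching[touching > 0]
        sat_k = np.isin(lab, touching) if touching.size else np.zeros_like(fat_k)
        if fat_k.any() and not sat_k.any():
            empty_sat_slices.append(k)

        interior = body_k & ~(sat_k | shell)
        cav_k = _largest_component(interior, conn)
        if cav_k.any():
            cav_k = binary_fill_holes(cav_k) & ~sat_k & body_k
        else:
            empty_cavity_slices.append(k)

        sat[k] = sat_k
        cavity[k] = cav_k
        vat[k] = fat_k & cav_k & ~sat_k

    if empty_sat_slices:
        logger.warning(
            "no fat component touches the boundary shell on %d slice(s) "
            "(e.g. slice %d); SAT left empty there",
            len(empty_sat_slices), empty_sat_slices[0],
        )
    if empty_cavity_slices:
        logger.warning(
            "empty cavity on %d slice(s) (e.g. slice %d); VAT left empty there",
            len(empty_cavity_slices), empty_cavity_slices[0],
        )

    geom = fat_mask.geometry
    result = SegmentationResult(
        body=body,
        fat=fat_mask,
        sat=Mask(data=sat, geometry=geom, region_label="SAT"),
        vat=Mask(data=vat, geometry=geom, region_label="VAT"),
        cavity=Mask(data=cavity, geometry=geom, region_label="cavity"),
        roi=roi if roi is not None else RoiSpec(
            l4l5_index=(n - 1) // 2,
            half_width=max(1, (n - 1) // 2),
            central_count=min(30, 2 * max(1, (n - 1) // 2) + 1),
        ),
        params=params,
    )
    result.validate()
    return result


# ---------------------------------------------------------------------------
# Stage 5: volumetry over the central slab
# ---------------------------------------------------------------------------


def compute_volumes(
    result: SegmentationResult,
    geometry: VoxelGeometry,
    roi: RoiSpec,
) -> FatVolumes:
    """Volumes (mL) from the central ``roi.central_count`` slices of the ROI.

    The slab is centred on the L4/L5 slice (index ``half_width`` within the
    ROI); volume = voxel count x dx*dy*dz / 1000.  TAT comes from the fat
    mask and the abdominal volume from the body mask.
    """
    n_roi = result.body.geometry.n_slices
    if roi.central_count > n_roi:
        raise BoundsError(
            f"central slab of {roi.central_count} slices exceeds the "
            f"{n_roi}-slice ROI"
        )
    lo, hi = central_slab(roi.half_width, roi.central_count)
    lo = max(lo, 0)
    hi = min(hi, n_roi)
    vox_ml = geometry.voxel_volume_mm3 / 1000.0

    def slab_ml(mask: Mask) -> float:
        return float(mask.data[lo:hi].sum()) * vox_ml

    return FatVolumes(
        vat_ml=slab_ml(result.vat),
        sat_ml=slab_ml(result.sat),
        tat_ml=slab_ml(result.fat),
        abdominal_ml=slab_ml(result.body),
    )


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def segment_abdomen(
    fat: ImageVolume,
    in_phase: ImageVolume,
    roi: RoiSpec,
    thr: ThresholdSpec = ThresholdSpec(),
    params: SegmentationParams = SegmentationParams(),
    exclude: Optional[Mask] = None,
) -> tuple[SegmentationResult, FatVolumes]:
    """Run the full pipeline on full-length fat-only and in-phase volumes.

    ``exclude`` is an optional operator-drawn mask (full-length grid) removed
    from the fat mask before the SAT/VAT split, e.g. to discard vertebral
    marrow picked up by the threshold.
    """
    check_same_geometry(fat, in_phase)
    fat_roi = select_roi(fat, roi)
    ip_roi = select_roi(in_phase, roi)
    body = build_body_mask(ip_roi, params)
    fat_mask = build_fat_mask(fat_roi, body, thr, params)
    if exclude is not None:
        excl = crop_mask_to_roi(exclude, roi)
        fat_mask = Mask(
            data=fat_mask.data & ~excl.data,
            geometry=fat_mask.geometry,
            region_label="fat",
        )
    result = split_sat_vat(fat_mask, body, params, roi=roi)
    volumes = compute_volumes(result, fat.geometry, roi)
    return result, volumes
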