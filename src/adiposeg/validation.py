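"""Validation of the segmentation against a reference standard.

Two instruments, mirroring how semi-automatic segmentations are judged
against manual ("gold standard") outlines:

* the Dice coefficient 2|A n B| / (|A| + |B|) per region, and
* Bland-Altman agreement of the paired volume measurements at cohort level
  (bias = mean difference, limits of agreement = bias +/- 1.96 SD, and a
  t-based 95% confidence interval of the bias).

The published interval for this kind of table is ambiguous between the CI
of the bias and the limits of agreement (they differ by a factor of about
sqrt(n) in width), so both are computed and labelled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

from .core_io import (
    FatVolumes,
    InsufficientDataError,
    Mask,
    VoxelGeometry,
    check_same_geometry,
    logger,
)
from .segmentation import RoiSpec, SegmentationResult, central_slab, compute_volumes

VALIDATED_REGIONS = ("SAT", "VAT", "TAT")


def dice_coefficient(a: Mask, b: Mask) -> float:
    """Overlap 2|a n b| / (|a| + |b|); two empty masks agree (1.0, logged)."""
    check_same_geometry(a, b)
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        logger.info("dice_coefficient: both masks empty; returning 1.0")
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired measurement series."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_low: float
    ci_high: float
    n: int


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman analysis of paired measurements, differences d = x - y.

    Reports the bias (mean difference), SD of the differences, 95% limits of
    agreement (bias +/- 1.96 SD) and the t-based 95% confidence interval of
    the bias (n - 1 degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D series")
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = float(sp_stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        ci_low=bias - half,
        ci_high=bias + half,
        n=n,
    )


@dataclass
class ValidationReport:
    """Per-region Dice of one subject, the paired volumes, and (at cohort
    level) Bland-Altman agreement per region."""

    dice_per_region: Dict[str, float]
    volumes_auto: FatVolumes
    volumes_ref: FatVolumes
    bland_altman_per_region: Optional[Dict[str, BlandAltmanResult]] = None


def _slab_crop(mask: Mask, roi: RoiSpec) -> Mask:
    lo, hi = central_slab(roi.half_width, roi.central_count)
    lo = max(lo, 0)
    hi = min(hi, mask.geometry.n_slices)
    return Mask(
        data=mask.data[lo:hi],
        geometry=mask.geometry.with_slices(hi - lo),
        region_label=mask.region_label,
    )


def compare_segmentations(
    auto: SegmentationResult,
    ref: Dict[str, Mask],
    geometry: VoxelGeometry,
    roi: RoiSpec,
) -> ValidationReport:
    """Dice per region over the central slab, plus paired volumes.

    ``ref`` maps region names ("SAT", "VAT", "TAT") to ROI-aligned reference
    masks; missing regions yield a partial report with a warning.  The
    reference abdominal volume is taken from the automatic body mask (the
    body outline is not part of the manual reference).
    """
    auto_masks = {"SAT": auto.sat, "VAT": auto.vat, "TAT": auto.fat}
    dice = {}
    for region in VALIDATED_REGIONS:
        if region not in ref:
            logger.warning("compare_segmentations: no reference %s mask; skipped",
                           region)
            continue
        dice[region] = dice_coefficient(
            _slab_crop(auto_masks[region], roi), _slab_crop(ref[region], roi)
        )

    volumes_auto = compute_volumes(auto, geometry, roi)
    vox_ml = geometry.voxel_volume_mm3 / 1000.0

    def ref_ml(region: str, fallback: float) -> float:
        if region not in ref:
            return fallback
        return float(_slab_crop(ref[region], roi).data.sum()) * vox_ml

    ref_tat = ref_ml("TAT", volumes_auto.tat_ml)
    volumes_ref = FatVolumes(
        vat_ml=ref_ml("VAT", volumes_auto.vat_ml),
        sat_ml=ref_ml("SAT", volumes_auto.sat_ml),
        tat_ml=ref_tat,
        abdominal_ml=max(volumes_auto.abdominal_ml, ref_tat),
    )
    return ValidationReport(
        dice_per_region=dice,
        volumes_auto=volumes_auto,
        volumes_ref=volumes_ref,
    )


def cohort_bland_altman(
    reports: Sequence[ValidationReport],
) -> Dict[str, BlandAltmanResult]:
    """Bland-Altman per region across subjects, reference minus automatic."""
    getters = {
        "VAT": lambda v: v.vat_ml,
        "SAT": lambda v: v.sat_ml,
        "TAT": lambda v: v.tat_ml,
        "VAT/SAT": lambda v: v.vat_sat_ratio,
        "VAT/TAT": lambda v: v.vat_tat_ratio,
    }
    out = {}
    for region, get in getters.items():
        ref = [get(r.volumes_ref) for r in reports]
        auto = [get(r.volumes_auto) for r in reports]
        out[region] = bland_altman(ref, auto)
    return out
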