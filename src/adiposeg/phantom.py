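"""Synthetic abdominal two-echo Dixon phantom with analytic ground truth.

The phantom emulates a transverse 3-D T1-weighted mDIXON acquisition of the
abdomen: 150 slices of 1.25 x 1.25 x 3 mm voxels containing an elliptical
body cross-section, a bright subcutaneous fat ring reaching the skin,
scattered ellipsoidal visceral fat deposits, darker water-dominant organs,
and an optional vertebral body with a fat-marrow core embedded in the
posterior wall.  Magnitude images carry Rician noise (Gaussian noise added
to the two complex channels, then the magnitude is taken).

Voxels on region boundaries take area-weighted composite intensities from
in-plane supersampling; ground-truth masks use the >= 50% occupancy rule, so
voxelized and analytic volumes agree to within one surface layer of voxels.

Signal model per voxel: with fat occupancy w and lean/organ/bone occupancies
from the geometry,

    F  = fat_signal * w
    W  = water_signal * (w_lean + organ_scale * w_organ + bone_scale * w_bone)
    IP = F + W,   OP = W - F  (signed, phase-corrected).

All geometric parameters are millimetres, measured from the body centre
(x to the subject's left, y anterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core_io import AdiposegError, FatVolumes, ImageVolume, Mask, VoxelGeometry, logger
from .dixon import DixonPair
from .segmentation import central_slab

ORGAN_SIGNAL_SCALE = 0.75   # water-dominant organs, darker than muscle
BONE_SIGNAL_SCALE = 0.45    # cortical/trabecular vertebral body


class PhantomSpecError(AdiposegError):
    """Phantom specification violates a geometric constraint."""


@dataclass(frozen=True)
class VatBlob:
    """An ellipsoidal visceral fat deposit: centre (cx, cy, cz) mm, semi-axes
    (rx, ry, rz) mm; cz is measured along the slice axis from slice 0."""

    center: tuple
    radii: tuple


@dataclass(frozen=True)
class OrganEllipse:
    """A water-dominant organ, modelled as an elliptic cylinder spanning the
    whole stack: centre (cx, cy) mm, semi-axes (rx, ry) mm."""

    center: tuple
    radii: tuple
    signal_scale: float = ORGAN_SIGNAL_SCALE


@dataclass(frozen=True)
class MarrowFeature:
    """Vertebral body (non-fat) with a fat marrow core, both elliptic
    cylinders embedded in the posterior subcutaneous ring band."""

    center: tuple
    vertebra_radii: tuple
    marrow_radii: tuple
    signal_scale: float = BONE_SIGNAL_SCALE


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic abdomen."""

    geometry: VoxelGeometry = VoxelGeometry(1.25, 1.25, 3.0, 150)
    n_rows: int = 192
    n_cols: int = 272
    body_semi_axes: tuple = (160.0, 110.0)
    sat_thickness: float = 30.0
    vat_blobs: tuple = ()
    organs: tuple = ()
    marrow: Optional[MarrowFeature] = None
    intensities: tuple = (1000.0, 450.0)    # (fat_signal, water_signal)
    noise_sd: float = 50.0
    l4l5_index: int = 75
    taper: float = 0.0
    supersample: int = 4
    clearance_mm: float = 5.0               # >= 2 shell-depth voxels

    @property
    def fat_signal(self) -> float:
        return self.intensities[0]

    @property
    def water_signal(self) -> float:
        return self.intensities[1]

    def l4l5_z(self) -> float:
        return (self.l4l5_index + 0.5) * self.geometry.dz


def default_spec() -> PhantomSpec:
    """The study-default phantom.

    Sized like an overweight adult abdomen: 160 x 110 mm body semi-axes,
    a 30 mm subcutaneous ring, five visceral deposits (~670 mL inside the
    central slab), three organs, a vertebral body with marrow, and moderate
    magnitude noise (SD 50 against a 1000/450 fat/water signal).
    """
    z0 = (75 + 0.5) * 3.0
    return PhantomSpec(
        vat_blobs=(
            VatBlob(center=(0.0, 28.0, z0), radii=(48.0, 28.0, 42.0)),
            VatBlob(center=(-72.0, -10.0, z0 - 6.0), radii=(34.0, 26.0, 36.0)),
            VatBlob(center=(72.0, -10.0, z0 + 6.0), radii=(34.0, 26.0, 36.0)),
            VatBlob(center=(0.0, -38.0, z0), radii=(40.0, 20.0, 40.0)),
            VatBlob(center=(0.0, -9.0, z0), radii=(26.0, 8.0, 35.0)),
        ),
        organs=(
            OrganEllipse(center=(0.0, 20.0), radii=(50.0, 30.0)),
            OrganEllipse(center=(-60.0, -20.0), radii=(30.0, 22.0)),
            OrganEllipse(center=(60.0, -20.0), radii=(30.0, 22.0)),
        ),
        marrow=MarrowFeature(
            center=(0.0, -96.0),
            vertebra_radii=(30.0, 11.0),
            marrow_radii=(20.0, 6.0),
        ),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _ellipse_contains_box(cx, cy, rx, ry, A, B) -> bool:
    """Sufficient condition: the box around an ellipse fits in (A, B)."""
    if A <= 0 or B <= 0:
        return False
    return ((abs(cx) + rx) / A) ** 2 + ((abs(cy) + ry) / B) ** 2 <= 1.0


def _blobs_overlap_2d(b1: VatBlob, b2: VatBlob, step: float = 1.0) -> bool:
    """Grid test for overlap of the in-plane projections of two blobs."""
    (x1, y1, _), (rx1, ry1, _) = b1.center, b1.radii
    (x2, y2, _), (rx2, ry2, _) = b2.center, b2.radii
    lo_x, hi_x = max(x1 - rx1, x2 - rx2), min(x1 + rx1, x2 + rx2)
    lo_y, hi_y = max(y1 - ry1, y2 - ry2), min(y1 + ry1, y2 + ry2)
    if lo_x >= hi_x or lo_y >= hi_y:
        return False
    xs = np.arange(lo_x, hi_x + step, step)
    ys = np.arange(lo_y, hi_y + step, step)
    X, Y = np.meshgrid(xs, ys)
    in1 = ((X - x1) / rx1) ** 2 + ((Y - y1) / ry1) ** 2 <= 1.0
    in2 = ((X - x2) / rx2) ** 2 + ((Y - y2) / ry2) ** 2 <= 1.0
    return bool((in1 & in2).any())


def validate_spec(spec: PhantomSpec) -> None:
    """Check the geometric invariants; raise listing every offender."""
    problems = []
    a, b = spec.body_semi_axes
    t = spec.sat_thickness
    if t < 0:
        problems.append(f"sat_thickness must be >= 0, got {t}")
    if spec.fat_signal <= 0 or spec.water_signal <= 0:
        problems.append(f"intensities must be positive, got {spec.intensities}")
    if spec.noise_sd < 0:
        problems.append(f"noise_sd must be >= 0, got {spec.noise_sd}")
    if not 0 <= spec.l4l5_index < spec.geometry.n_slices:
        problems.append(f"l4l5_index {spec.l4l5_index} outside the stack")

    A = a - t - spec.clearance_mm
    B = b - t - spec.clearance_mm
    for i, blob in enumerate(spec.vat_blobs):
        cx, cy, _ = blob.center
        rx, ry, _ = blob.radii
        if not _ellipse_contains_box(cx, cy, rx, ry, A, B):
            problems.append(
                f"blob {i} at ({cx}, {cy}) r=({rx}, {ry}) violates the "
                f"{spec.clearance_mm} mm clearance inside the cavity "
                f"({A:.1f} x {B:.1f} mm)"
            )
    for i, b1 in enumerate(spec.vat_blobs):
        for j in range(i + 1, len(spec.vat_blobs)):
            b2 = spec.vat_blobs[j]
            if _blobs_overlap_2d(b1, b2):
                problems.append(f"blobs {i} and {j} overlap in plane")

    for i, organ in enumerate(spec.organs):
        cx, cy = organ.center
        rx, ry = organ.radii
        if not _ellipse_contains_box(cx, cy, rx, ry, a - t, b - t):
            problems.append(f"organ {i} extends outside the abdominal cavity")

    if spec.marrow is not None:
        m = spec.marrow
        cx, cy = m.center
        vrx, vry = m.vertebra_radii
        mrx, mry = m.marrow_radii
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        px = cx + vrx * np.cos(theta)
        py = cy + vry * np.sin(theta)
        if np.any((px / a) ** 2 + (py / b) ** 2 > 1.0):
            problems.append("vertebra extends outside the body")
        # the ring fat separating vertebra and cavity must be at least
        # clearance_mm thick, or morphological opening can breach it and the
        # marrow leaks into the visceral compartment
        gx = cx + (vrx + spec.clearance_mm) * np.cos(theta)
        gy = cy + (vry + spec.clearance_mm) * np.sin(theta)
        if t > 0 and np.any((gx / (a - t)) ** 2 + (gy / (b - t)) ** 2 < 1.0 - 1e-9):
            problems.append("vertebra reaches within the clearance of the "
                            "abdominal cavity; the marrow would be segmented "
                            "as visceral fat")
        qx = cx + mrx * np.cos(theta)
        qy = cy + mry * np.sin(theta)
        if np.any(((qx - cx) / vrx) ** 2 + ((qy - cy) / vry) ** 2 > 1.0):
            problems.append("marrow core extends outside the vertebra")

    if problems:
        raise PhantomSpecError("; ".join(problems))


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def _subgrid(spec: PhantomSpec):
    """Subsample-centre coordinates of the supersampled in-plane grid."""
    s = spec.supersample
    g = spec.geometry
    nx, ny = spec.n_cols, spec.n_rows
    ix = (np.arange(nx * s) + 0.5) / s
    iy = (np.arange(ny * s) + 0.5) / s
    x = ix * g.dx - nx * g.dx / 2.0
    y = iy * g.dy - ny * g.dy / 2.0
    return np.meshgrid(x, y)


def _block_mean(sub: np.ndarray, s: int) -> np.ndarray:
    ny, nx = sub.shape[0] // s, sub.shape[1] // s
    return sub.reshape(ny, s, nx, s).mean(axis=(1, 3))


def _plane_maps(spec: PhantomSpec, X, Y, scale: float = 1.0) -> dict:
    """Occupancy fractions of the z-independent structures at one scale."""
    a, b = spec.body_semi_axes
    a, b = a * scale, b * scale
    t = spec.sat_thickness
    s = spec.supersample

    body_sub = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    if t > 0 and a - t > 0 and b - t > 0:
        inner_sub = (X / (a - t)) ** 2 + (Y / (b - t)) ** 2 <= 1.0
    else:
        inner_sub = body_sub if t == 0 else np.zeros_like(body_sub)
    ring_sub = body_sub & ~inner_sub

    if spec.marrow is not None:
        m = spec.marrow
        vert_sub = (((X - m.center[0]) / m.vertebra_radii[0]) ** 2
                    + ((Y - m.center[1]) / m.vertebra_radii[1]) ** 2) <= 1.0
        marrow_sub = (((X - m.center[0]) / m.marrow_radii[0]) ** 2
                      + ((Y - m.center[1]) / m.marrow_radii[1]) ** 2) <= 1.0
        vert_sub &= body_sub
        marrow_sub &= vert_sub
    else:
        vert_sub = np.zeros_like(body_sub)
        marrow_sub = vert_sub

    organ_sub = np.zeros_like(body_sub)
    for organ in spec.organs:
        organ_sub |= (((X - organ.center[0]) / organ.radii[0]) ** 2
                      + ((Y - organ.center[1]) / organ.radii[1]) ** 2) <= 1.0

    sat_fat_sub = ring_sub & ~vert_sub
    bone_sub = vert_sub & ~marrow_sub
    fat_static_sub = sat_fat_sub | marrow_sub
    organ_eff_sub = organ_sub & body_sub & ~fat_static_sub & ~vert_sub

    return {
        "body": _block_mean(body_sub, s),
        "sat": _block_mean(sat_fat_sub, s),
        "marrow": _block_mean(marrow_sub, s),
        "bone": _block_mean(bone_sub, s),
        "organ": _block_mean(organ_eff_sub, s),
        "fat_static": _block_mean(fat_static_sub, s),
        "organ_eff_sub": organ_eff_sub,
        "fat_static_sub": fat_static_sub,
        "body_sub": body_sub,
    }


def _taper_scale(spec: PhantomSpec, k: int) -> float:
    if spec.taper == 0.0:
        return 1.0
    g = spec.geometry
    z = (k + 0.5) * g.dz
    half = g.n_slices * g.dz / 2.0
    return 1.0 - spec.taper * abs(z - spec.l4l5_z()) / half


def _blob_occupancy(spec: PhantomSpec, X, Y):
    """Per-slice blob (VAT) occupancy and blob-over-organ overlap fraction.

    Returns float arrays ``(n_slices, n_rows, n_cols)``: the fraction of each
    voxel inside a visceral deposit, and the fraction where a deposit covers
    what would otherwise be organ tissue (needed to keep the water signal
    composition exact).
    """
    g = spec.geometry
    s = spec.supersample
    shape = (g.n_slices, spec.n_rows, spec.n_cols)
    w_vat = np.zeros(shape)
    w_org_blob = np.zeros(shape)
    if not spec.vat_blobs:
        return w_vat, w_org_blob

    maps = _plane_maps(spec, X, Y) if spec.taper == 0.0 else None
    for k in range(g.n_slices):
        z = (k + 0.5) * g.dz
        blob_sub = None
        for blob in spec.vat_blobs:
            cx, cy, cz = blob.center
            rx, ry, rz = blob.radii
            u = (z - cz) / rz
            if abs(u) >= 1.0:
                continue
            f = np.sqrt(1.0 - u * u)
            this = (((X - cx) / (rx * f)) ** 2 + ((Y - cy) / (ry * f)) ** 2) <= 1.0
            blob_sub = this if blob_sub is None else (blob_sub | this)
        if blob_sub is None:
            continue
        plane = maps if maps is not None else _plane_maps(spec, X, Y, _taper_scale(spec, k))
        blob_sub &= plane["body_sub"] & ~plane["fat_static_sub"]
        w_vat[k] = _block_mean(blob_sub, s)
        w_org_blob[k] = _block_mean(blob_sub & plane["organ_eff_sub"], s)
    return w_vat, w_org_blob


def _rician(rng: np.random.Generator, clean: np.ndarray, sd: float) -> np.ndarray:
    n1 = rng.normal(0.0, sd, clean.shape)
    n2 = rng.normal(0.0, sd, clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2 ** 2)


@dataclass
class GroundTruth:
    """Analytic masks and volumes of a generated phantom (full-length grids;
    volumes over the central slab around the L4/L5 slice)."""

    body: Mask
    fat: Mask
    sat: Mask
    vat: Mask
    volumes_voxel: FatVolumes
    volumes_analytic: FatVolumes

    def masks(self) -> dict:
        return {"body": self.body, "TAT": self.fat, "SAT": self.sat, "VAT": self.vat}


def generate_phantom(
    spec: PhantomSpec, seed: int, central_count: int = 30
) -> tuple[DixonPair, ImageVolume, GroundTruth]:
    """Voxelize a phantom and synthesize its noisy magnitude images.

    Returns the phase-corrected in-phase/opposed-phase pair, the
    scanner-style fat-only image, and the ground truth.  Identical
    ``spec`` + ``seed`` give bit-identical output; different seeds change
    only the noise realization.
    """
    validate_spec(spec)
    g = spec.geometry
    X, Y = _subgrid(spec)

    if spec.taper == 0.0:
        plane = _plane_maps(spec, X, Y)
        w_body = np.broadcast_to(plane["body"], (g.n_slices,) + plane["body"].shape)
        w_sat = np.broadcast_to(plane["sat"], w_body.shape)
        w_marrow = np.broadcast_to(plane["marrow"], w_body.shape)
        w_bone = np.broadcast_to(plane["bone"], w_body.shape)
        w_organ = np.broadcast_to(plane["organ"], w_body.shape)
        w_fat_static = np.broadcast_to(plane["fat_static"], w_body.shape)
    else:
        shape = (g.n_slices, spec.n_rows, spec.n_cols)
        w_body = np.zeros(shape); w_sat = np.zeros(shape)
        w_marrow = np.zeros(shape); w_bone = np.zeros(shape)
        w_organ = np.zeros(shape); w_fat_static = np.zeros(shape)
        for k in range(g.n_slices):
            plane = _plane_maps(spec, X, Y, _taper_scale(spec, k))
            for arr, key in ((w_body, "body"), (w_sat, "sat"),
                             (w_marrow, "marrow"), (w_bone, "bone"),
                             (w_organ, "organ"), (w_fat_static, "fat_static")):
                arr[k] = plane[key]

    w_vat, w_org_blob = _blob_occupancy(spec, X, Y)

    w_fat = w_fat_static + w_vat
    w_lean = w_body - w_fat - w_bone - (w_organ - w_org_blob)

    F = spec.fat_signal * w_fat
    W = spec.water_signal * (
        w_lean + ORGAN_SIGNAL_SCALE * (w_organ - w_org_blob)
        + (spec.marrow.signal_scale if spec.marrow else BONE_SIGNAL_SCALE) * w_bone
    )
    ip_clean = F + W
    op_clean = W - F

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        ip = _rician(rng, ip_clean, spec.noise_sd)
        op_sign = np.where(op_clean < 0, -1.0, 1.0)
        op = op_sign * _rician(rng, np.abs(op_clean), spec.noise_sd)
        fat_img = _rician(rng, F, spec.noise_sd)
    else:
        ip, op, fat_img = ip_clean, op_clean, F

    pair = DixonPair(
        in_phase=ImageVolume(data=ip, geometry=g, label="in_phase"),
        opposed_phase=ImageVolume(data=op, geometry=g, label="opposed_phase"),
    )
    fat_only = ImageVolume(data=fat_img, geometry=g, label="fat_only")

    truth_body = w_body >= 0.5
    truth_sat = w_sat >= 0.5
    truth_vat = w_vat >= 0.5
    truth_fat = w_fat >= 0.5

    lo, hi = central_slab(spec.l4l5_index, central_count)
    vox_ml = g.voxel_volume_mm3 / 1000.0
    volumes_voxel = FatVolumes(
        vat_ml=float(truth_vat[lo:hi].sum()) * vox_ml,
        sat_ml=float(truth_sat[lo:hi].sum()) * vox_ml,
        tat_ml=float(truth_fat[lo:hi].sum()) * vox_ml,
        abdominal_ml=float(truth_body[lo:hi].sum()) * vox_ml,
    )

    truth = GroundTruth(
        body=Mask(data=truth_body, geometry=g, region_label="body"),
        fat=Mask(data=truth_fat, geometry=g, region_label="fat"),
        sat=Mask(data=truth_sat, geometry=g, region_label="SAT"),
        vat=Mask(data=truth_vat, geometry=g, region_label="VAT"),
        volumes_voxel=volumes_voxel,
        volumes_analytic=analytic_volumes(spec, central_count),
    )
    return pair, fat_only, truth


# ---------------------------------------------------------------------------
# Closed-form volumes
# ---------------------------------------------------------------------------


def _ellipsoid_slab_volume(blob: VatBlob, z1: float, z2: float) -> float:
    """Volume of an axis-aligned ellipsoid between the planes z1 and z2."""
    _, _, cz = blob.center
    rx, ry, rz = blob.radii
    zl = max(z1, cz - rz)
    zu = min(z2, cz + rz)
    if zu <= zl:
        return 0.0

    def anti(z):
        u = z - cz
        return u - u ** 3 / (3.0 * rz ** 2)

    return np.pi * rx * ry * (anti(zu) - anti(zl))


def analytic_volumes(spec: PhantomSpec, central_count: int = 30) -> FatVolumes:
    """Closed-form region volumes over the central slab (exact when the body
    is untapered; per-slice cross-section sums otherwise)."""
    g = spec.geometry
    a, b = spec.body_semi_axes
    t = spec.sat_thickness
    lo, hi = central_slab(spec.l4l5_index, central_count)
    z1, z2 = lo * g.dz, hi * g.dz
    height = z2 - z1

    vert_area = marrow_area = 0.0
    if spec.marrow is not None:
        vert_area = np.pi * spec.marrow.vertebra_radii[0] * spec.marrow.vertebra_radii[1]
        marrow_area = np.pi * spec.marrow.marrow_radii[0] * spec.marrow.marrow_radii[1]

    if spec.taper == 0.0:
        body_vol = np.pi * a * b * height
        if t > 0:
            ring_area = np.pi * (a * b - (a - t) * (b - t))
            sat_vol = (ring_area - vert_area) * height
        else:
            sat_vol = 0.0
    else:
        body_vol = 0.0
        sat_vol = 0.0
        for k in range(lo, hi):
            s = _taper_scale(spec, k)
            ak, bk = a * s, b * s
            body_vol += np.pi * ak * bk * g.dz
            if t > 0 and ak > t and bk > t:
                ring = np.pi * (ak * bk - (ak - t) * (bk - t))
                sat_vol += (ring - vert_area) * g.dz

    vat_vol = sum(_ellipsoid_slab_volume(blob, z1, z2) for blob in spec.vat_blobs)
    marrow_vol = marrow_area * height
    tat_vol = sat_vol + vat_vol + marrow_vol

    return FatVolumes(
        vat_ml=vat_vol / 1000.0,
        sat_ml=sat_vol / 1000.0,
        tat_ml=tat_vol / 1000.0,
        abdominal_ml=body_vol / 1000.0,
    )


def scaled_spec(spec: PhantomSpec, factor: float) -> PhantomSpec:
    """Scale every linear dimension of the anatomy by ``factor`` (volumes
    scale by ``factor**3``); the voxel grid is left unchanged."""
    z0 = spec.l4l5_z()
    blobs = tuple(
        VatBlob(
            center=(c[0] * factor, c[1] * factor, z0 + (c[2] - z0) * factor),
            radii=tuple(r * factor for r in b.radii),
        )
        for b in spec.vat_blobs
        for c in (b.center,)
    )
    organs = tuple(
        OrganEllipse(
            center=tuple(c * factor for c in o.center),
            radii=tuple(r * factor for r in o.radii),
            signal_scale=o.signal_scale,
        )
        for o in spec.organs
    )
    marrow = None
    if spec.marrow is not None:
        m = spec.marrow
        marrow = MarrowFeature(
            center=tuple(c * factor for c in m.center),
            vertebra_radii=tuple(r * factor for r in m.vertebra_radii),
            marrow_radii=tuple(r * factor for r in m.marrow_radii),
            signal_scale=m.signal_scale,
        )
    return replace(
        spec,
        body_semi_axes=tuple(s * factor for s in spec.body_semi_axes),
        sat_thickness=spec.sat_thickness * factor,
        vat_blobs=blobs,
        organs=organs,
        marrow=marrow,
    )
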