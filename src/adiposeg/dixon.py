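"""Two-point Dixon water/fat reconstruction.

A two-echo chemical-shift acquisition yields an in-phase image IP = W + F and
an opposed-phase image OP = W - F, where W and F are the water and fat signal
contributions of each voxel.  Inverting the pair gives

    F = (IP - OP) / 2,     W = IP - F,

so water + fat reproduces the in-phase image exactly.  The scanner normally
performs this separation itself; this module exists so the pipeline can also
start from raw echoes.

Inputs are assumed phase-corrected, i.e. OP carries its sign (negative in
fat-dominant voxels).  A magnitude-only OP can be accepted behind a flag; the
sign is then restored with a coarse intensity heuristic and the result is
only approximate near half-fat voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ImageVolume, check_same_geometry, logger


def estimate_background_sd(volume: ImageVolume, patch: int = 10) -> float:
    """Estimate the magnitude-noise SD from a signal-free corner patch.

    For a Rayleigh-distributed air patch the underlying Gaussian SD is
    ``mean / sqrt(pi/2)``.
    """
    corner = np.asarray(volume.data)[:, :patch, :patch]
    return float(np.mean(corner) / np.sqrt(np.pi / 2.0))


@dataclass
class DixonPair:
    """Phase-corrected in-phase / opposed-phase echo pair.

    On construction the pair is checked for geometry agreement and for the
    physical identity IP >= |OP|, which magnitude noise can violate slightly;
    violations beyond a tolerance of 3x the background noise SD are reported
    as a warning, not an error.
    """

    in_phase: ImageVolume
    opposed_phase: ImageVolume

    def __post_init__(self) -> None:
        check_same_geometry(self.in_phase, self.opposed_phase)
        ip = np.asarray(self.in_phase.data, dtype=float)
        op = np.asarray(self.opposed_phase.data, dtype=float)
        tau = 3.0 * estimate_background_sd(self.in_phase)
        bad = int(np.count_nonzero(np.abs(op) > ip + tau))
        frac = bad / ip.size
        if bad:
            # a few-percent tail is expected from independent magnitude noise
            # on the two echoes; a large share points at mismatched inputs
            level = logger.warning if frac > 0.05 else logger.debug
            level(
                "DixonPair: |OP| exceeds IP + 3*noise_sd (%.3g) in %d voxels "
                "(%.2f%%)", tau, bad, 100 * frac,
            )


def reconstruct_water_fat(
    pair: DixonPair, op_is_magnitude: bool = False
) -> tuple[ImageVolume, ImageVolume]:
    """Separate a Dixon pair into (water, fat) images.

    Water + fat equals the in-phase image exactly; negative intermediate
    values (from noise) are clipped to zero afterwards, re-assigning the full
    in-phase signal to the other species so the conservation still holds.

    With ``op_is_magnitude`` the sign of OP is first restored by assuming
    water dominance (fat fraction <= 0.5) in voxels below the median in-phase
    intensity of non-background voxels and fat dominance above it.  This is a
    coarse positional/intensity heuristic -- T1-weighted fat is bright --
    and is documented as approximate.
    """
    ip = np.asarray(pair.in_phase.data, dtype=float)
    op = np.asarray(pair.opposed_phase.data, dtype=float)
    if op_is_magnitude:
        from skimage.filters import threshold_otsu

        op = np.abs(op)
        nonbg = ip > 3.0 * estimate_background_sd(pair.in_phase)
        vals = ip[nonbg]
        cut = threshold_otsu(vals) if vals.size and vals.max() > vals.min() else np.inf
        sign = np.where(ip >= cut, -1.0, 1.0)
        op = sign * op
        logger.warning(
            "reconstruct_water_fat: restoring OP sign from magnitude input "
            "with an intensity heuristic (cut=%.3g); result is approximate",
            cut,
        )

    # Compute the dominant species as (IP + |OP|)/2 and the other as the
    # remainder IP - dominant.  Because dominant >= IP/2, the subtraction is
    # exact (Sterbenz), so water + fat reproduces IP bit for bit.
    dominant = 0.5 * (ip + np.abs(op))
    minority = ip - dominant
    neg = minority < 0  # |OP| > IP from noise: clip, keeping the sum
    if neg.any():
        minority = np.where(neg, 0.0, minority)
        dominant = np.where(neg, ip, dominant)
    water_major = op >= 0
    water = np.where(water_major, dominant, minority)
    fat = np.where(water_major, minority, dominant)

    geom = pair.in_phase.geometry
    return (
        ImageVolume(data=water, geometry=geom, label="water_only"),
        ImageVolume(data=fat, geometry=geom, label="fat_only"),
    )


def fat_fraction(fat: ImageVolume, water: ImageVolume) -> ImageVolume:
    """Fat fraction F/(F+W) in [0, 1]; voxels with F+W = 0 map to 0."""
    check_same_geometry(fat, water)
    f = np.asarray(fat.data, dtype=float)
    w = np.asarray(water.data, dtype=float)
    total = f + w
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(total > 0, f / np.where(total > 0, total, 1.0), 0.0)
    return ImageVolume(data=np.clip(ff, 0.0, 1.0), geometry=fat.geometry,
                       label="other")
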