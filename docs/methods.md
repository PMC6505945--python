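# Methods

## Signal model and Dixon separation

A two-echo chemical-shift acquisition yields, per voxel, an in-phase image
IP = W + F and an opposed-phase image OP = W − F, where W and F are the
water and fat signal contributions. `dixon.reconstruct_water_fat` inverts
the pair. Numerically, the dominant species is computed as
(IP + |OP|)/2 and the other as IP minus it; because the dominant term is at
least IP/2, the subtraction incurs no rounding (Sterbenz lemma) and
**water + fat reproduces IP bit for bit**. Where noise makes |OP| > IP the
negative minority species is clipped to zero and the full in-phase signal
assigned to the other, preserving the identity. Inputs are assumed
phase-corrected (signed OP); a magnitude-only OP is accepted behind
`op_is_magnitude=True`, with the sign restored by an Otsu cut on non-
background in-phase intensity (fat is bright on T1) — an explicitly
approximate path that mislabels voxels near 50% fat fraction.

The physical constraint IP ≥ |OP| is checked on pair construction with a
tolerance of 3× the background noise SD (estimated from a corner patch as
mean/√(π/2), the Rayleigh relation). With independent magnitude noise on
the two echoes, one or two percent of voxels exceed the tolerance wherever
one species is absent; the check therefore logs a warning only when more
than 5% of voxels violate it, which indicates genuinely mismatched inputs.

## Segmentation

All processing is 2-D per slice with 8-connectivity by default: slices are
thick (6 mm acquired, 3 mm reconstructed) relative to the 1.25 mm in-plane
grid, so through-plane connectivity is unreliable. Stages and their
parameters (`SegmentationParams`, units of voxels):

* **Region of interest.** 0-based slice indices, half-open ranges. The ROI
  is `[l4l5 − hw, l4l5 + hw + 1)` with `half_width` hw = 25 by default
  (51 slices). Final volumes use the central `central_count` = 30 slices,
  taken as `[c − ⌈k/2⌉ + 1, c + ⌊k/2⌋ + 1)` around the anchor slice c — for
  even counts the extra slice lies superior. Which 30 of the 51 slices the
  original protocol used is not documented; this centred convention is the
  package's choice and is configurable.
* **Body mask** (`body_close_radius` 3, hole filling on). Per-slice Otsu on
  the in-phase image. On a trimodal air/lean/fat histogram, Otsu can place
  the cut above the lean class; the pipeline still recovers the full
  cross-section because the subcutaneous fat ring reaches the skin, so hole
  filling closes everything inside it. A subject with essentially no
  subcutaneous fat would break this assumption — a documented limitation.
  The largest connected component suppresses noise specks outside the body.
* **Fat mask** (`fat_open_radius` 1). `fat ≥ threshold` within the body;
  the default threshold is Otsu over in-body fat-image voxels, computed
  once per volume (per-slice optional). A fixed operator threshold is
  honoured verbatim, with a logged warning if it falls below the in-body
  background intensity mode. The radius-1 opening breaks single-voxel
  bridges between depots; it also erases any genuine fat structure thinner
  than about 3 voxels (~4 mm), which is why the phantom keeps a ≥5 mm fat
  margin around the vertebra (below).
* **SAT/VAT split** (`shell_depth` 2). Boundary shell = body minus its
  erosion; SAT = fat components touching the shell; cavity = hole-filled
  largest component of body ∖ (SAT ∪ shell); VAT = fat ∩ cavity. Fat in
  neither compartment (vertebral marrow, intermuscular fat) remains in TAT
  only, which is why TAT can exceed VAT + SAT. Ties in the largest-
  component choice resolve to the lowest label, deterministically. The
  partition invariants (SAT ∩ VAT = ∅, SAT ∪ VAT ⊆ fat ⊆ body) are
  asserted on every run.
* **Degenerate inputs.** A constant slice or an all-empty body raises a
  segmentation failure naming the slice; an empty fat mask, a slice where
  no fat touches the shell, or an empty cavity produce warnings and empty
  masks rather than errors.

## The phantom

The generator emulates the target acquisition: 150 transverse slices of
1.25 × 1.25 × 3 mm voxels (192 × 272 in-plane). Geometry is parametric and
validated: an elliptical body (default semi-axes 160 × 110 mm, roughly an
overweight adult), a subcutaneous fat ring of constant thickness (30 mm)
reaching the skin, ellipsoidal visceral deposits, water-dominant organ
cylinders at 0.75× the lean signal, and a vertebral body (0.45× lean) with
a fat marrow core embedded in the posterior ring band. Signals default to
fat 1000 and lean tissue 450 — about the 2:1 fat:muscle contrast of a
T1-weighted acquisition — with magnitude noise SD 50 (SNR ≈ 20 in fat,
9 in muscle).

Partial volume: each in-plane voxel is split 4 × 4, subsamples are labelled
by the finest enclosing region, and intensities are occupancy-weighted
averages; slices are sampled at their centre plane. Ground-truth masks use
the ≥ 50% occupancy rule, so voxelized and analytic volumes differ by at
most one surface layer of voxels — the bound the volume-recovery tests
assert. Noise is Rician (Gaussian on two complex channels, then magnitude),
seeded; a fixed spec + seed is bit-reproducible and different seeds change
only the noise. With the occupancy fractions being multiples of 1/16 and
binary-fraction signal levels, the noise-free forward model is exactly
invertible by the Dixon stage — tested bit-for-bit.

Geometric validation enforces: deposits inside the cavity with ≥ 5 mm
clearance (twice the shell depth) from the ring, pairwise disjoint (checked
on a 1 mm projection grid); the vertebra inside the ring band with ≥ 5 mm
of ring fat on its cavity side, so that the radius-1 opening cannot breach
the fat layer that keeps the marrow out of the visceral compartment; the
marrow inside the vertebra. Violations raise errors listing every offender.

Default-anatomy volumes over the central slab (analytic): VAT 667.6 mL,
SAT 1942.4 mL, TAT 2644.0 mL. These sit inside the ranges observed in a
real overweight diverticular-disease cohort, though the VAT mean there is
higher (~1020 mL): real mesenteric fat is a connected, space-filling
tissue, while disjoint ellipsoids under the clearance constraints cannot
pack as densely. The synthetic cohort used by the tests and the acceptance
script is 10 noise realizations (seeds 1–10) of this single anatomy — it
probes noise robustness of every pipeline stage, not anatomical
variability, and says nothing about motion, bias fields, stack-stitching
artefacts or pathology, all of which real data contain.

## Validation statistics

Dice is 2|A∩B|/(|A|+|B|) over the central slab; two empty masks score 1
(identity of empty regions is agreement), logged. Bland–Altman reports the
bias (mean of paired differences), the SD of differences, 95% limits of
agreement bias ± 1.96·SD, and a t-based 95% CI of the bias (n − 1 df).
Published agreement tables of this kind are often ambiguous between the CI
of the bias and the limits of agreement — with n = 10 the two differ by
about √10 in width — so both are computed and labelled explicitly.

## Power and correlation

The sample-size routine finds the smallest per-group n for which a
two-sided two-sample t test detects the effect d = relative_difference ×
ref_mean / ref_sd with the requested power, using noncentral-t power
(noncentrality d·√(n/2), 2n − 2 df) and a doubling-plus-bisection search
(power is monotone in n). The exact noncentral-t route matters: for a 30%
difference at mean 3829, SD 1106, it yields 16 per group where the normal
approximation gives 15. The n = 16 result is cross-checked in the tests
against a 50,000-replicate Monte-Carlo power sweep and against an
independent solver.

Spearman's ρ is the Pearson correlation of mid-ranks (ties averaged). The
two-sided p-value is an exact permutation probability
P(|ρ_perm| ≥ |ρ_obs|) over all n! orderings for n ≤ 9, and the usual
t approximation with n − 2 df above that; the tests verify the two agree
within 0.05 at the boundary and that the exact path matches a brute-force
enumeration.

## Problem sizes

Unit tests run on a reduced phantom (70 × 50 mm body, 40 slices) so the
suite stays interactive; the acceptance script and the end-to-end tests use
the full 150-slice default anatomy with a 10-subject ensemble, the cohort
size of the original validation study.

## Known limitations

* The body mask depends on a subcutaneous fat ring reaching the skin.
* The SAT/VAT separation assumes the cavity is a single dominant interior
  component per slice; severely fragmented cavities (large bowel gas
  pockets splitting the slice) would mislabel fat near the split.
* Thin fat structures (< ~4 mm) are suppressed by the default opening.
* The magnitude-OP entry point is approximate by construction.
* NIfTI is the only supported container; scanner DICOMs must be converted
  upstream.
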