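# adiposeg

Semi-automatic quantification of abdominal **visceral (VAT)**,
**subcutaneous (SAT)** and **total (TAT)** adipose tissue from two-point
Dixon (mDIXON) MRI.

Abdominal obesity — and visceral fat in particular — is metabolically
active and pro-inflammatory, so body-composition studies need a
reproducible way to turn an abdominal MRI stack into fat volumes.
`adiposeg` implements a training-free, positional-prior pipeline for
transverse 3-D T1-weighted Dixon acquisitions (in-phase/opposed-phase
echoes, or scanner-reconstructed fat-only/water-only images), aimed at
imaging scientists and clinical researchers doing MRI volumetry.

## The method

Given the in-phase image IP = W + F and the phase-corrected opposed-phase
image OP = W − F, two-point Dixon separation gives the fat and water images

    F = (IP − OP) / 2,    W = IP − F,

with W + F = IP preserved bit-exactly. Segmentation then proceeds:

1. **Anchor.** The operator marks the L4/L5 intervertebral disc; 25 slices
   above and below it (3 mm each) form a 51-slice region of interest.
2. **Body mask.** Per slice: Otsu threshold on the in-phase image,
   morphological closing, hole filling, largest connected component. This
   mask also yields the abdominal volume.
3. **Fat mask.** A threshold on the fat-only image inside the body mask
   (Otsu over in-body voxels by default, or a fixed operator value),
   followed by a small opening. This is the TAT support.
4. **SAT/VAT split by positional priors.** Fat connected to the 2-voxel
   body-boundary shell is subcutaneous; the largest interior component of
   body ∖ (SAT ∪ shell) is the abdominal cavity, and fat inside it is
   visceral. Fat in neither compartment (e.g. vertebral marrow) counts
   toward TAT only, so TAT ≥ VAT + SAT.
5. **Volumetry.** Volumes are reported from the central 30 slices:
   V = (voxel count) × dx·dy·dz / 1000 mL, plus VAT/SAT and VAT/TAT ratios.

Validation uses the Dice coefficient 2|A∩B|/(|A|+|B|) per region and
Bland–Altman agreement (bias, 95% limits of agreement, and the t-based 95%
CI of the bias) of paired volumes. Supporting statistics include a
noncentral-t two-sample sample-size calculation and Spearman rank
correlation with an exact permutation p-value for n ≤ 9.

Because no public scans accompany the method, the package ships a
**synthetic phantom**: a parametric abdomen (elliptical body, subcutaneous
fat ring, ellipsoidal visceral deposits, darker organs, a vertebral body
with fat marrow) voxelized at 1.25 × 1.25 × 3 mm over 150 slices with
partial-volume mixing and Rician magnitude noise, together with analytic
ground-truth masks and closed-form volumes.

## Worked example

```python
import adiposeg as ap

spec = ap.default_spec()                       # overweight-adult phantom
pair, fat_only, truth = ap.generate_phantom(spec, seed=1)

roi = ap.RoiSpec(l4l5_index=75)                # operator anchor
result, vols = ap.segment_abdomen(fat_only, pair.in_phase, roi)
print(f"VAT {vols.vat_ml:.1f} mL, SAT {vols.sat_ml:.1f} mL, "
      f"TAT {vols.tat_ml:.1f} mL, abdominal {vols.abdominal_ml:.1f} mL")

ref = {k: ap.crop_mask_to_roi(m, roi) for k, m in
       {"SAT": truth.sat, "VAT": truth.vat, "TAT": truth.fat}.items()}
report = ap.compare_segmentations(result, ref, spec.geometry, roi)
print({k: round(v, 3) for k, v in report.dice_per_region.items()})
```

prints

```
VAT 664.7 mL, SAT 1927.5 mL, TAT 2625.6 mL, abdominal 4967.3 mL
{'SAT': 0.994, 'VAT': 0.996, 'TAT': 0.994}
```

The measured volumes sit within a few percent of the phantom's analytic
truth (VAT 667.6, SAT 1942.4, TAT 2644.0 mL over the central slab), and
each region overlaps its ground truth with Dice ≥ 0.99 despite the added
magnitude noise. The same pipeline is available from the shell:

```bash
adiposeg phantom --seed 1 --out-dir phantom1/
adiposeg segment --fat phantom1/fat.nii.gz --ip phantom1/ip.nii.gz \
    --l4l5 75 --out-dir results1/
adiposeg stats power --mean 3829 --sd 1106 --diff 0.30
# -> 16 participants per group (achieved power 0.811)
```

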