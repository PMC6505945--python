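import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import adiposeg as ap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_small_spec(**overrides) -> ap.PhantomSpec:
    """A reduced abdomen (70 x 50 mm body, 40 slices) for fast unit tests."""
    z0 = (20 + 0.5) * 3.0
    spec = ap.PhantomSpec(
        geometry=ap.VoxelGeometry(1.25, 1.25, 3.0, 40),
        n_rows=96,
        n_cols=128,
        body_semi_axes=(70.0, 50.0),
        sat_thickness=15.0,
        vat_blobs=(
            ap.VatBlob(center=(0.0, 10.0, z0), radii=(20.0, 12.0, 18.0)),
            ap.VatBlob(center=(-26.0, -6.0, z0), radii=(12.0, 9.0, 14.0)),
        ),
        organs=(ap.OrganEllipse(center=(20.0, -12.0), radii=(14.0, 9.0)),),
        marrow=ap.MarrowFeature(
            center=(0.0, -44.0),
            vertebra_radii=(12.0, 4.0),
            marrow_radii=(8.0, 2.5),
        ),
        l4l5_index=20,
    )
    return dataclasses.replace(spec, **overrides) if overrides else spec


SMALL_ROI = ap.RoiSpec(l4l5_index=20, half_width=10, central_count=10)


@pytest.fixture(scope="session")
def small_clean():
    spec = make_small_spec(noise_sd=0.0)
    pair, fat_only, truth = ap.generate_phantom(spec, seed=1, central_count=10)
    return spec, pair, fat_only, truth


@pytest.fixture(scope="session")
def small_noisy():
    spec = make_small_spec()
    pair, fat_only, truth = ap.generate_phantom(spec, seed=1, central_count=10)
    return spec, pair, fat_only, truth


@pytest.fixture(scope="session")
def default_clean():
    """The study-default phantom without noise (full 150-slice stack)."""
    spec = dataclasses.replace(ap.default_spec(), noise_sd=0.0)
    pair, fat_only, truth = ap.generate_phantom(spec, seed=1)
    return spec, pair, fat_only, truth


@pytest.fixture(scope="session")
def phantom_ensemble():
    """Ten noise realizations of the default phantom, fully segmented.

    Returns per-subject dictionaries with the Dice coefficients against
    ground truth over the central slab and the paired volumes; the image
    volumes themselves are discarded to keep memory flat.
    """
    spec = ap.default_spec()
    roi = ap.RoiSpec(l4l5_index=spec.l4l5_index)
    subjects = []
    for seed in range(1, 11):
        pair, fat_only, truth = ap.generate_phantom(spec, seed=seed)
        result, volumes = ap.segment_abdomen(fat_only, pair.in_phase, roi)
        ref = {
            "SAT": ap.crop_mask_to_roi(truth.sat, roi),
            "VAT": ap.crop_mask_to_roi(truth.vat, roi),
            "TAT": ap.crop_mask_to_roi(truth.fat, roi),
        }
        report = ap.compare_segmentations(result, ref, spec.geometry, roi)
        subjects.append(
            {
                "seed": seed,
                "dice": report.dice_per_region,
                "auto": volumes,
                "truth": truth.volumes_voxel,
                "analytic": truth.volumes_analytic,
                "result_summary": {
                    "sat_and_vat_disjoint": not (
                        result.sat.data & result.vat.data
                    ).any(),
                    "sat_vat_in_fat": bool(
                        ((result.sat.data | result.vat.data) <= result.fat.data).all()
                    ),
                    "fat_in_body": bool((result.fat.data <= result.body.data).all()),
                },
            }
        )
    return subjects
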