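import numpy as np
import pytest
from scipy import ndimage

from bosfem.synthetic_ct import (
    CTProtocol,
    LesionSpec,
    PhantomSpec,
    SyntheticFemurSpec,
    SyntheticSpecError,
    default_femur,
    default_phantom,
    generate_phantom_volume,
    ground_truth_masks,
    preset_specs,
)

CONN26 = np.ones((3, 3, 3), dtype=bool)


def test_protocol_defaults():
    p = CTProtocol()
    assert (p.tube_voltage_kVp, p.slice_thickness_mm, p.pitch, p.fov_mm, p.in_plane_resolution_mm) == (
        120.0, 3.0, 1.5, 480.0, 0.9375,
    )


@pytest.mark.parametrize("field,value", [("pitch", 0.0), ("fov_mm", -1.0)])
def test_protocol_rejects_nonpositive(field, value):
    with pytest.raises(SyntheticSpecError):
        CTProtocol(**{field: value})


def test_phantom_needs_two_distinct_densities():
    with pytest.raises(SyntheticSpecError):
        PhantomSpec(
            rod_densities_mg_cm3=(100.0, 100.0),
            rod_radius_mm=5.0,
            rod_world_centers=((-40, 0, 40), (-40, 20, 40)),
        )


def test_femur_density_ordering_enforced():
    with pytest.raises(SyntheticSpecError):
        SyntheticFemurSpec(cortical_density_mg_cm3=200.0, trabecular_density_mg_cm3=300.0)


def test_identity_mapping_hu_equals_density(intact_case):
    femur, phantom, _, _ = intact_case
    vol = generate_phantom_volume(femur, phantom, slope_hu_per_mg_cm3=1.0, intercept_hu=0.0, spacing_mm=2.0)
    gt = ground_truth_masks(femur, phantom, vol)
    assert np.all(vol.voxels[gt.cortical] == femur.cortical_density_mg_cm3)
    assert np.all(vol.voxels[gt.trabecular] == femur.trabecular_density_mg_cm3)
    assert np.all(vol.voxels[~gt.femur & ~np.any(gt.rods, axis=0)] == 0.0)


def test_rod_mean_hu_follows_affine_law():
    femur = default_femur()
    phantom = PhantomSpec(
        rod_densities_mg_cm3=(0.0, 200.0),
        rod_radius_mm=6.0,
        rod_world_centers=((-45.0, -20.0, 40.0), (-45.0, 20.0, 40.0)),
    )
    vol = generate_phantom_volume(femur, phantom, slope_hu_per_mg_cm3=1.5, intercept_hu=10.0, spacing_mm=2.0)
    gt = ground_truth_masks(femur, phantom, vol)
    assert vol.voxels[gt.rods[1]].mean() == pytest.approx(1.5 * 200 + 10)
    assert vol.voxels[gt.rods[0]].mean() == pytest.approx(10.0)


def test_lesion_voxel_count_matches_sphere_volume():
    # 5 mm lesion at 1 mm spacing: (4/3)*pi*125 ~ 523.6 voxels +-10%
    lesion = LesionSpec(center=(0.0, 0.0, 90.0), radius_mm=5.0, density_mg_cm3=50.0)
    femur = default_femur(lesion)
    vol = generate_phantom_volume(femur, default_phantom(), spacing_mm=1.0)
    gt = ground_truth_masks(femur, default_phantom(), vol)
    expected = 4.0 / 3.0 * np.pi * 5.0**3
    assert gt.lesion.sum() == pytest.approx(expected, rel=0.10)


def test_determinism_same_seed_bit_identical():
    femur, phantom = preset_specs("lytic-small")
    kw = dict(noise_sd_hu=8.0, seed=42, spacing_mm=2.0)
    a = generate_phantom_volume(femur, phantom, **kw)
    b = generate_phantom_volume(femur, phantom, **kw)
    assert np.array_equal(a.voxels, b.voxels)
    c = generate_phantom_volume(femur, phantom, noise_sd_hu=8.0, seed=43, spacing_mm=2.0)
    assert not np.array_equal(a.voxels, c.voxels)


def test_noise_requires_seed():
    femur, phantom = preset_specs("intact")
    with pytest.raises(SyntheticSpecError):
        generate_phantom_volume(femur, phantom, noise_sd_hu=5.0, spacing_mm=2.0)


def test_noiseless_histogram_is_exactly_generated_densities(intact_case):
    femur, phantom, vol, _ = intact_case
    # HU = rho - 50 for slope 1, intercept -50
    expected = {
        -50.0,
        femur.cortical_density_mg_cm3 - 50.0,
        femur.trabecular_density_mg_cm3 - 50.0,
    } | {d - 50.0 for d in phantom.rod_densities_mg_cm3}
    assert set(np.unique(vol.voxels)) == expected


def test_femur_voxel_volume_matches_analytic():
    # head on the shaft axis: overlap is a spherical cap with a closed form
    femur = default_femur()
    vol = generate_phantom_volume(femur, default_phantom(), spacing_mm=1.0)
    gt = ground_truth_masks(femur, default_phantom(), vol)
    R, L, r = femur.shaft_outer_radius_mm, femur.shaft_length_mm, femur.head_radius_mm
    d = femur.head_center_offset[2]
    h = r - d
    analytic = np.pi * R**2 * L + 4.0 / 3.0 * np.pi * r**3 - np.pi * h**2 * (3 * r - h) / 3.0
    voxel = gt.femur.sum() * np.prod(vol.spacing_mm)
    assert voxel == pytest.approx(analytic, rel=0.05)


def test_ground_truth_mask_contracts(lytic_case):
    _, _, _, gt = lytic_case
    assert gt.femur.any()
    _, ncomp = ndimage.label(gt.femur, structure=CONN26)
    assert ncomp == 1
    assert not np.any(gt.lesion & ~gt.femur)  # lesion inside femur
    for i in range(len(gt.rods)):
        for j in range(i + 1, len(gt.rods)):
            assert not np.any(gt.rods[i] & gt.rods[j])


def test_lesion_outside_bone_rejected():
    lesion = LesionSpec(center=(100.0, 0.0, 60.0), radius_mm=5.0, density_mg_cm3=50.0)
    femur = default_femur(lesion)
    with pytest.raises(SyntheticSpecError, match="lesion"):
        generate_phantom_volume(femur, default_phantom(), spacing_mm=2.0)


def test_rod_overlapping_bone_rejected():
    phantom = PhantomSpec(
        rod_densities_mg_cm3=(100.0, 400.0),
        rod_radius_mm=6.0,
        rod_world_centers=((0.0, 0.0, 60.0), (-45.0, 20.0, 40.0)),
    )
    with pytest.raises(SyntheticSpecError, match="rod"):
        generate_phantom_volume(default_femur(), phantom, spacing_mm=2.0)


def test_rotated_affine_covers_anatomy():
    th = np.deg2rad(20)
    rot = np.array(
        [[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]]
    )
    femur, phantom = preset_specs("intact")
    vol = generate_phantom_volume(femur, phantom, spacing_mm=2.0, rotation=rot)
    gt = ground_truth_masks(femur, phantom, vol)
    ref = generate_phantom_volume(femur, phantom, spacing_mm=2.0)
    gt_ref = ground_truth_masks(femur, phantom, ref)
    # same anatomy volume regardless of grid orientation (within voxelization)
    v1 = gt.femur.sum() * np.prod(vol.spacing_mm)
    v2 = gt_ref.femur.sum() * np.prod(ref.spacing_mm)
    assert v1 == pytest.approx(v2, rel=0.03)
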