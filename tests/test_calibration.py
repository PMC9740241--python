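import numpy as np
import pytest

from bosfem.calibration import (
    CalibrationError,
    apply_calibration,
    fit_calibration,
)
from bosfem.synthetic_ct import RawVolume


def _volume_from_blocks(hu_blocks):
    """Stack per-rod HU blocks into a toy volume plus one mask per block."""
    n = len(hu_blocks)
    size = hu_blocks[0].size
    vox = np.zeros((n, 1, size))
    masks = []
    for i, blk in enumerate(hu_blocks):
        vox[i, 0, :] = blk.ravel()
        m = np.zeros((n, 1, size), dtype=bool)
        m[i] = True
        masks.append(m)
    vol = RawVolume(
        voxels=vox,
        spacing_mm=np.ones(3),
        affine=np.eye(4),
        gt_slope_hu_per_mg_cm3=np.nan,
        gt_intercept_hu=np.nan,
        gt_noise_sd_hu=0.0,
    )
    return vol, masks


def test_exact_line_through_three_rods():
    # rods at (0 -> 10 HU, 100 -> 160 HU, 200 -> 310 HU): density = (HU-10)/1.5
    vol, masks = _volume_from_blocks([np.full(20, 10.0), np.full(20, 160.0), np.full(20, 310.0)])
    fit = fit_calibration(vol, masks, [0.0, 100.0, 200.0], erode_rods=False)
    assert fit.slope_mg_cm3_per_hu == pytest.approx(1 / 1.5, rel=1e-12)
    assert fit.intercept_mg_cm3 == pytest.approx(-10 / 1.5, rel=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_identity_generation_recovered(intact_case):
    femur, phantom, _, _ = intact_case
    from bosfem.synthetic_ct import generate_phantom_volume, ground_truth_masks

    vol = generate_phantom_volume(femur, phantom, slope_hu_per_mg_cm3=1.0, intercept_hu=0.0, spacing_mm=2.0)
    gt = ground_truth_masks(femur, phantom, vol)
    fit = fit_calibration(vol, gt.rods, list(phantom.rod_densities_mg_cm3))
    assert fit.slope_mg_cm3_per_hu == pytest.approx(1.0, abs=1e-9)
    assert fit.intercept_mg_cm3 == pytest.approx(0.0, abs=1e-6)


def test_apply_is_affine_then_clamp():
    vol, masks = _volume_from_blocks([np.full(20, 10.0), np.full(20, 310.0)])
    fit = fit_calibration(vol, masks, [0.0, 200.0], erode_rods=False)
    out = apply_calibration(vol, fit)
    assert out.voxels[1, 0, 0] == pytest.approx(200.0)
    # HU below the zero-density HU clamps at 0
    vol.voxels[0, 0, 0] = -500.0
    out2 = apply_calibration(vol, fit)
    assert out2.voxels[0, 0, 0] == 0.0
    assert np.all(out2.voxels >= 0)


def test_noiseless_round_trip_machine_precision(intact_case):
    femur, phantom, vol, gt = intact_case
    fit = fit_calibration(vol, gt.rods, list(phantom.rod_densities_mg_cm3))
    cal = apply_calibration(vol, fit)
    rho_truth = np.zeros_like(vol.voxels)
    rho_truth[gt.trabecular] = femur.trabecular_density_mg_cm3
    rho_truth[gt.cortical] = femur.cortical_density_mg_cm3
    for rm, d in zip(gt.rods, phantom.rod_densities_mg_cm3):
        rho_truth[rm] = d
    np.testing.assert_allclose(cal.voxels, rho_truth, atol=1e-8)


def test_rod_order_invariance():
    vol, masks = _volume_from_blocks([np.full(9, 10.0), np.full(9, 160.0), np.full(9, 310.0)])
    f1 = fit_calibration(vol, masks, [0.0, 100.0, 200.0], erode_rods=False)
    f2 = fit_calibration(vol, masks[::-1], [200.0, 100.0, 0.0], erode_rods=False)
    assert f1.slope_mg_cm3_per_hu == pytest.approx(f2.slope_mg_cm3_per_hu)
    assert f1.intercept_mg_cm3 == pytest.approx(f2.intercept_mg_cm3)


def test_too_few_rods_rejected():
    vol, masks = _volume_from_blocks([np.full(9, 10.0)])
    with pytest.raises(CalibrationError):
        fit_calibration(vol, masks, [100.0])


def test_degenerate_rod_hu_rejected():
    vol, masks = _volume_from_blocks([np.full(9, 50.0), np.full(9, 50.0)])
    with pytest.raises(CalibrationError, match="degenerate"):
        fit_calibration(vol, masks, [0.0, 200.0], erode_rods=False)


def test_negative_slope_rejected():
    vol, masks = _volume_from_blocks([np.full(9, 310.0), np.full(9, 10.0)])
    with pytest.raises(CalibrationError, match="slope"):
        fit_calibration(vol, masks, [0.0, 200.0], erode_rods=False)


def _ols_slope(x, y):
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())


def ols_slope_sampling_sd(rho, true_slope, true_intercept, noise_sd, n_per_rod):
    """Delta-method SD of the fitted slope when rod-mean HU carries
    N(0, noise_sd^2 / n) error: gradient of the closed-form OLS slope at the
    noiseless point, computed by central differences on the formula itself.
    """
    x0 = true_slope * rho + true_intercept
    g = np.zeros_like(rho)
    h = 1e-5
    for i in range(len(rho)):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (_ols_slope(xp, rho) - _ols_slope(xm, rho)) / (2 * h)
    var = float(np.sum(g**2) * noise_sd**2 / n_per_rod)
    return np.sqrt(var)


def test_noisy_slope_within_ols_interval():
    """>=95% of 200 seeded replicates land inside +-1.96 closed-form SD."""
    rho = np.array([0.0, 100.0, 200.0, 400.0])
    s, c, sd, n = 1.5, 10.0, 5.0, 500
    sd_slope = ols_slope_sampling_sd(rho, s, c, sd, n)
    true = 1.0 / s
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        blocks = [s * r + c + rng.normal(0, sd, n) for r in rho]
        vol, masks = _volume_from_blocks(blocks)
        fit = fit_calibration(vol, masks, list(rho), erode_rods=False)
        if abs(fit.slope_mg_cm3_per_hu - true) <= 1.96 * sd_slope:
            hits += 1
    assert hits >= 190  # 95% of 200


def test_eroded_rod_sampling_excludes_rim():
    # rod block with a corrupted rim layer: erosion must ignore it
    vox = np.zeros((10, 5, 5))
    vox[0:5] = 160.0
    vox[0] = 1e4  # partial-volume-like rim on one face of rod 1
    vox[5:10] = 310.0
    vol = RawVolume(
        voxels=vox,
        spacing_mm=np.ones(3),
        affine=np.eye(4),
        gt_slope_hu_per_mg_cm3=np.nan,
        gt_intercept_hu=np.nan,
        gt_noise_sd_hu=0.0,
    )
    m1 = np.zeros((10, 5, 5), dtype=bool)
    m1[0:5] = True
    m2 = np.zeros((10, 5, 5), dtype=bool)
    m2[5:10] = True
    fit = fit_calibration(vol, [m1, m2], [100.0, 200.0], erode_rods=True)
    # eroded mean of rod 1 is exactly 160 -> slope (200-100)/(310-160)
    assert fit.slope_mg_cm3_per_hu == pytest.approx(100.0 / 150.0, rel=1e-9)
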