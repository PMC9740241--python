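import numpy as np
import pytest

from bosfem.calibration import apply_calibration, fit_calibration
from bosfem.geometry import align_and_crop, find_head_center, find_knee_center
from bosfem.segmentation import segment_femur
from bosfem.synthetic_ct import generate_phantom_volume, ground_truth_masks, preset_specs


@pytest.fixture(scope="session")
def intact_case():
    """Noiseless intact femur + phantom volume with ground truth."""
    femur, phantom = preset_specs("intact")
    vol = generate_phantom_volume(
        femur, phantom, slope_hu_per_mg_cm3=1.0, intercept_hu=-50.0, spacing_mm=1.5
    )
    gt = ground_truth_masks(femur, phantom, vol)
    return femur, phantom, vol, gt


@pytest.fixture(scope="session")
def lytic_case():
    femur, phantom = preset_specs("lytic-large")
    vol = generate_phantom_volume(
        femur, phantom, slope_hu_per_mg_cm3=1.0, intercept_hu=-50.0, spacing_mm=1.5
    )
    gt = ground_truth_masks(femur, phantom, vol)
    return femur, phantom, vol, gt


@pytest.fixture(scope="session")
def intact_calibrated(intact_case):
    femur, phantom, vol, gt = intact_case
    fit = fit_calibration(vol, gt.rods, list(phantom.rod_densities_mg_cm3))
    return apply_calibration(vol, fit)


@pytest.fixture(scope="session")
def intact_mask(intact_case, intact_calibrated):
    _, _, _, gt = intact_case
    return segment_femur(intact_calibrated, rod_masks=gt.rods)


@pytest.fixture(scope="session")
def intact_aligned(intact_case, intact_calibrated, intact_mask):
    _, _, _, _ = intact_case
    hc, hr = find_head_center(intact_mask)
    kc = find_knee_center(intact_mask, hc)
    return align_and_crop(
        intact_calibrated, intact_mask, hc, kc, head_radius_mm=hr
    )


@pytest.fixture()
def bar_mesh():
    """1 x 1 x 10 mm bar of 1 mm voxels with top/bottom node sets."""
    from bosfem.meshing import mask_to_tets

    mesh = mask_to_tets(np.ones((1, 1, 10), dtype=bool), 1.0)
    z = mesh.nodes[:, 2]
    top = np.where(z >= z.max() - 1e-9)[0]
    bot = np.where(z <= 1e-9)[0]
    return mesh, top, bot


def roller_pins(mesh, bottom_nodes):
    """Minimal pinned DOFs to remove in-plane rigid modes for roller BCs."""
    b0 = bottom_nodes[0]
    pins = [3 * b0, 3 * b0 + 1]
    for b in bottom_nodes[1:]:
        if abs(mesh.nodes[b, 0] - mesh.nodes[b0, 0]) > 1e-9:
            pins.append(3 * b + 1)
            break
    return tuple(pins)
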