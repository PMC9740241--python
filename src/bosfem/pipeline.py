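"""End-to-end orchestration: synthesize/ingest -> calibrate -> segment ->
align/crop -> mesh -> materials -> solve -> score -> classify -> report.

Every stage writes its parameters and an SHA-256 checksum of its main array
into a JSON manifest so a run can be audited and replayed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import calibration, fe_solver, geometry, materials, meshing, scoring, segmentation
from .config import RunConfig
from .scoring import Patient, ScoreDatabase
from .synthetic_ct import generate_phantom_volume, ground_truth_masks, preset_specs

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    f_max_n: float
    bos_score: scoring.BOSScore
    risk_category: str
    report: dict | None
    manifest: dict
    simulation: fe_solver.SimulationResult
    mesh: meshing.TetMesh


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    db: ScoreDatabase | None = None,
) -> PipelineResult:
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
                raise PipelineError(name, str(exc)) from exc

        return deco

    @stage("synth")
    def synth():
        femur, phantom = preset_specs(config.preset)
        vol = generate_phantom_volume(
            femur,
            phantom,
            config.protocol,
            slope_hu_per_mg_cm3=config.hu_slope,
            intercept_hu=config.hu_intercept,
            noise_sd_hu=config.noise_sd_hu,
            seed=config.seed,
            spacing_mm=config.spacing_mm,
        )
        return femur, phantom, vol

    femur_spec, phantom_spec, raw = synth
    gt = ground_truth_masks(femur_spec, phantom_spec, raw)
    manifest["stages"]["synth"] = {
        "preset": config.preset,
        "seed": config.seed,
        "shape": list(raw.voxels.shape),
        "checksum": _sha(raw.voxels),
    }

    @stage("calibrate")
    def calibrate():
        fit = calibration.fit_calibration(
            raw, gt.rods, list(phantom_spec.rod_densities_mg_cm3)
        )
        return fit, calibration.apply_calibration(raw, fit)

    fit, cal = calibrate
    manifest["stages"]["calibrate"] = {"fit": fit.to_dict(), "checksum": _sha(cal.voxels)}

    @stage("segment")
    def segment():
        return segmentation.segment_femur(
            cal,
            density_threshold_mg_cm3=config.density_threshold_mg_cm3,
            closing_radius_mm=config.closing_radius_mm,
            rod_masks=gt.rods,
        )

    mask = segment
    manifest["stages"]["segment"] = {
        "threshold": config.density_threshold_mg_cm3,
        "voxels": int(mask.voxels.sum()),
        "checksum": _sha(mask.voxels),
    }

    @stage("align")
    def align():
        head_c, head_r = geometry.find_head_center(mask)
        knee_c = geometry.find_knee_center(mask, head_c)
        lesion_pts = None
        if gt.lesion is not None and gt.lesion.any():
            idx = np.argwhere(gt.lesion).astype(float)
            hom = np.column_stack([idx, np.ones(len(idx))])
            lesion_pts = (raw.affine @ hom.T).T[:, :3]
        return geometry.align_and_crop(
            cal,
            mask,
            head_c,
            knee_c,
            head_radius_mm=head_r,
            lesion_world_points=lesion_pts,
            margin_mm=config.target_edge_mm,
        )

    aligned = align
    manifest["stages"]["align"] = {
        "head_radius_mm": aligned.head_radius_mm,
        "knee_center": aligned.knee_center.tolist(),
        "crop_plane_z": aligned.crop_plane_z,
        "transform": aligned.world_to_aligned.tolist(),
        "checksum": _sha(aligned.density),
    }

    @stage("mesh")
    def mesh_():
        return meshing.voxels_to_tets(aligned, target_edge_mm=config.target_edge_mm)

    mesh = mesh_
    manifest["stages"]["mesh"] = {
        "elements": len(mesh.elements),
        "nodes": len(mesh.nodes),
        "volume_mm3": mesh.total_volume_mm3,
        "checksum": _sha(mesh.nodes),
    }

    @stage("materials")
    def mats():
        return materials.map_materials(mesh, config.material_law)

    mat = mats
    manifest["stages"]["materials"] = {
        "E_range_mpa": [float(mat.youngs_modulus_mpa.min()), float(mat.youngs_modulus_mpa.max())],
        "checksum": _sha(mat.youngs_modulus_mpa),
    }

    @stage("solve")
    def solve():
        load = fe_solver.make_stance_load_case(
            mesh,
            aligned.head_center,
            aligned.head_radius_mm,
            cap_angle_deg=config.cap_angle_deg,
            displacement_increment_mm=config.displacement_increment_mm,
            max_displacement_mm=config.max_displacement_mm,
            force_drop_fraction=config.force_drop_fraction,
        )
        return fe_solver.solve_to_failure(
            mesh, mat, load, newton_tol=config.newton_tol, max_iter=config.max_newton_iter
        )

    sim = solve
    manifest["stages"]["solve"] = {
        "f_max_n": sim.f_max_n,
        "steps": len(sim.curve) - 1,
        "plastic_elements_at_peak": len(sim.plastic_elements_at_peak),
    }

    @stage("score")
    def score_():
        patient = Patient(body_weight_kg=config.body_weight_kg)
        s = scoring.compute_bos(sim.f_max_n, patient, config.g_n_per_kg)
        cat = scoring.classify_risk(s, config.high_risk_cut, config.moderate_upper)
        return s, cat

    bos, category = score_
    manifest["stages"]["score"] = {"bos": bos.value, "category": category}

    report = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        @stage("report")
        def report_():
            return scoring.render_report(bos, category, db, sim, out, mesh=mesh)

        report = report_
        meshing.write_vtk(
            mesh, out / "femur_mesh.vtk", {"eqps_at_peak": sim.eqps_at_peak}
        )
        (out / "simulation.json").write_text(json.dumps(sim.to_dict(), indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        f_max_n=sim.f_max_n,
        bos_score=bos,
        risk_category=category,
        report=report,
        manifest=manifest,
        simulation=sim,
        mesh=mesh,
    )
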