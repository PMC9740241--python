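# bosfem

CT-based femoral bone-strength scoring for femurs with osteolytic lesions,
plus a decision-impact audit for a pilot cohort. The pipeline runs entirely
on synthetic data generated in-repo, so every stage is testable offline:

1. **synthetic_ct** — CT-like HU volumes of an idealized femur (cortical
   shell + trabecular core + optional lytic lesion) with in-field
   calibration rods and a known HU↔density law.
2. **calibration** — OLS fit of known rod densities against mean rod HU;
   per-voxel affine map to calcium-equivalent density (mg/cm³, clamped ≥ 0).
3. **segmentation** — threshold → largest 26-connected component →
   morphological closing → hole fill (classical stand-in for a learned
   segmentation, same mask contract).
4. **geometry** — femoral-head sphere fit, knee-centre estimate, rigid
   alignment of the head→knee axis onto −z, proximal-half crop (extended
   distally to cover the lesion).
5. **meshing** — structured 6-tets-per-voxel decomposition (volume-exact),
   optional integer coarsening, per-element density by trilinear centroid
   sampling.
6. **materials** — power laws density → Young's modulus and yield stress,
   with positive floors; von Mises perfect plasticity.
7. **fe_solver** — displacement-controlled nonlinear FE solve (linear tets,
   radial return, consistent tangent, Newton with a tangent predictor per
   increment). Strength = peak total reaction force at the loaded head cap;
   weakest location = plastic elements at the peak step.
8. **scoring** — score = strength (N) / body weight (N, g = 9.81);
   risk: `< 7.5` high, `7.5–8.5` (inclusive) moderate, `> 8.5` low;
   report with percentile vs. a score database and PPV/NPV at the 7.5 cut.
9. **audit** — femur-level cohort cross-tabulations (physician estimate vs.
   score category vs. treatment, fracture/death follow-up, delivery times,
   usage), with the packaged 42-femur pilot fixture.

## CLI

```sh
bos synth --preset lytic-small --seed 1 --out run/ct       # NIfTI + ground-truth sidecar
bos segment --in run/ct/volume.nii.gz --sidecar run/ct/sidecar.json --out run/mask.nii.gz
bos score --preset lytic-large --weight-kg 80 --out run/report/
bos audit --out run/audit/                                 # packaged pilot fixture
bos pipeline --config cfg.json --out run/full/             # end-to-end with manifest
```

Presets: `intact`, `lytic-small`, `lytic-medium`, `lytic-large`. Every run
writes a JSON manifest (parameters, seeds, stage checksums) sufficient to
replay it. Defaults live in `bosfem.config.RunConfig` and can be overridden
via a JSON or TOML config file.

## Data files

- `src/bosfem/data/table2_cohort.csv` — 42 femur-level pilot records
  (physician risk, score risk, treatment, outcomes, delivery, usage).
- `src/bosfem/data/example_database.csv` — synthetic 62-record score
  database reproducing the prior-cohort predictive values (PPV 39 %,
  NPV 100 %, sensitivity 100 %, specificity 74 %) used by the report.
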