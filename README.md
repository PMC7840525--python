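# gratiomap

Aggregate MR g-ratio modelling, single-point calibration of myelin
biomarkers, and voxel-map fusion with tissue-probability masking.

The voxel is modelled as axonal, myelin, and extracellular compartments
(AVF + MVF + EVF = 1) and the aggregate g-ratio is the closed form
`g = sqrt(1 − MVF/(MVF + AVF))`, which reduces to the microscopic `RI/RO`
for a single fibre.  Myelin biomarkers (MWF, BPF, MTsat, MTV, …) relate to
MVF linearly, `MVF = α·M + β`; since α and β are scanner- and
sequence-dependent, the package implements the two single-point calibration
(SPC) procedures used in vivo — against a reference MVF or against a
reference g-ratio (solved in closed form) — together with a synthetic
ground-truth cohort generator and a Bland–Altman evaluation harness that
quantifies the bias/error trade-off of calibration.

## Layout

| module                  | contents                                                                                   |
| ----------------------- | ------------------------------------------------------------------------------------------ |
| `gratiomap.core`        | volume-fraction types, aggregate g-ratio, NODDI fraction conversion, compartment biomarkers |
| `gratiomap.calibration` | linear law, `spc_mvf`, `spc_gratio` (closed form), identity calibration                    |
| `gratiomap.cohort`      | seeded synthetic white-matter cohorts (axon populations, demyelination arms, biomarkers)   |
| `gratiomap.evaluation`  | Bland–Altman analysis and the biomarker × calibration-mode experiment runner               |
| `gratiomap.maps`        | NIfTI front end: TPM overlap masking, voxel-wise g-ratio maps, ROI calibration             |
| `gratiomap.cli`         | `gratiomap` command-line interface                                                         |

## CLI

```sh
# synthetic ground-truth cohort (CSV + config echo)
gratiomap simulate --seed 1 --n 200 --out cohort.csv

# biomarker x calibration-mode experiment (bias/error table)
gratiomap evaluate --cohort cohort.csv --out table.csv --json summary.json

# single-point calibration of voxel maps against a reference ROI
gratiomap calibrate --myelin mtsat.nii --nu nu.nii --nu0 nu0.nii \
    --roi pyramid_roi.nii --reference g --reference-value 0.71 \
    --out calib.json

# masked g-ratio map (+ companion validity mask and QC JSON)
gratiomap map --myelin mtsat.nii --nu nu.nii --nu0 nu0.nii \
    --tpm wm_tpm_a.nii --tpm wm_tpm_b.nii --threshold 0.5 \
    --calibration calib.json --out g.nii --qc qc.json
```

All co-processed maps must already be co-registered (same grid and affine
to 1e-4); misaligned inputs are rejected, never resampled.  Missing voxels
are NaN in the output NIfTI and also recorded in the companion
`*_validmask.nii` volume.

## Python API sketch

```python
import gratiomap as gm

cfg = gm.CohortConfig(seed=1, n_samples=200,
                      biomarker_specs=(gm.BiomarkerSpec("M", alpha=0.8, beta=0.05),))
frame = gm.cohort_frame(gm.build_cohort(cfg))
result = gm.run_calibration_experiment(frame)   # none / g_spc / mvf_spc
print(result.table)                             # alpha_eff, bias, error per condition
```
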