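# glioresponse

Discrimination of treated vs. control glioblastoma-bearing subjects from two
MR modalities, implemented as a tested, reusable pipeline:

* **Radiomics (MRI)** — 90 features per masked T2w slice: 42 texture
  statistics from four texture matrices (GLCM, GLRLM, GLSZM, NGTDM) computed
  on the tumor bounding box, plus 48 Minkowski functionals (area, perimeter,
  Euler number at 16 threshold levels) computed on the mask itself. Linear
  classification with leave-one-subject-out CV and slice-voting (SVS:
  mask-size-weighted average of slice responses) per subject.
* **Source extraction (MRSI)** — convex nonnegative matrix factorization of
  tumor-complete voxel spectra (sources are nonnegative combinations of data
  spectra; mixing weights nonnegative; the spectra themselves may go
  negative). NNLS source weights are the classification features; 20-fold
  grouped CV and voxel-voting (VVS: majority over voxel labels) per subject.
* **Feature selection** — univariate Welch t-test filter, embedded RFE with
  mean-|weight| relevance across K fold-models, wrapper RFE driven by CV
  accuracy, and the hybrid embedded→wrapper chain (top-30 kept, then
  refined).
* **Nosological maps** — per-voxel certainty via the piecewise posterior
  (0 / π / 1 on separable training scores, Platt sigmoid otherwise), rendered
  over the anatomical image with red contours on misclassified voxels and
  class bars.
* **Synthetic cohorts** — seeded generator producing slice records whose
  spectra are noisy convex mixtures of metabolite-like source profiles with
  class-dependent mixing, and whose images carry class-dependent texture
  (hypointense foci in treated tumors). Every downstream stage is testable
  without any external data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (feature-count
conformance, brute-force texture oracle equivalence, Minkowski exactness,
convex-NMF properties and source recovery, feature-selection recovery
simulations, voting fixtures, posterior formula, and the end-to-end
synthetic benchmark). The brute-force oracles live in `tests/oracles.py`
and share no code with the package.

## CLI

```bash
glioresponse simulate  --seed 1 --out run_out           # write a cohort
glioresponse features  --seed 1 --out run_out           # radiomic table
glioresponse sources   --seed 1 --out run_out           # cNMF sources
glioresponse benchmark --seed 1 --out run_out           # both pipelines + report
```

All commands accept `--config run.yaml` with keys matching
`glioresponse.pipeline.RunConfig` (cohort sizes, model types, selection
schemes, sweep ranges, CV protocols, `paper_mode` for a joint
train+holdout cNMF fit, …). Outputs land under the run directory with a
`manifest.json` recording the config hash and seeds.

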