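# tpmrisk

A tested, self-contained re-implementation of a claims-based
risk-prediction pipeline: synthetic longitudinal claims generation,
case-control cohort construction from diagnosis codes, temporal phenomic
map (TPM) encoding, a small fixed convolutional neural network, 5-fold
cross-validated evaluation, and occlusion-sensitivity feature importance.

The pipeline targets the prediction of new-onset psoriatic arthropathy
(ICD-9-CM 696.0) among psoriasis patients (696.1/696.8) from 2.5 years
(131 weeks) of diagnosis/prescription history, with a 0.5-year (25-week)
prediction gap before the index date. Since the original claims database
is not publicly available, a seeded synthetic generator with planted
ground truth stands in for it; every downstream stage is validated by
signal-recovery and null experiments against that ground truth.

## Modules

| module | role |
| --- | --- |
| `tpmrisk.synth` | seeded synthetic claims populations (Poisson visit process, planted risk-code signal, qualifying case patterns) |
| `tpmrisk.cohort` | case/control definitions, index dates, eligibility filters, 1:4 control sampling |
| `tpmrisk.vocab_tpm` | code vocabularies (1098 diagnosis + 830 drug categories), code truncation, TPM encoding, per-row max normalization |
| `tpmrisk.model` | the 8-hidden-layer CNN (conv 32@1x131 / avg-pool 2x2 / conv 2@1x131 / max-pool 1x3 / flatten / concat age+sex / dense 128 / dropout 0.3), trained with Adam on binary cross-entropy — implemented directly on NumPy |
| `tpmrisk.evaluate` | 80:20 holdout split, stratified 5-fold CV, AUROC (Mann-Whitney), optimal threshold, confusion metrics |
| `tpmrisk.importance` | occlusion AUROC-loss ranking and logistic-regression odds ratios |
| `tpmrisk.experiments` | end-to-end signal-recovery / null experiments used by tests and the acceptance report |

The CNN is written on plain NumPy (Toeplitz-unrolled time-axis
convolutions evaluated as matrix products, hand-derived backprop, Adam)
because no deep-learning framework is assumed at run time; gradients are
verified against finite differences in the test suite.

## CLI

```sh
tpmrisk simulate --config sim.yaml --seed 1 --out data/
tpmrisk build-cohort --claims data/ --seed 1 --out cohort.csv
tpmrisk build-tpm --claims data/ --cohort cohort.csv --compact --out tpm/
tpmrisk train --tpm tpm/ --seed 1 --out model/
tpmrisk evaluate --model model/ --tpm tpm/ --out eval/
tpmrisk importance --model model/ --tpm tpm/ --out imp/
```

Config files are YAML mappings of the `SimConfig` / `CohortCriteria` /
`ModelSpec` dataclass fields. `--compact` restricts the vocabulary to
codes observed in the claims (recommended for small simulations; the
default is the full 1928-row vocabulary).

## File formats

- claims CSV: `patient_id,event_date,kind,code,setting,days_supplied`
  (ISO-8601 dates; `setting` only for diagnoses, `days_supplied` only
  for prescriptions)
- demographics CSV: `patient_id,birth_date,sex`
- cohort CSV: `patient_id,label,index_date,age_at_index,sex`
- TPM store: `tpm.npz` (maps, age/sex auxiliaries, labels, ids) with a
  `tpm.json` sidecar recording vocabulary hash, window spec and
  normalization statistics. Row 0 is the first diagnosis code; column 0
  is the oldest week of the observation window.
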