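# Published daily transcription quotients (GTQ) for dosing regimens.
# Reference values for the validation battery.  Reproducing them requires
# the authoritative supplementary PK parameter sets; with the shipped
# placeholder PK defaults these rows are reported as skipped, not failed.
schema_version: 1
rows:
  - {drug: dexamethasone,      dose_mg: 1,   schedule: qd,  route: IV,   gtq: 0.29}
  - {drug: dexamethasone,      dose_mg: 10,  schedule: qd,  route: IV,   gtq: 0.736}
  - {drug: dexamethasone,      dose_mg: 10,  schedule: bid, route: IV,   gtq: 0.788}
  - {drug: dexamethasone,      dose_mg: 40,  schedule: qd,  route: IV,   gtq: 0.91}
  - {drug: dexamethasone,      dose_mg: 1,   schedule: qd,  route: oral, gtq: 0.29}
  - {drug: dexamethasone,      dose_mg: 10,  schedule: qd,  route: oral, gtq: 0.75}
  - {drug: dexamethasone,      dose_mg: 40,  schedule: qd,  route: oral, gtq: 0.91}
  - {drug: methylprednisolone, dose_mg: 5,   schedule: qd,  route: IV,   gtq: 0.19}
  - {drug: methylprednisolone, dose_mg: 20,  schedule: qd,  route: IV,   gtq: 0.35}
  - {drug: methylprednisolone, dose_mg: 20,  schedule: bid, route: IV,   gtq: 0.45}
  - {drug: methylprednisolone, dose_mg: 80,  schedule: qd,  route: IV,   gtq: 0.54}
  - {drug: methylprednisolone, dose_mg: 80,  schedule: bid, route: IV,   gtq: 0.72}
  - {drug: methylprednisolone, dose_mg: 320, schedule: qd,  route: IV,   gtq: 0.73}
  - {drug: methylprednisolone, dose_mg: 320, schedule: bid, route: IV,   gtq: 0.90}
  - {drug: prednisone,         dose_mg: 5,   schedule: qd,  route: oral, gtq: 0.24}
  - {drug: prednisone,         dose_mg: 10,  schedule: qd,  route: oral, gtq: 0.31}
  - {drug: prednisone,         dose_mg: 10,  schedule: bid, route: oral, gtq: 0.41}
  - {drug: prednisone,         dose_mg: 20,  schedule: qd,  route: oral, gtq: 0.40}
  - {drug: prednisone,         dose_mg: 100, schedule: qd,  route: oral, gtq: 0.60}
  - {drug: prednisone,         dose_mg: 100, schedule: bid, route: oral, gtq: 0.81}
  - {drug: prednisone,         dose_mg: 400, schedule: qd,  route: oral, gtq: 0.77}
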