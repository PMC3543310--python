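# Reference in vitro assay: 200 nM androstenedione added to 2 ml of medium
# over 600,000 granulosa cells (300,000/ml in 12-well plates), 48 h readout.
# sigma_l is the calibrated transcription random effect of the reference
# (baseline) study; set fsh_ng_ml to 20 for the FSH-stimulated arm.
preset: flux_assay
experiment:
  cells_per_ml: 300000.0
  medium_volume_ml: 2.0
  initial_medium_nM:
    A: 200.0
    T: 0.0
    E1: 0.0
    E2: 0.0
  fsh_ng_ml: 0.0
  sigma_l: 0.685
  duration_min: 2880.0
  fold_changes: {f_cyp19: 1.0, f_hsd17b1: 1.0, f_m: 1.0}
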