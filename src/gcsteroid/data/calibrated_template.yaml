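# Estrous-cycle forcing templates for the three-compartment ovary model.
# The shape waveforms, cell numbers, compartment volumes, snapshot times and
# the in vivo transcription effect sigma_l are not printed measurements; this
# bundled template was tuned once so that the simulated A->E1 reference flux
# at the diestrus/proestrus/estrus snapshots matches the in vivo flux-analysis
# reference values (6.09e-9, 6.17e-9, 5.10e-9 pmoles/min/cell) to within ~2%.
# Shapes are sampled (time, value) pairs interpolated linearly and
# periodically over a 4-day (5760 min) cycle, unit-normalised peaks: a small
# FSH plateau through diestrus/early proestrus, then the pre-ovulatory
# FSH/androgen surge in late proestrus.
preset: calibrated_template
cycle_minutes: 5760.0
stages:
  diestrus: [0.0, 1440.0]
  proestrus: [1440.0, 2880.0]
  estrus: [2880.0, 4320.0]
  metestrus: [4320.0, 5760.0]
snapshot_minutes:
  diestrus: 720.0
  proestrus: 1680.0
  estrus: 4080.0
q_shape:
  FSH:
    t: [0.0, 1800.0, 2000.0, 2160.0, 2400.0, 2640.0, 5760.0]
    v: [0.085, 0.085, 0.0, 0.0, 1.0, 0.0, 0.0]
  A:
    t: [0.0, 2160.0, 2400.0, 2640.0, 5760.0]
    v: [0.0, 0.0, 1.0, 0.0, 0.0]
  T:
    t: [0.0, 2160.0, 2400.0, 2640.0, 5760.0]
    v: [0.0, 0.0, 1.0, 0.0, 0.0]
geometry:
  n_gcs: 6.17e+07
  n_others: 6.17e+07
  v_ext_ml: 0.016666666666666666
  v_others_ml: 0.016666666666666666
sigma_l: 0.36
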