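# Highest-posterior (maximum a posteriori) parameter vector from the
# hierarchical Bayesian calibration of the in vitro model, layered on the
# deterministic point values.  The `statistical` block carries the MAP of the
# hyperparameters, the per-study transcription random effects sigma_L (one per
# calibration study), and the two log-scale measurement SDs.
preset: table4_map
parameters:
  delta_mrna: 6.0e-03
  delta_prot: 3.0e-03
  mrna0:
    Cyp19: 4.96e-08
    Hsd17b1: 1.03e-07
    Hsd17b2: 7.0e-09
  prot0:
    Cyp19: 0.1
    Hsd17b1: 0.21
    Hsd17b2: 0.014
  nu_mrna:
    Cyp19: 2.976e-10
    Hsd17b1: 6.18e-10
    Hsd17b2: 4.2e-11
  nu_prot:
    Cyp19: 6048.387096774193
    Hsd17b1: 6116.504854368932
    Hsd17b2: 6000.0
  kappa:
    Cyp19: 2080000.0
    Hsd17b1: 604000.0
  lam:
    "Cyp19,A": 1.07e-07
    "Cyp19,T": 2.67e-07
    "Hsd17b1,A": 5.65e-08
    "Hsd17b1,E1": 1.78e-05
    "Hsd17b2,T": 6.65e-08
    "Hsd17b2,E2": 7.91e-08
  xi:
    "Cyp19,A": 8.25e-09
    "Cyp19,T": 1.24e-08
    "Hsd17b1,A": 4.84e-05
    "Hsd17b1,E1": 1.3e-06
    "Hsd17b2,T": 5.67e-06
    "Hsd17b2,E2": 5.4e-06
  k_out:
    A: 1.0e-08
    T: 1.0e-08
    E1: 1.0e-08
    E2: 1.0e-08
    FSH: 1.0e-08
  r_oi:
    A: 0.0124
    T: 0.013
    E1: 0.0084
    E2: 0.0108
    FSH: 1.0
  v_gc: 2.7e-10
  f_ov: 0.2654
  v_ov_diestrus: 0.05
statistical:
  mu0: 1.46
  sigma1: 0.265
  sigma2: 0.626
  sigma3: 0.501
  sigma_l: [0.117, 1.99, 0.0293, 0.0193, 2.86, 0.0213, 0.153, 0.612, 0.114, 0.685]
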