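# Deterministic point values for one granulosa cell.
# Synthesis rates are derived exactly from the steady-state identities
# nu_mRNA = delta_mRNA * mRNA0 and nu_prot = delta_prot * prot0 / mRNA0,
# so baseline gene expression is at equilibrium by construction.
# The FSH slope factors and the aromatase/Hsd17b1 Vmax & Km values are
# calibrated quantities; here they default to the geometric means of their
# priors (kappa defaults to 0: no FSH regulation until calibrated).
preset: table2_defaults
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
    Cyp19: 0.0
    Hsd17b1: 0.0
  lam:
    "Cyp19,A": 1.33e-07
    "Cyp19,T": 1.33e-07
    "Hsd17b1,A": 7.59e-08
    "Hsd17b1,E1": 1.03e-05
    "Hsd17b2,T": 6.65e-08
    "Hsd17b2,E2": 7.91e-08
  xi:
    "Cyp19,A": 8.1e-09
    "Cyp19,T": 3.24e-08
    "Hsd17b1,A": 4.32e-05
    "Hsd17b1,E1": 5.29e-06
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
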