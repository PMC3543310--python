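# Prior distributions of the ten calibrated kinetic/regulatory parameters and
# of the hierarchical/statistical parameters.
# lognormal args are (geometric mean, geometric SD); uniform args are
# (min, max); halfnormal args are (SD,) with mode at zero.
preset: table3_priors
priors:
  kappa_cyp19: {family: uniform, args: [0.0, 1.0e+07]}
  kappa_hsd17b1: {family: uniform, args: [0.0, 1.0e+06]}
  lam_cyp19_a: {family: lognormal, args: [1.33e-07, 1.2]}
  lam_cyp19_t: {family: lognormal, args: [1.33e-07, 2.0]}
  lam_hsd17b1_a: {family: lognormal, args: [7.59e-08, 2.0]}
  lam_hsd17b1_e1: {family: lognormal, args: [1.03e-05, 2.0]}
  xi_cyp19_a: {family: lognormal, args: [8.1e-09, 1.2]}
  xi_cyp19_t: {family: lognormal, args: [3.24e-08, 2.0]}
  xi_hsd17b1_a: {family: lognormal, args: [4.32e-05, 2.0]}
  xi_hsd17b1_e1: {family: lognormal, args: [5.29e-06, 2.0]}
  mu0: {family: lognormal, args: [1.0, 2.0]}
  sigma1: {family: halfnormal, args: [0.5]}
  sigma2: {family: halfnormal, args: [0.2]}
  sigma3: {family: halfnormal, args: [0.2]}
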