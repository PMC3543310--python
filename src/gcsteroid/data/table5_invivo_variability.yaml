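# In vivo variability distributions for parameters that were not calibrated
# from in vitro data.  Used as Monte-Carlo inputs for the cross-validation and
# endocrine-disruption simulations.  lognormal args are (geometric mean,
# geometric SD).  Dose-rate units: pg/min for FSH, pmoles/min for A and T.
# Note: the Hsd17b2 lam/xi geometric means here differ from the deterministic
# point values (lam Hsd17b2,E2: 7.91e-6 vs 7.91e-8; xi Hsd17b2,T: 5.67e-8 vs
# 5.67e-6); deterministic simulations default to the point values and the
# loader flags the discrepancy.
preset: table5_invivo_variability
priors:
  q_base_fsh: {family: lognormal, args: [330.0, 1.2]}
  q_scale_fsh: {family: lognormal, args: [1450.0, 1.2]}
  q_base_a: {family: lognormal, args: [1.2, 1.2]}
  q_scale_a: {family: lognormal, args: [18.0, 1.2]}
  q_base_t: {family: lognormal, args: [3.0, 1.2]}
  q_scale_t: {family: lognormal, args: [13.0, 1.2]}
  f_ov: {family: lognormal, args: [0.2654, 1.1]}
  k_out_a: {family: lognormal, args: [1.0e-08, 2.0]}
  r_oi_a: {family: lognormal, args: [0.0124, 1.2]}
  k_out_t: {family: lognormal, args: [1.0e-08, 2.0]}
  r_oi_t: {family: lognormal, args: [0.013, 1.2]}
  k_out_e1: {family: lognormal, args: [1.0e-08, 2.0]}
  r_oi_e1: {family: lognormal, args: [0.0084, 1.2]}
  k_out_e2: {family: lognormal, args: [1.0e-08, 2.0]}
  r_oi_e2: {family: lognormal, args: [0.0108, 1.2]}
  delta_mrna: {family: lognormal, args: [0.006, 1.2]}
  delta_prot: {family: lognormal, args: [0.003, 1.2]}
  nu_mrna_cyp19: {family: lognormal, args: [3.0e-10, 1.2]}
  nu_mrna_hsd17b1: {family: lognormal, args: [6.0e-10, 1.2]}
  nu_mrna_hsd17b2: {family: lognormal, args: [4.2e-11, 1.2]}
  nu_prot_cyp19: {family: lognormal, args: [6000.0, 1.2]}
  nu_prot_hsd17b1: {family: lognormal, args: [6300.0, 1.2]}
  nu_prot_hsd17b2: {family: lognormal, args: [6000.0, 1.2]}
  lam_hsd17b2_t: {family: lognormal, args: [6.65e-08, 2.0]}
  lam_hsd17b2_e2: {family: lognormal, args: [7.91e-06, 2.0]}
  xi_hsd17b2_t: {family: lognormal, args: [5.67e-08, 2.0]}
  xi_hsd17b2_e2: {family: lognormal, args: [5.4e-06, 2.0]}
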