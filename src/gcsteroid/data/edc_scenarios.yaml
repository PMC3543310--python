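# Fold-changes measured in vitro (4 h, 10 uM chemical; letrozole 50 nM from
# the literature) on granulosa cells: direct aromatase activity (microsomal
# tritiated-water assay) and Cyp19/Hsd17b1 mRNA levels, treated over control.
# `significant` flags mark fold-changes that differed from control (p < 0.05);
# unmeasured entries are 1.0.  The aromatase Km fold f_M is the reciprocal of
# the activity fold.
preset: edc_scenarios
scenarios:
  atrazine:
    activity_fold: 0.99
    f_cyp19: 1.94
    f_hsd17b1: 3.04
    significant: {activity: false, f_cyp19: true, f_hsd17b1: true}
  bisphenol_a:
    activity_fold: 0.94
    f_cyp19: 1.61
    f_hsd17b1: 1.41
    significant: {activity: false, f_cyp19: true, f_hsd17b1: false}
  hpte:
    activity_fold: 0.89
    f_cyp19: 1.06
    f_hsd17b1: 1.32
    significant: {activity: true, f_cyp19: false, f_hsd17b1: false}
  vinclozolin_m2:
    activity_fold: 0.98
    f_cyp19: 3.13
    f_hsd17b1: 1.61
    significant: {activity: false, f_cyp19: true, f_hsd17b1: true}
  letrozole:
    activity_fold: 0.29
    f_cyp19: 1.0
    f_hsd17b1: 1.0
    significant: {activity: true, f_cyp19: false, f_hsd17b1: false}
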