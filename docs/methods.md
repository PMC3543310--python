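# Methods

`gcsteroid` is a mechanistic model of the last steps of sex-steroid synthesis
in a rat ovarian granulosa cell (GC): expression of the three terminal
steroidogenic enzymes and the interconversion of the four steroids they act
on, embedded in either a culture well (in vitro) or a three-compartment ovary
(in vivo).  This note records the model, its assumptions, the numerical
choices, and what the synthetic-data experiments do and do not demonstrate.

## The cell model

State variables are *quantities* per cell — pg for mRNA, protein and FSH,
pmoles for steroids — not concentrations.  The Michaelis constants are given
in pmoles per cell, so quantities are the natural units; concentrations are
derived views (quantity / compartment volume).

**Gene expression.**  For the FSH-inducible enzymes (aromatase Cyp19 and the
activating dehydrogenase Hsd17b1):

    d mRNA_e/dt = sigma_L * f_e * nu_mRNA,e * (1 + kappa_e * FSH_GC)
                  - delta_mRNA * mRNA_e

and for the inactivating Hsd17b2 (neither FSH- nor disruptor-sensitive):

    d mRNA/dt = sigma_L * nu_mRNA - delta_mRNA * mRNA

with translation `d e/dt = nu_prot,e * mRNA_e - delta_prot * e` for all
three.  `sigma_L` (unitless) is a per-study random effect on baseline
transcription capturing differences in cell pre-treatment; `f_e` is a
disruptor fold-change on transcription; `kappa_e` (/pg FSH) is the FSH slope.
The multiplicative form `(1 + kappa * FSH_GC)` is a reconstruction choice:
it leaves the unstimulated equilibrium at the measured baseline quantities
and, with FSH 20 ng/ml partitioned at R_oi = 1, yields the ~12-fold
induction of the reference aromatization flux that anchors the flux analysis.

**Steady-state parameterisation.**  Synthesis rates are derived, not fitted:
`nu_mRNA = delta_mRNA * mRNA0` and `nu_prot = delta_prot * prot0 / mRNA0`
(one protein per mRNA), so the unstimulated cell is exactly at equilibrium at
the measured baseline quantities.  The bundled presets store the exact
derived values rather than re-rounded ones; with mRNA0 = 1.03e-7 pg the
derived Hsd17b1 mRNA synthesis rate is 6.18e-10 pg/min, slightly above the
commonly quoted 6.0e-10 — the derived value is kept because it is the one
consistent with the steady-state identity.

**Biotransformation.**  Six competitive Michaelis-Menten fluxes (pmoles/min
per cell): A→E1 and T→E2 by aromatase, A→T and E1→E2 by Hsd17b1, T→A and
E2→E1 by Hsd17b2.  Each enzyme has two substrates; the other substrate acts
as a pure competitive inhibitor with its own Km as inhibition constant
(single Km per enzyme-substrate pair is all the data support):

    alpha = lam * e * Z / (Km_Z * (1 + C/Km_C) + Z)

Direct aromatase inhibition is modelled by inflating both aromatase Km
values by `f_M`, the reciprocal of the measured activity fold-change (for a
competitive inhibitor, activity is inversely proportional to apparent Km).
The tritiated-water assay readout is the cumulative time-integral of the
A→E1 flux: one labelled water per aromatization of labelled A; aromatization
of T releases no label.

Fluxes are evaluated on quantities clipped at zero; solver tolerances keep
the clipping cosmetic.  The fluxes only interconvert the four steroids
(stoichiometric closure), so a closed system conserves total steroid.

## Transport

**In vitro** (two compartments, per-cell bookkeeping): simple diffusion with
excretion rate constant K_out (ml/min, fixed at the nominal 1e-8 for all
hormones) and uptake K_in = K_out / R_oi, where R_oi is the extra- over
intra-cellular partition coefficient; at equilibrium C_med/C_GC = R_oi.
Medium quantities are totals divided by the number of cells; V_med is medium
volume per cell.  FSH has transport only.  The FSH partition coefficient and
excretion rate are not measured quantities; the package fixes R_oi,FSH = 1
and K_out,FSH = 1e-8 ml/min (the same nominal excretion constant as the
steroids), which reproduces the ~12-fold FSH flux induction; both are
config-exposed.

**In vivo** (three compartments: GCs, inert "other cells", extracellular
space): the GC internals are byte-for-byte the same kinetics; "other cells"
(thecal/interstitial) carry no steroidogenic enzymes and only exchange
hormones.  The extracellular pool receives cyclic blood inputs
`Q_input(t) = Q_base + Q_scale * Q_shape(t)` for FSH and the androgens, and
is cleared at `F_ov * X_ext / V_ov,diestrus` (ovarian blood flow over the
0.05 ml diestrus ovary).  Per-cell "other cell" volume is V_others/N_others,
so the whole compartment equilibrates to the same partition ratio as the GC
population; "other cells" share the GC transport constants (no separate
measurements exist).

**Forcing templates.**  The shape waveforms, cell counts, compartment
volumes and the in vivo `sigma_L` are not measured; the bundled
`calibrated_template` was tuned once against the in vivo flux-analysis
reference values (6.09/6.17/5.10 e-9 pmoles/min/cell at
diestrus/proestrus/estrus) and then frozen: a small FSH plateau (8.5% of the
surge scale) through diestrus and early proestrus, a late-proestrus
FSH/androgen surge, constant geometry N_GCs = N_others = 6.17e7 and
V_ext = V_others = V_ov/3, sigma_L = 0.36.  These in vivo flux values are
template-dependent tuning references, not test targets; the suite asserts
the template reproduces them only loosely.

## Reference conditions

The flux-analysis assay is 200 nM androstenedione in 2 ml medium over
600,000 cells (300,000/ml), read at 48 h, with or without FSH 20 ng/ml.
Reproducing the reference flux values (7.29e-9 without and 8.72e-8 with FSH)
requires running the assay at the *calibrated reference study's* random
effect sigma_L = 0.685 (the MAP of the tenth study's effect) rather than
sigma_L = 1; the bundled `flux_assay` preset therefore carries
`sigma_l: 0.685`.  With sigma_L = 1 every flux is 1/0.685 larger.

## Numerical scheme

The gene-expression + FSH-transport subsystem is linear and autonomous in
vitro, so it is solved exactly in closed form (sums of exponentials in
delta_mRNA, delta_prot and the FSH exchange rate); only the nine steroid
states are integrated numerically with a numba-compiled right-hand side
(LSODA, rtol 1e-8, atol 1e-14 pmoles by default — states span ~10 orders of
magnitude).  The closed forms require the three rates to be distinct, which
holds for all realistic parameter values; a full 17-state reference
integration is kept and cross-checked in the tests (agreement ~1e-5).
The calibration likelihood uses an endpoint-only integration at rtol 1e-5:
its error is orders of magnitude below the ~50-70% measurement noise.
In vivo, the full 21-state system is integrated (LSODA, rtol 1e-7); runs
start from the unstimulated equilibrium, the first cycle is burn-in, and a
periodic orbit is declared when cycle-boundary states drift < 0.1%.
Disruptor scenarios are step changes: integration is split at the switch
time.  Time is measured from treatment start (post-attachment).

## Calibration

Observations are lognormal around predictions: `ln(obs) ~ N(ln(pred),
Sigma^2)` with Sigma_2 for mRNA/protein endpoints and Sigma_3 for hormone
endpoints.  Sigma_1..3 are *log-scale standard deviations*: the implied
measurement CVs, `sqrt(exp(Sigma^2) - 1)`, are ~70% (mRNA/protein) and ~53%
(hormones) at the calibrated values, matching the reported ~65%/48%.
Fold-change endpoints are modelled as ratios of the treated to the control
prediction (the study effect cancels) before the lognormal error.
Per-study effects are hierarchical: `ln sigma_L ~ N(ln mu0, Sigma1^2)` with
vague hyperpriors.  24 parameters are sampled in total with ten studies.

The sampler is random-walk Metropolis-Hastings on log-transformed
parameters.  One design choice departs from a plain component-wise sweep:
the ten kinetic parameters are updated as a single joint block whose
proposal covariance is re-estimated from the chain during burn-in
(adaptation frozen afterwards, preserving detailed balance on the retained
half).  Rationale: component-wise kinetic updates would cost ~10x the ODE
solves per sweep, and several Vmax/Km pairs are identified only through
their ratio — a correlated ridge that diagonal proposals traverse slowly.
All other parameters (mu0, Sigma1, each sigma_L, Sigma2, Sigma3) use scalar
updates, plus one joint "shift" move that translates ln(mu0) and every
ln(sigma_L) by the same increment — re-centring the random effects with
their mean leaves the conditional hierarchy terms unchanged, so this move
walks the mu0 funnel that scalar updates traverse slowly.  Scalar and block
scales adapt toward 20-45% acceptance during burn-in only.  Only studies whose predictions a proposal touches are
re-simulated; identical conditions within a study share one solve; Sigma
updates reuse cached residuals and cost no solves.  MAP is the
highest-posterior *sampled* point (no separate mode optimisation).
Convergence is judged by the classic Gelman-Rubin ratio on the retained
second half of each chain.

## Synthetic data

The generator emulates the structure of the in vitro calibration corpus:
ten studies — four reporting absolute mRNA quantities at 4 h (± FSH), two
reporting protein at 48 h (± FSH), two reporting FSH-induction fold-changes
at 4 h, and two reporting 48-h medium hormone accumulations plus the
tritiated-water readout (one without, one with FSH; each anchored by an
unstimulated mRNA reading), three replicates each.  Study effects and
measurement noise are drawn from the hierarchical model at the calibrated
(MAP) truth: mu0 = 1.46, Sigma1 = 0.265, Sigma2 = 0.626, Sigma3 = 0.501.

What passing tests show: the sampler recovers parameters generated by the
model's own noise process, converges at the full 3 x 20,000 scale, and the
likelihood prefers the generating parameters over perturbed ones.  What they
do not show: fit to the real (unavailable) literature corpus, nor
identifiability beyond these endpoint sets — in particular the aromatase Km
for T and the Hsd17b1 constants are prior-dominated here, as their wide
calibrated intervals suggest they were in the original corpus.

## Disruptor prediction

Scenarios carry the measured 4-h fold-changes (Cyp19 and Hsd17b1 mRNA;
aromatase activity → f_M): atrazine, bisphenol A, HPTE, vinclozolin M2, and
letrozole (no mRNA data; Km inflation only).  Non-significant measured
entries are applied as measured by default; a significance-gated mode is
available.  The scenario switches on eight hours into the second simulated
diestrus and ovarian E2 (summed over compartments / ovarian volume) is read
six hours later.  Because protein turnover is ~5.5 h, the 6-h readout sees
an attenuated response relative to the new steady state — the tests assert
this, and the direction of effect (atrazine up, letrozole down) at the MAP
vector.  Monte-Carlo bands combine posterior kinetic draws with the in vivo
variability distributions, with treated and control runs coupled draw by
draw.  Observed-animal comparisons use the two-sample Kolmogorov-Smirnov
test (exact p at small n), validated against an exhaustive enumeration
oracle; individual animal values are user-supplied inputs.

## Known limitations

- No hypothalamic-pituitary feedback, plasma compartment, thecal
  steroidogenesis, receptor binding, or toxicokinetics: scenarios start from
  in vitro fold-changes, and predictions are ovarian concentrations only.
- The in vivo forcing templates are constructed, not measured; all in vivo
  absolute levels inherit that uncertainty.
- Viability is assumed 100%; attachment/priming phases are not modelled
  (t = 0 is treatment start).
- Hsd17b2 kinetic constants differ between the deterministic table and the
  in vivo variability table (λ_E2 by 100x, ξ_T by 1/100); the package
  defaults to the deterministic values and warns when loading the other set.
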