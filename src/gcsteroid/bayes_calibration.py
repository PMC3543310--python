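"""Hierarchical Bayesian calibration of the in vitro model.

Ten kinetic/regulatory parameters (two FSH slope factors, four Vmax, four Km)
are sampled jointly with the hierarchical structure: an inter-study mean mu0
and spread Sigma1 for the per-study transcription random effects sigma_L, and
two log-scale measurement SDs (Sigma2 for mRNA/protein endpoints, Sigma3 for
hormone endpoints).  Observations are lognormal around the model predictions:

    ln(obs) ~ Normal(ln(pred), Sigma_class^2)
    ln(sigma_L) ~ Normal(ln(mu0), Sigma1^2)

Sampling is random-walk Metropolis-Hastings on log-transformed parameters:
one joint adaptive block for the ten kinetic parameters (a component-wise
sweep would multiply the number of ODE solves) and scalar updates for every
other parameter, with proposal scales adapted toward a 20-45% acceptance rate
during burn-in only.  Only studies whose predictions a proposal invalidates
are re-simulated, and identical conditions within a study share one solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import FoldChanges
from .model_core import (Enzyme, Hormone, HierarchicalSpec, ParameterSet,
                         PriorSpec, default_hierarchy)
from . import sim_invitro
from .sim_invitro import fast_final_state

#: sampling order of the ten kinetic/regulatory parameters
KINETIC_NAMES = (
    "kappa_cyp19", "kappa_hsd17b1",
    "lam_cyp19_a", "lam_cyp19_t", "lam_hsd17b1_a", "lam_hsd17b1_e1",
    "xi_cyp19_a", "xi_cyp19_t", "xi_hsd17b1_a", "xi_hsd17b1_e1",
)

_KIN_TARGETS = {
    "lam_cyp19_a": ("lam", Enzyme.CYP19, Hormone.A),
    "lam_cyp19_t": ("lam", Enzyme.CYP19, Hormone.T),
    "lam_hsd17b1_a": ("lam", Enzyme.HSD17B1, Hormone.A),
    "lam_hsd17b1_e1": ("lam", Enzyme.HSD17B1, Hormone.E1),
    "xi_cyp19_a": ("xi", Enzyme.CYP19, Hormone.A),
    "xi_cyp19_t": ("xi", Enzyme.CYP19, Hormone.T),
    "xi_hsd17b1_a": ("xi", Enzyme.HSD17B1, Hormone.A),
    "xi_hsd17b1_e1": ("xi", Enzyme.HSD17B1, Hormone.E1),
}

_ENZ_NAMES = ("Cyp19", "Hsd17b1", "Hsd17b2")


def apply_kinetics(params: ParameterSet, kin: np.ndarray) -> ParameterSet:
    """Overlay a kinetic vector (KINETIC_NAMES order) on a parameter set."""
    lam, xi = {}, {}
    for name, value in zip(KINETIC_NAMES[2:], kin[2:]):
        kind, enz, sub = _KIN_TARGETS[name]
        (lam if kind == "lam" else xi)[(enz, sub)] = float(value)
    return params.with_kinetics(kappa_cyp19=float(kin[0]),
                                kappa_hsd17b1=float(kin[1]), lam=lam, xi=xi)


def parameter_names(n_studies: int = 10) -> list[str]:
    return (list(KINETIC_NAMES) + ["mu0", "sigma1"]
            + [f"sigma_l_{i + 1}" for i in range(n_studies)]
            + ["sigma2", "sigma3"])


@dataclass(frozen=True)
class Condition:
    """Experimental condition of one calibration measurement."""

    fsh_ng_ml: float = 0.0
    initial_a_nm: float = 0.0
    time_min: float = 2880.0
    f_cyp19: float = 1.0
    f_hsd17b1: float = 1.0
    f_m: float = 1.0

    def fold_changes(self) -> FoldChanges:
        return FoldChanges(self.f_cyp19, self.f_hsd17b1, self.f_m)


@dataclass(frozen=True)
class CalibrationDatum:
    """One observed endpoint value (one replicate)."""

    study: int
    endpoint_class: str    # "mrna_protein" | "hormone"
    endpoint: str          # e.g. mrna_Cyp19, prot_Hsd17b1, mrna_fold_Cyp19,
                           #      med_A, med_T, med_E1, med_E2, t2o
    condition: Condition
    value: float

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("observed values must be strictly positive "
                             "(lognormal support)")
        if self.endpoint_class not in ("mrna_protein", "hormone"):
            raise ValueError(f"unknown endpoint class {self.endpoint_class!r}")


@dataclass
class SampledParameterVector:
    """One point of the sampled 24-dimensional (with 10 studies) space."""

    kinetic: np.ndarray            # (10,) in KINETIC_NAMES order
    mu0: float
    sigma1: float
    sigma_l: np.ndarray            # (n_studies,)
    sigma2: float
    sigma3: float

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.kinetic, [self.mu0, self.sigma1],
                               self.sigma_l, [self.sigma2, self.sigma3]])

    @classmethod
    def from_array(cls, x: np.ndarray, n_studies: int) -> "SampledParameterVector":
        x = np.asarray(x, float)
        return cls(kinetic=x[:10].copy(), mu0=float(x[10]), sigma1=float(x[11]),
                   sigma_l=x[12:12 + n_studies].copy(),
                   sigma2=float(x[12 + n_studies]), sigma3=float(x[13 + n_studies]))


# ---------------------------------------------------------------------------
# Prior
# ---------------------------------------------------------------------------

def log_prior(v: SampledParameterVector, priors: dict[str, PriorSpec],
              hier: HierarchicalSpec) -> float:
    """Joint log prior density: independent priors for the kinetic vector and
    the hyper/error parameters, plus the hierarchical lognormal terms for the
    per-study random effects conditioned on (mu0, Sigma1)."""
    lp = 0.0
    for name, value in zip(KINETIC_NAMES, v.kinetic):
        lp += priors[name].logpdf(value)
    lp += hier.mu0_prior.logpdf(v.mu0)
    lp += hier.sigma1_prior.logpdf(v.sigma1)
    lp += hier.sigma2_prior.logpdf(v.sigma2)
    lp += hier.sigma3_prior.logpdf(v.sigma3)
    if not np.isfinite(lp):
        return -np.inf
    if v.mu0 <= 0 or v.sigma1 <= 0:
        return -np.inf
    s = v.sigma1
    for sl in v.sigma_l:
        if sl <= 0:
            return -np.inf
        z = (np.log(sl) - np.log(v.mu0)) / s
        lp += -np.log(sl * s * np.sqrt(2 * np.pi)) - 0.5 * z * z
    return float(lp)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

class LikelihoodEvaluator:
    """Model predictions and residual bookkeeping for the calibration data.

    Gene-expression endpoints (mRNA/protein quantities and induction
    fold-changes) use the exact closed-form solution of the linear
    subsystem; hormone endpoints (medium quantities and cumulative
    tritiated water) run the steroid ODE once per unique condition per
    study.  ``solve_count`` tracks the number of ODE solves.
    """

    _GENE_ENDPOINTS = ("mrna_", "prot_")
    _HORMONE_MAP = {"med_A": 4, "med_T": 5, "med_E1": 6, "med_E2": 7, "t2o": 8}

    def __init__(self, data: list[CalibrationDatum], params: ParameterSet,
                 cells_per_ml: float = 3.0e5, medium_volume_ml: float = 2.0,
                 rtol: float = 1e-5, atol: float = 1e-15):
        self.params = params
        self.v_med = 1.0 / cells_per_ml
        self.rtol, self.atol = rtol, atol
        self.studies = sorted({d.study for d in data})
        self._gene: dict[int, dict] = {}
        self._horm: dict[int, list] = {}
        # fixed constants of the closed forms
        kin_f = params.k_in(Hormone.FSH)
        self._kf = kin_f / self.v_med + params.k_out[Hormone.FSH] / params.v_gc
        self._c_fsh = (kin_f / self.v_med) / self._kf  # F_inf per unit total FSH
        self._nu_m = np.array([params.nu_mrna[Enzyme(e)] for e in _ENZ_NAMES])
        self._nu_p = np.array([params.nu_prot[Enzyme(e)] for e in _ENZ_NAMES])
        self._m0 = np.array([params.mrna0[Enzyme(e)] for e in _ENZ_NAMES])
        self._p0 = np.array([params.prot0[Enzyme(e)] for e in _ENZ_NAMES])
        for s in self.studies:
            rows = [d for d in data if d.study == s]
            self._index_study(s, rows)

    @property
    def solve_count(self) -> int:
        return sim_invitro._solve_counter["n"]

    def _index_study(self, s: int, rows: list[CalibrationDatum]):
        gene = {"enz": [], "t": [], "fsh_tot": [], "fold": [], "is_prot": [],
                "is_fold": [], "cls3": [], "lnobs": []}
        horm_conditions: dict[Condition, dict[str, list]] = {}
        for d in rows:
            ep = d.endpoint
            if ep in self._HORMONE_MAP:
                slot = horm_conditions.setdefault(d.condition, {})
                slot.setdefault(ep, []).append(np.log(d.value))
                continue
            is_fold = ep.startswith("mrna_fold_")
            enz_name = ep.split("_")[-1]
            j = _ENZ_NAMES.index(enz_name)
            fold = (d.condition.f_cyp19, d.condition.f_hsd17b1, 1.0)[j]
            gene["enz"].append(j)
            gene["t"].append(d.condition.time_min)
            gene["fsh_tot"].append(d.condition.fsh_ng_ml * 1000.0 * self.v_med)
            gene["fold"].append(fold)
            gene["is_prot"].append(ep.startswith("prot_"))
            gene["is_fold"].append(is_fold)
            gene["cls3"].append(d.endpoint_class == "hormone")
            gene["lnobs"].append(np.log(d.value))
        self._gene[s] = {k: np.asarray(a) for k, a in gene.items()}
        self._horm[s] = [(cond, {ep: np.asarray(v) for ep, v in slot.items()})
                         for cond, slot in horm_conditions.items()]

    # -- closed-form gene endpoints -----------------------------------------

    def _gene_values(self, g, kin, sigma_l, fold_on=True):
        dm, dp, kf = self.params.delta_mrna, self.params.delta_prot, self._kf
        kappa = np.array([kin[0], kin[1], 0.0])[g["enz"]]
        nu = self._nu_m[g["enz"]]
        m0 = self._m0[g["enz"]]
        p0 = self._p0[g["enz"]]
        np_e = self._nu_p[g["enz"]]
        f = g["fold"] if fold_on else np.ones_like(g["fold"])
        f_inf = self._c_fsh * g["fsh_tot"] if fold_on else 0.0
        base = sigma_l * f * nu
        b0 = base * (1.0 + kappa * f_inf)
        b1 = -base * kappa * f_inf          # FSH_GC starts at zero
        t = g["t"]
        m_kf = b1 / (dm - kf)
        c_m = m0 - b0 / dm - m_kf
        mrna = b0 / dm + c_m * np.exp(-dm * t) + m_kf * np.exp(-kf * t)
        e0 = np_e * b0 / (dm * dp)
        e1 = np_e * c_m / (dp - dm)
        e3 = np_e * b1 / ((dm - kf) * (dp - kf))
        e2 = p0 - e0 - e1 - e3
        prot = (e0 + e1 * np.exp(-dm * t) + e2 * np.exp(-dp * t)
                + e3 * np.exp(-kf * t))
        return np.where(g["is_prot"], prot, mrna)

    def predict_gene(self, study: int, kin: np.ndarray, sigma_l: float):
        """Predicted values for the study's gene-expression endpoints, in the
        study's row order.  Fold endpoints are ratios of treated over control
        (control: no FSH, identity fold-changes; study effect cancels)."""
        g = self._gene[study]
        if g["t"].size == 0:
            return np.empty(0)
        pred = self._gene_values(g, kin, sigma_l)
        if np.any(g["is_fold"]):
            ctrl = self._gene_values(g, kin, sigma_l, fold_on=False)
            pred = np.where(g["is_fold"], pred / ctrl, pred)
        return pred

    # -- hormone endpoints ---------------------------------------------------

    def predict_hormones(self, cond: Condition, kin: np.ndarray,
                         sigma_l: float) -> dict[str, float]:
        p = apply_kinetics(self.params, kin)
        med0 = np.zeros(4)
        med0[0] = cond.initial_a_nm * self.v_med
        y = fast_final_state(p, cond.fold_changes(), sigma_l, self.v_med, med0,
                             cond.fsh_ng_ml * 1000.0 * self.v_med,
                             cond.time_min, rtol=self.rtol, atol=self.atol)
        return {ep: float(y[idx]) for ep, idx in self._HORMONE_MAP.items()}

    # -- residual statistics -------------------------------------------------

    def study_stats(self, study: int, kin: np.ndarray, sigma_l: float):
        """(sum of squared log-residuals, count) per error class for one
        study, or None if any prediction is non-positive."""
        g = self._gene[study]
        ss = np.zeros(2)   # [mrna_protein, hormone]
        n = np.zeros(2, dtype=int)
        if g["t"].size:
            pred = self.predict_gene(study, kin, sigma_l)
            if np.any(~np.isfinite(pred)) or np.any(pred <= 0):
                return None
            r = g["lnobs"] - np.log(pred)
            cls = g["cls3"].astype(int)
            for c in (0, 1):
                m = cls == c
                ss[c] += float(np.sum(r[m] ** 2))
                n[c] += int(np.count_nonzero(m))
        for cond, slot in self._horm[study]:
            pred = self.predict_hormones(cond, kin, sigma_l)
            for ep, lnobs in slot.items():
                pv = pred[ep]
                if not np.isfinite(pv) or pv <= 0:
                    return None
                r = lnobs - np.log(pv)
                ss[1] += float(np.sum(r ** 2))
                n[1] += lnobs.size
        return ss, n

    def has_solves(self, study: int) -> bool:
        return bool(self._horm[study])


def _stats_loglik(stats, sigma2: float, sigma3: float) -> float:
    """Gaussian log-density of the log observations given residual stats."""
    ll = 0.0
    for (ss, n) in stats:
        for c, sig in ((0, sigma2), (1, sigma3)):
            if n[c]:
                ll += (-n[c] * np.log(sig) - 0.5 * n[c] * np.log(2 * np.pi)
                       - ss[c] / (2.0 * sig * sig))
    return ll


def log_likelihood(v: SampledParameterVector, data: list[CalibrationDatum],
                   params: ParameterSet,
                   evaluator: LikelihoodEvaluator | None = None) -> float:
    """Total lognormal log-likelihood of a calibration data collection.

    Predictions are produced by simulating each datum's condition with the
    datum's study random effect; identical conditions within a study reuse
    one simulation.  Non-positive predictions yield -inf.
    """
    ev = evaluator or LikelihoodEvaluator(data, params)
    if v.sigma2 <= 0 or v.sigma3 <= 0:
        return -np.inf
    stats = []
    for i, s in enumerate(ev.studies):
        st = ev.study_stats(s, v.kinetic, float(v.sigma_l[i]))
        if st is None:
            return -np.inf
        stats.append(st)
    return float(_stats_loglik(stats, v.sigma2, v.sigma3))


# ---------------------------------------------------------------------------
# Metropolis-Hastings
# ---------------------------------------------------------------------------

@dataclass
class ChainSet:
    """Raw MCMC output: full per-chain sample paths on the natural scale."""

    samples: np.ndarray        # (n_chains, n_iter, d)
    log_posterior: np.ndarray  # (n_chains, n_iter)
    names: list[str]
    seeds: list[int]
    n_burn: int
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    def retained(self, use_last: float = 0.5) -> np.ndarray:
        """Tail fraction of each chain used for inference, (m, n_keep, d)."""
        n = self.samples.shape[1]
        keep = max(1, int(round(n * use_last)))
        return self.samples[:, n - keep:, :]

    def pooled(self, use_last: float = 0.5) -> np.ndarray:
        r = self.retained(use_last)
        return r.reshape(-1, r.shape[-1])

    def to_frame(self, use_last: float = 0.5) -> pd.DataFrame:
        return pd.DataFrame(self.pooled(use_last), columns=self.names)

    def save(self, path) -> None:
        np.savez_compressed(
            path, samples=self.samples, log_posterior=self.log_posterior,
            names=np.array(self.names), seeds=np.array(self.seeds),
            n_burn=self.n_burn)

    @classmethod
    def load(cls, path) -> "ChainSet":
        z = np.load(path, allow_pickle=False)
        return cls(samples=z["samples"], log_posterior=z["log_posterior"],
                   names=[str(s) for s in z["names"]],
                   seeds=[int(s) for s in z["seeds"]], n_burn=int(z["n_burn"]))


def _init_vector(priors, hier, n_studies, rng) -> np.ndarray:
    x = np.empty(14 + n_studies)
    for i, name in enumerate(KINETIC_NAMES):
        v = priors[name].sample(1, rng)[0]
        while v <= 0:
            v = priors[name].sample(1, rng)[0]
        x[i] = v
    x[10] = hier.mu0_prior.sample(1, rng)[0]
    x[11] = max(hier.sigma1_prior.sample(1, rng)[0], 1e-3)
    x[12:12 + n_studies] = np.exp(rng.normal(np.log(x[10]), x[11], n_studies))
    x[12 + n_studies] = max(hier.sigma2_prior.sample(1, rng)[0], 1e-3)
    x[13 + n_studies] = max(hier.sigma3_prior.sample(1, rng)[0], 1e-3)
    return x


def metropolis_hastings(data: list[CalibrationDatum] | None,
                        priors: dict[str, PriorSpec],
                        hier: HierarchicalSpec,
                        n_iter: int = 20000, n_chains: int = 3,
                        seeds: list[int] | None = None,
                        params: ParameterSet | None = None,
                        n_burn: int | None = None,
                        adapt_interval: int = 50,
                        evaluator: LikelihoodEvaluator | None = None,
                        progress: bool = False) -> ChainSet:
    """Run random-walk MH chains on the log-transformed parameter space.

    With ``data`` None or empty the target is the prior alone (used for
    prior-recovery checks).  Proposal scales adapt toward a 20-45%
    acceptance rate during the burn-in (first half by default) and are
    frozen afterwards, preserving detailed balance on the retained tail.
    Chains are bitwise reproducible given seeds.
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    n_studies = hier.n_studies
    names = parameter_names(n_studies)
    d = len(names)
    if n_burn is None:
        n_burn = n_iter // 2
    if seeds is None:
        seeds = list(range(1, n_chains + 1))
    if len(seeds) != n_chains:
        raise ValueError("one seed per chain required")

    have_data = bool(data)
    if have_data:
        if params is None:
            raise ValueError("params required when calibrating against data")
        ev = evaluator or LikelihoodEvaluator(data, params)
        if set(ev.studies) - set(range(1, n_studies + 1)):
            raise ValueError("study ids must lie in 1..n_studies")
    else:
        ev = None

    # block layout: one joint adaptive block for the ten kinetic parameters,
    # scalar updates for everything else
    kin_idx = np.arange(10)
    d_kin = kin_idx.size
    blocks = [("kin", kin_idx)]
    blocks += [("mu0", np.array([10])), ("sigma1", np.array([11]))]
    blocks += [(f"sigma_l_{i + 1}", np.array([12 + i])) for i in range(n_studies)]
    blocks += [("sigma2", np.array([d - 2])), ("sigma3", np.array([d - 1]))]
    # joint shift of mu0 and every sigma_L along the hierarchy's ridge:
    # re-centring the random effects with their mean leaves the conditional
    # prior terms unchanged, so the move explores the mu0 funnel efficiently
    shift_idx = np.concatenate([[10], np.arange(12, 12 + n_studies)])
    blocks += [("hier_shift", shift_idx)]

    all_samples = np.empty((n_chains, n_iter, d))
    all_logpost = np.empty((n_chains, n_iter))
    acc_report: dict[str, list] = {b: [] for b, _ in blocks}

    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        x = _init_vector(priors, hier, n_studies, rng)
        theta = np.log(x)

        def vec(xx):
            return SampledParameterVector.from_array(xx, n_studies)

        def prior_term(xx, th):
            lp = log_prior(vec(xx), priors, hier)
            return lp + float(np.sum(th)) if np.isfinite(lp) else -np.inf

        # per-study residual stats for the current state
        def all_stats(xx):
            if not have_data:
                return []
            out = []
            for i, s in enumerate(ev.studies):
                st = ev.study_stats(s, xx[:10], xx[12 + (s - 1)])
                if st is None:
                    return None
                out.append(st)
            return out

        stats = all_stats(x)
        tries = 0
        while have_data and stats is None:
            x = _init_vector(priors, hier, n_studies, rng)
            theta = np.log(x)
            stats = all_stats(x)
            tries += 1
            if tries > 100:
                raise RuntimeError("could not find a valid starting point")
        lp_prior = prior_term(x, theta)
        lp_lik = (_stats_loglik(stats, x[d - 2], x[d - 1]) if have_data else 0.0)
        lp = lp_prior + lp_lik

        # for the joint block: step = scale * (2.38/sqrt(d)) * chol(Sigma_hat) @ z,
        # with the shape (chol) estimated from the chain and the scalar scale
        # driven by acceptance feedback — the two adapt independently
        scales = {name: (1.0 if name == "kin" else 0.35) for name, _ in blocks}
        # joint-block proposal shape: starts diagonal at the prior spread and
        # is re-estimated from the chain's own covariance through burn-in, so
        # correlated ridges (a Vmax/Km pair identified only through its
        # ratio) are proposed along their principal axes
        kin_sd0 = np.array([np.log(priors[n_].args[1])
                            if priors[n_].family == "lognormal" else 1.0
                            for n_ in KINETIC_NAMES])
        kin_chol = np.diag(kin_sd0)
        kin_step = 2.38 / np.sqrt(d_kin)
        n_shape = n_burn              # covariance re-estimated through burn-in
        acc_counts = {b: 0 for b, _ in blocks}
        acc_total = {b: 0 for b, _ in blocks}
        window = {b: 0 for b, _ in blocks}
        stall = 0

        for it in range(n_iter):
            for bname, idx in blocks:
                theta_p = theta.copy()
                if bname == "kin":
                    theta_p[idx] += scales[bname] * kin_step * (
                        kin_chol @ rng.standard_normal(d_kin))
                elif bname == "hier_shift":
                    theta_p[idx] += scales[bname] * rng.standard_normal()
                else:
                    theta_p[idx] += scales[bname] * rng.standard_normal(idx.size)
                x_p = np.exp(theta_p)
                lp_prior_p = prior_term(x_p, theta_p)
                if not np.isfinite(lp_prior_p):
                    accept = False
                    lp_p = -np.inf
                else:
                    if not have_data:
                        lp_lik_p = 0.0
                        stats_p = stats
                    elif bname in ("kin", "hier_shift"):
                        stats_p = all_stats(x_p)
                        lp_lik_p = (-np.inf if stats_p is None else
                                    _stats_loglik(stats_p, x_p[d - 2], x_p[d - 1]))
                    elif bname.startswith("sigma_l_"):
                        i = int(bname.split("_")[-1]) - 1
                        s_id = i + 1
                        if s_id in ev.studies:
                            k = ev.studies.index(s_id)
                            st = ev.study_stats(s_id, x_p[:10], x_p[12 + i])
                            if st is None:
                                stats_p, lp_lik_p = None, -np.inf
                            else:
                                stats_p = list(stats)
                                stats_p[k] = st
                                lp_lik_p = _stats_loglik(stats_p, x_p[d - 2],
                                                         x_p[d - 1])
                        else:
                            stats_p, lp_lik_p = stats, lp_lik
                    elif bname in ("sigma2", "sigma3"):
                        stats_p = stats
                        lp_lik_p = _stats_loglik(stats, x_p[d - 2], x_p[d - 1])
                    else:  # mu0, sigma1: prior-only
                        stats_p, lp_lik_p = stats, lp_lik
                    lp_p = lp_prior_p + lp_lik_p
                    accept = (np.isfinite(lp_p)
                              and np.log(rng.uniform()) < lp_p - lp)
                if accept:
                    theta, x = theta_p, x_p
                    lp, lp_prior, lp_lik = lp_p, lp_prior_p, lp_lik_p
                    stats = stats_p
                    acc_counts[bname] += 1
                    if it >= n_burn:
                        acc_total[bname] += 1
                window[bname] += 1
            all_samples[c, it] = x
            all_logpost[c, it] = lp

            if it < n_burn and (it + 1) % adapt_interval == 0:
                for bname, idx in blocks:
                    rate = acc_counts[bname] / window[bname]
                    target = 0.25 if bname == "kin" else 0.35
                    scales[bname] *= float(np.exp(1.2 * (rate - target)))
                    scales[bname] = float(np.clip(scales[bname], 1e-4, 10.0))
                    acc_counts[bname] = 0
                    window[bname] = 0
                # shape the joint block from the chain's own covariance
                if 500 <= it + 1 <= n_shape and (it + 1) % 250 == 0:
                    hist = np.log(all_samples[c, max(0, it - 3999):it + 1]
                                  [:, kin_idx])
                    cov = np.cov(hist, rowvar=False)
                    cov += np.diag(np.maximum(1e-6, 1e-4 * np.diag(cov)))
                    try:
                        kin_chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
            if not np.isfinite(lp):
                stall += 1
                if stall > 1000:
                    raise RuntimeError("sampler stalled at -inf posterior")

        for bname, _ in blocks:
            denom = max(1, n_iter - n_burn)
            acc_report[bname].append(acc_total[bname] / denom)

    return ChainSet(samples=all_samples, log_posterior=all_logpost,
                    names=names, seeds=list(seeds), n_burn=n_burn,
                    acceptance={b: list(v) for b, v in acc_report.items()})


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(chains: ChainSet | np.ndarray,
                 use_last: float = 0.5) -> pd.Series:
    """Potential scale reduction, computed per parameter on the retained
    tail of each chain (classic between/within variance ratio).

    Rhat = sqrt(((n-1)/n * W + B/n) / W) for m chains of n retained samples.
    """
    if isinstance(chains, ChainSet):
        arr = chains.retained(use_last)
        names = chains.names
    else:
        arr = np.asarray(chains, float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        keep = max(1, int(round(arr.shape[1] * use_last)))
        arr = arr[:, arr.shape[1] - keep:, :]
        names = [f"p{i}" for i in range(arr.shape[2])]
    m, n, d = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains and >= 10 retained samples each")
    means = arr.mean(axis=1)                       # (m, d)
    w = arr.var(axis=1, ddof=1).mean(axis=0)       # (d,)
    b_over_n = means.var(axis=0, ddof=1)           # (d,)
    if np.any(w == 0):
        raise ZeroDivisionError("zero within-chain variance")
    var_plus = (n - 1) / n * w + b_over_n
    return pd.Series(np.sqrt(var_plus / w), index=names, name="rhat")


def posterior_summary(chains: ChainSet, use_last: float = 0.5,
                      percentiles=(0.5, 2.5, 97.5, 99.5)) -> pd.DataFrame:
    """Mean, SD, highest-posterior sample (MAP) and percentiles per
    parameter, over the pooled retained samples."""
    pool = chains.pooled(use_last)
    n = chains.samples.shape[1]
    keep = max(1, int(round(n * use_last)))
    lp = chains.log_posterior[:, n - keep:].reshape(-1)
    map_row = pool[int(np.argmax(lp))]
    out = {"mean": pool.mean(axis=0), "sd": pool.std(axis=0, ddof=1),
           "map": map_row}
    for p in percentiles:
        out[f"p{p}"] = np.percentile(pool, p, axis=0)
    df = pd.DataFrame(out, index=chains.names)
    try:
        df["rhat"] = gelman_rubin(chains, use_last)
    except (ValueError, ZeroDivisionError):
        pass
    return df
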