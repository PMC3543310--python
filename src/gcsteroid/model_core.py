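"""Parameters, priors, and steady-state derivations for the granulosa-cell model.

The model tracks, for a single rat granulosa cell (GC), the mRNA and protein
quantities of the three terminal steroidogenic enzymes (aromatase/Cyp19,
Hsd17b1, Hsd17b2) and the quantities of the four sex steroids it interconverts
(androstenedione A, testosterone T, estrone E1, estradiol E2), plus FSH which
regulates transcription but is not metabolised.

Internal units are fixed: pg for mRNA/protein/FSH, pmoles for steroids,
ml for volumes, minutes for time.  Quantities (not concentrations) are the
state variables; concentrations are derived views.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import yaml


class Enzyme(str, Enum):
    """The three terminal steroidogenic enzymes expressed by a GC."""

    CYP19 = "Cyp19"
    HSD17B1 = "Hsd17b1"
    HSD17B2 = "Hsd17b2"


class Hormone(str, Enum):
    """Hormones in the model.

    FSH participates in transport and transcriptional regulation but never
    in the metabolic (steroid interconversion) reactions.
    """

    A = "A"
    T = "T"
    E1 = "E1"
    E2 = "E2"
    FSH = "FSH"


#: The four steroids, in canonical state-vector order.
STEROIDS = (Hormone.A, Hormone.T, Hormone.E1, Hormone.E2)

#: The six biotransformation reactions, in canonical order alpha1..alpha6:
#: (enzyme, substrate, product, competing substrate of the same enzyme).
REACTIONS = (
    (Enzyme.CYP19, Hormone.A, Hormone.E1, Hormone.T),
    (Enzyme.HSD17B1, Hormone.A, Hormone.T, Hormone.E1),
    (Enzyme.HSD17B2, Hormone.T, Hormone.A, Hormone.E2),
    (Enzyme.CYP19, Hormone.T, Hormone.E2, Hormone.A),
    (Enzyme.HSD17B1, Hormone.E1, Hormone.E2, Hormone.A),
    (Enzyme.HSD17B2, Hormone.E2, Hormone.E1, Hormone.T),
)

REACTION_LABELS = (
    "A->E1 (Cyp19)",
    "A->T (Hsd17b1)",
    "T->A (Hsd17b2)",
    "T->E2 (Cyp19)",
    "E1->E2 (Hsd17b1)",
    "E2->E1 (Hsd17b2)",
)


class UndefinedProteinRateError(ValueError):
    """Raised when prot0 > 0 but mRNA0 = 0: the per-mRNA translation rate
    constant cannot be derived."""


def derive_steady_state_rates(delta_mrna: float, delta_prot: float,
                              mrna0: float, prot0: float) -> tuple[float, float]:
    """Derive synthesis rates from degradation rates and baseline quantities.

    Under the steady-state assumption (no FSH, no disruptor, unit study
    effect), transcription balances mRNA degradation and translation balances
    protein degradation, one protein per mRNA:

        nu_mRNA = delta_mRNA * mRNA0          [pg/min]
        nu_prot = delta_prot * prot0 / mRNA0  [/min]

    Parameters
    ----------
    delta_mrna, delta_prot : first-order degradation rate constants (/min).
    mrna0, prot0 : baseline quantities (pg/cell).

    Returns
    -------
    (nu_mrna, nu_prot) such that the gene-expression ODEs are at equilibrium
    at (mrna0, prot0).
    """
    if delta_mrna <= 0 or delta_prot <= 0:
        raise ValueError("degradation rate constants must be strictly positive")
    if mrna0 < 0 or prot0 < 0:
        raise ValueError("baseline quantities must be non-negative")
    if mrna0 == 0:
        if prot0 > 0:
            raise UndefinedProteinRateError(
                "prot0 > 0 with mRNA0 = 0: protein synthesis rate constant "
                "is undefined")
        return 0.0, 0.0  # empty cell, by convention
    return delta_mrna * mrna0, delta_prot * prot0 / mrna0


def scale_relative_initials(aromatase_mrna0: float, aromatase_prot0: float,
                            ratios: dict[Enzyme, tuple[float, float]],
                            ) -> dict[Enzyme, tuple[float, float]]:
    """Convert enzyme quantities measured relative to aromatase into absolute
    pg/cell values.

    ``ratios`` maps each enzyme to (mRNA ratio, protein ratio) with aromatase
    itself at (1, 1).
    """
    out = {}
    for enz, (rm, rp) in ratios.items():
        if rm <= 0 or rp <= 0:
            raise ValueError(f"ratios must be > 0 (got {rm}, {rp} for {enz})")
        out[Enzyme(enz)] = (aromatase_mrna0 * rm, aromatase_prot0 * rp)
    return out


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior/variability distribution.

    families:
      * ``lognormal(geometric mean, geometric SD)`` — stored internally as
        (log-median, log-SD = ln gsd), the convention used throughout for
        multiplicative quantities;
      * ``uniform(min, max)``;
      * ``halfnormal(SD)`` with mode at zero.
    """

    family: str
    args: tuple[float, ...]

    def __post_init__(self):
        if self.family == "lognormal":
            gm, gsd = self.args
            if gm <= 0 or gsd <= 1:
                raise ValueError("lognormal needs gm > 0 and geometric SD > 1")
        elif self.family == "uniform":
            lo, hi = self.args
            if not hi > lo:
                raise ValueError("uniform needs max > min")
        elif self.family == "halfnormal":
            (sd,) = self.args
            if sd <= 0:
                raise ValueError("halfnormal needs SD > 0")
        else:
            raise ValueError(f"unknown prior family {self.family!r}")

    # -- sampling / densities -------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lognormal":
            gm, gsd = self.args
            return rng.lognormal(mean=np.log(gm), sigma=np.log(gsd), size=n)
        if self.family == "uniform":
            lo, hi = self.args
            return rng.uniform(lo, hi, size=n)
        sd, = self.args
        return np.abs(rng.normal(0.0, sd, size=n))

    def logpdf(self, x: float) -> float:
        x = float(x)
        if self.family == "lognormal":
            gm, gsd = self.args
            if x <= 0:
                return -np.inf
            s = np.log(gsd)
            z = (np.log(x) - np.log(gm)) / s
            return -np.log(x * s * np.sqrt(2 * np.pi)) - 0.5 * z * z
        if self.family == "uniform":
            lo, hi = self.args
            if lo <= x <= hi:
                return -np.log(hi - lo)
            return -np.inf
        sd, = self.args
        if x < 0:
            return -np.inf
        return 0.5 * np.log(2 / np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2

    def median(self) -> float:
        if self.family == "lognormal":
            return self.args[0]
        if self.family == "uniform":
            return 0.5 * (self.args[0] + self.args[1])
        # halfnormal median = sd * sqrt(2) * erfinv(1/2)
        from scipy.special import erfinv
        return self.args[0] * np.sqrt(2) * erfinv(0.5)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval of the distribution."""
        from scipy import stats
        a = (1 - level) / 2
        if self.family == "lognormal":
            gm, gsd = self.args
            d = stats.lognorm(s=np.log(gsd), scale=gm)
        elif self.family == "uniform":
            lo, hi = self.args
            d = stats.uniform(lo, hi - lo)
        else:
            d = stats.halfnorm(scale=self.args[0])
        return d.ppf(a), d.ppf(1 - a)


def sample_prior(spec: PriorSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` reproducible samples from a prior specification."""
    return spec.sample(n, np.random.default_rng(seed))


@dataclass(frozen=True)
class HierarchicalSpec:
    """Hyper-structure of the calibration: inter-study random effects and the
    two measurement-error classes.

    sigma_L (one per study) multiplies all baseline transcription rates of a
    study; ln sigma_L ~ Normal(ln mu0, Sigma1^2).  Sigma2 and Sigma3 are the
    log-scale measurement SDs for mRNA/protein and hormone endpoints.
    """

    mu0_prior: PriorSpec
    sigma1_prior: PriorSpec
    sigma2_prior: PriorSpec
    sigma3_prior: PriorSpec
    n_studies: int = 10

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValueError("need at least one study")


def default_hierarchy(n_studies: int = 10) -> HierarchicalSpec:
    return HierarchicalSpec(
        mu0_prior=PriorSpec("lognormal", (1.0, 2.0)),
        sigma1_prior=PriorSpec("halfnormal", (0.5,)),
        sigma2_prior=PriorSpec("halfnormal", (0.2,)),
        sigma3_prior=PriorSpec("halfnormal", (0.2,)),
        n_studies=n_studies,
    )


@dataclass(frozen=True)
class ParameterSet:
    """All kinetic and transport constants for one granulosa cell.

    Keys of the per-enzyme dicts are :class:`Enzyme`; keys of lam/xi are
    (enzyme, substrate) pairs for the six reactions in :data:`REACTIONS`;
    transport dicts are keyed by :class:`Hormone` (including FSH).
    """

    nu_mrna: dict          # pg/min, per enzyme
    nu_prot: dict          # /min, per enzyme
    delta_mrna: float      # /min
    delta_prot: float      # /min
    kappa: dict            # /pg FSH, for Cyp19 and Hsd17b1
    lam: dict              # Vmax, pmoles/min/pg enzyme, per (enzyme, substrate)
    xi: dict               # Km, pmoles, per (enzyme, substrate)
    k_out: dict            # ml/min, per hormone (incl. FSH)
    r_oi: dict             # unitless extra/intra partition, per hormone
    v_gc: float            # ml, single-cell volume
    f_ov: float            # ml/min, ovarian blood flow
    v_ov_diestrus: float   # ml, ovarian volume at diestrus
    mrna0: dict            # pg/cell, per enzyme
    prot0: dict            # pg/cell, per enzyme

    def __post_init__(self):
        for name in ("delta_mrna", "delta_prot", "v_gc", "f_ov", "v_ov_diestrus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for d, what in ((self.lam, "lam"), (self.xi, "xi"),
                        (self.k_out, "k_out"), (self.r_oi, "r_oi")):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"{what}[{k}] must be strictly positive")

    def k_in(self, hormone: Hormone) -> float:
        """Uptake rate constant K_in = K_out / R_oi (ml/min)."""
        return self.k_out[hormone] / self.r_oi[hormone]

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def with_kinetics(self, kappa_cyp19=None, kappa_hsd17b1=None, lam=None,
                      xi=None) -> "ParameterSet":
        """Return a copy with (some of) the ten calibrated kinetic parameters
        replaced.  ``lam``/``xi`` are partial dicts keyed like self.lam/xi."""
        kap = dict(self.kappa)
        if kappa_cyp19 is not None:
            kap[Enzyme.CYP19] = kappa_cyp19
        if kappa_hsd17b1 is not None:
            kap[Enzyme.HSD17B1] = kappa_hsd17b1
        lm = dict(self.lam)
        lm.update(lam or {})
        x = dict(self.xi)
        x.update(xi or {})
        return replace(self, kappa=kap, lam=lm, xi=x)

    # -- config (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        ek = lambda d: {e.value: v for e, v in d.items()}
        rk = lambda d: {f"{e.value},{h.value}": v for (e, h), v in d.items()}
        hk = lambda d: {h.value: v for h, v in d.items()}
        return {
            "nu_mrna": ek(self.nu_mrna), "nu_prot": ek(self.nu_prot),
            "delta_mrna": self.delta_mrna, "delta_prot": self.delta_prot,
            "kappa": ek(self.kappa), "lam": rk(self.lam), "xi": rk(self.xi),
            "k_out": hk(self.k_out), "r_oi": hk(self.r_oi),
            "v_gc": self.v_gc, "f_ov": self.f_ov,
            "v_ov_diestrus": self.v_ov_diestrus,
            "mrna0": ek(self.mrna0), "prot0": ek(self.prot0),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        ek = lambda m: {Enzyme(k): float(v) for k, v in m.items()}
        hk = lambda m: {Hormone(k): float(v) for k, v in m.items()}
        rk = lambda m: {(Enzyme(k.split(",")[0]), Hormone(k.split(",")[1])): float(v)
                        for k, v in m.items()}
        return cls(
            nu_mrna=ek(d["nu_mrna"]), nu_prot=ek(d["nu_prot"]),
            delta_mrna=float(d["delta_mrna"]), delta_prot=float(d["delta_prot"]),
            kappa=ek(d["kappa"]), lam=rk(d["lam"]), xi=rk(d["xi"]),
            k_out=hk(d["k_out"]), r_oi=hk(d["r_oi"]),
            v_gc=float(d["v_gc"]), f_ov=float(d["f_ov"]),
            v_ov_diestrus=float(d["v_ov_diestrus"]),
            mrna0=ek(d["mrna0"]), prot0=ek(d["prot0"]),
        )


# ---------------------------------------------------------------------------
# Bundled presets
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("gcsteroid.data").joinpath(name)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def load_preset(name: str) -> dict:
    """Load one of the bundled presets by name (without extension).

    Available: ``table2_defaults``, ``table4_map``,
    ``table5_invivo_variability``, ``table3_priors``, ``flux_assay``,
    ``edc_scenarios``, ``calibrated_template``.
    """
    with importlib.resources.as_file(_data_path(name + ".yaml")) as p:
        cfg = load_config(p)
    if name == "table5_invivo_variability":
        warnings.warn(
            "the Hsd17b2 constants in the in vivo variability preset "
            "(lam Hsd17b2,E2 gm 7.91e-6; xi Hsd17b2,T gm 5.67e-8) differ "
            "from the point values of the deterministic preset (7.91e-8 and "
            "5.67e-6); the deterministic simulations default to the point "
            "values", stacklevel=2)
    return cfg


def load_parameters(preset: str = "table2_defaults") -> ParameterSet:
    """Build a :class:`ParameterSet` from a bundled preset."""
    return ParameterSet.from_dict(load_preset(preset)["parameters"])


def priors_from_config(cfg: dict) -> dict[str, PriorSpec]:
    """Parse a {name: {family, args}} mapping into PriorSpec objects."""
    return {k: PriorSpec(v["family"], tuple(float(a) for a in v["args"]))
            for k, v in cfg.items()}


def load_priors(name: str = "table3_priors") -> dict[str, PriorSpec]:
    return priors_from_config(load_preset(name)["priors"])


def load_invivo_variability() -> dict[str, PriorSpec]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = load_preset("table5_invivo_variability")
    return priors_from_config(cfg["priors"])
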