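"""Three-compartment ovary model: granulosa cells, "other cells" (thecal and
interstitial, metabolically inert), and extracellular/vascular space.

Hormones enter the extracellular space from blood at cyclic rates
Q_input(t) = Q_base + Q_scale * Q_shape(t) (FSH and androgens only), exchange
with both cell populations by diffusion, and are cleared by ovarian blood
flow F_ov.  The granulosa-cell internals (gene expression and the six
metabolic fluxes) are exactly those of the in vitro model.

Per-cell bookkeeping: X_GC and X_others are per-cell quantities; the per-cell
volume of an "other cell" is V_others / N_others, so that the whole
compartment equilibrates to the partition ratio like the GC population does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .kinetics import (CellState, FoldChanges, IDENTITY_FOLDS, ReactionFluxes,
                       reaction_fluxes)
from .model_core import Enzyme, Hormone, ParameterSet, STEROIDS
from .sim_invitro import _pack_reaction_params, _fluxes_nb, _STOICH

_ENZ = (Enzyme.CYP19, Enzyme.HSD17B1, Enzyme.HSD17B2)
#: hormones with transport in vivo, state order
_HORMONES5 = (Hormone.A, Hormone.T, Hormone.E1, Hormone.E2, Hormone.FSH)

CYCLE_MINUTES = 5760.0  # 4-day rat estrous cycle


class EstrousStage(str, Enum):
    DIESTRUS = "diestrus"
    PROESTRUS = "proestrus"
    ESTRUS = "estrus"
    METESTRUS = "metestrus"


#: default stage partition of the cycle (minutes from cycle start)
STAGE_WINDOWS = {
    EstrousStage.DIESTRUS: (0.0, 1440.0),
    EstrousStage.PROESTRUS: (1440.0, 2880.0),
    EstrousStage.ESTRUS: (2880.0, 4320.0),
    EstrousStage.METESTRUS: (4320.0, 5760.0),
}


def stage_of(t: float, cycle_minutes: float = CYCLE_MINUTES) -> EstrousStage:
    """Map an absolute time to its estrous stage."""
    tc = t % cycle_minutes
    for stage, (lo, hi) in STAGE_WINDOWS.items():
        if lo <= tc < hi:
            return stage
    return EstrousStage.METESTRUS


@dataclass(frozen=True)
class CyclicInput:
    """Cyclic blood-to-ovary input rate for one hormone.

    Q_input(t) = Q_base + Q_scale * Q_shape(t); the shape is a sampled
    waveform interpolated linearly and periodically.  Units: pg/min for FSH,
    pmoles/min for steroids.
    """

    base: float
    scale: float = 0.0
    shape_t: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    shape_v: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    period: float = CYCLE_MINUTES

    def __post_init__(self):
        object.__setattr__(self, "shape_t", np.asarray(self.shape_t, float))
        object.__setattr__(self, "shape_v", np.asarray(self.shape_v, float))
        if self.shape_t.shape != self.shape_v.shape or self.shape_t.ndim != 1:
            raise ValueError("shape_t and shape_v must be 1-d and congruent")
        if self.period <= 0:
            raise ValueError("period must be positive")


def hormone_input_rate(t, inp: CyclicInput):
    """Evaluate Q_input(t); negative values are clamped to zero with a
    warning (the waveform should be constructed non-negative)."""
    tc = np.asarray(t, float) % inp.period
    q = inp.base + inp.scale * np.interp(tc, inp.shape_t, inp.shape_v,
                                         period=inp.period)
    if np.any(q < 0):
        warnings.warn("negative hormone input rate clamped to zero",
                      stacklevel=2)
        q = np.maximum(q, 0.0)
    return float(q) if np.isscalar(t) else q


@dataclass(frozen=True)
class OvaryGeometry:
    """Compartment sizes of the modelled ovary (constant by default)."""

    n_gcs: float = 6.17e7
    n_others: float = 6.17e7
    v_ext_ml: float = 0.05 / 3
    v_others_ml: float = 0.05 / 3

    def __post_init__(self):
        if min(self.n_gcs, self.n_others, self.v_ext_ml, self.v_others_ml) <= 0:
            raise ValueError("cell counts and volumes must be positive")


@dataclass
class InVivoOvary:
    """Snapshot state of the three-compartment ovary."""

    cell: CellState                # representative GC
    x_others: np.ndarray           # per-cell quantities (A, T, E1, E2, FSH)
    x_ext: np.ndarray              # extracellular quantities (A, T, E1, E2, FSH)
    geometry: OvaryGeometry

    def whole_ovary_concentrations(self, params: ParameterSet) -> dict:
        """Summed steroid quantities over all compartments divided by the
        diestrus ovarian volume (pmoles/ml)."""
        g = self.geometry
        out = {}
        for i, h in enumerate(STEROIDS):
            total = (g.n_gcs * self.cell.steroids[i]
                     + g.n_others * self.x_others[i] + self.x_ext[i])
            out[h.value] = total / params.v_ov_diestrus
        return out


# ---------------------------------------------------------------------------
# Compiled RHS: y = [mRNA(3), prot(3), X_gc(5), X_others(5), X_ext(5)]
# ---------------------------------------------------------------------------

N_STATE = 21


@njit(cache=False)
def _interp_periodic(t, period, xs, ys):
    tc = t % period
    n = xs.shape[0]
    if n == 1:
        return ys[0]
    if tc <= xs[0]:
        # wrap between last and first sample
        x0 = xs[n - 1] - period
        if xs[0] == x0:
            return ys[0]
        w = (tc - x0) / (xs[0] - x0)
        return ys[n - 1] + w * (ys[0] - ys[n - 1])
    if tc >= xs[n - 1]:
        x1 = xs[0] + period
        if x1 == xs[n - 1]:
            return ys[n - 1]
        w = (tc - xs[n - 1]) / (x1 - xs[n - 1])
        return ys[n - 1] + w * (ys[0] - ys[n - 1])
    lo = np.searchsorted(xs, tc) - 1
    w = (tc - xs[lo]) / (xs[lo + 1] - xs[lo])
    return ys[lo] + w * (ys[lo + 1] - ys[lo])


@njit(cache=False)
def _invivo_rhs_nb(t, y, nu_m, nu_p, dm, dp, kap, folds, sigma_l,
                   lam, kmz, kmc, kin, kout, v_gc, n_gcs, n_others,
                   v_ext, v_others, f_ov, v_ov,
                   qbase, qscale, qshape_t, qshape_v, qlen, period):
    dy = np.zeros(N_STATE)
    fsh_gc = y[10]
    # gene expression (shared cell model)
    for j in range(3):
        synth = sigma_l * folds[j] * nu_m[j]
        if j < 2:
            synth *= 1.0 + kap[j] * fsh_gc
        dy[j] = synth - dm * y[j]
        dy[3 + j] = nu_p[j] * y[j] - dp * y[3 + j]
    # metabolic fluxes in the representative GC
    sgc = np.empty(4)
    for s in range(4):
        sgc[s] = y[6 + s] if y[6 + s] > 0.0 else 0.0
    enz = np.empty(3)
    for j in range(3):
        enz[j] = y[3 + j] if y[3 + j] > 0.0 else 0.0
    fl = _fluxes_nb(sgc, enz, lam, kmz, kmc)
    v_oc = v_others / n_others  # per-cell volume of an "other cell"
    for s in range(5):
        c_ext = y[16 + s] / v_ext
        gc_out = kout[s] * y[6 + s] / v_gc
        gc_in = kin[s] * c_ext
        oth_out = kout[s] * y[11 + s] / v_oc
        oth_in = kin[s] * c_ext
        net = 0.0
        if s < 4:
            for i in range(6):
                net += _STOICH[s, i] * fl[i]
        dy[6 + s] = gc_in - gc_out + net
        dy[11 + s] = oth_in - oth_out
        q = qbase[s]
        if qscale[s] != 0.0:
            q += qscale[s] * _interp_periodic(t, period, qshape_t[s, :qlen[s]],
                                              qshape_v[s, :qlen[s]])
        if q < 0.0:
            q = 0.0
        dy[16 + s] = (q + n_gcs * (gc_out - gc_in) + n_others * (oth_out - oth_in)
                      - f_ov * y[16 + s] / v_ov)
    return dy


def invivo_rhs(t: float, ovary: InVivoOvary, params: ParameterSet,
               inputs: dict, fc: FoldChanges = IDENTITY_FOLDS,
               sigma_l: float = 1.0) -> np.ndarray:
    """Python-level in vivo right-hand side on the packed 21-state vector.

    ``inputs`` maps hormone name ("A", "T", "FSH") to :class:`CyclicInput`.
    Provided for inspection and testing; simulation uses the compiled twin.
    """
    y = _pack_invivo(ovary)
    args = _build_args(params, inputs, fc, sigma_l, ovary.geometry)
    return _invivo_rhs_nb(t, y, *args)


def _pack_invivo(ovary: InVivoOvary) -> np.ndarray:
    y = np.empty(N_STATE)
    y[0:3] = ovary.cell.mrna
    y[3:6] = ovary.cell.prot
    y[6:10] = ovary.cell.steroids
    y[10] = ovary.cell.fsh
    y[11:16] = ovary.x_others
    y[16:21] = ovary.x_ext
    return y


def _unpack_invivo(y: np.ndarray, geometry: OvaryGeometry) -> InVivoOvary:
    cell = CellState(mrna=y[0:3].copy(), prot=y[3:6].copy(),
                     steroids=np.maximum(y[6:10], 0.0), fsh=max(y[10], 0.0))
    return InVivoOvary(cell=cell, x_others=np.maximum(y[11:16], 0.0),
                       x_ext=np.maximum(y[16:21], 0.0), geometry=geometry)


def _build_args(params, inputs, fc, sigma_l, geom):
    nu_m = np.array([params.nu_mrna[e] for e in _ENZ])
    nu_p = np.array([params.nu_prot[e] for e in _ENZ])
    kap = np.array([params.kappa[Enzyme.CYP19], params.kappa[Enzyme.HSD17B1]])
    folds = np.array([fc.f_cyp19, fc.f_hsd17b1, 1.0])
    lam, kmz, kmc = _pack_reaction_params(params, fc)
    kin = np.array([params.k_in(h) for h in _HORMONES5])
    kout = np.array([params.k_out[h] for h in _HORMONES5])
    qbase = np.zeros(5)
    qscale = np.zeros(5)
    maxlen = max((len(i.shape_t) for i in inputs.values()), default=1)
    qshape_t = np.zeros((5, maxlen))
    qshape_v = np.zeros((5, maxlen))
    qlen = np.ones(5, dtype=np.int64)
    period = CYCLE_MINUTES
    for s, h in enumerate(_HORMONES5):
        inp = inputs.get(h.value)
        if inp is None:
            continue
        qbase[s] = inp.base
        qscale[s] = inp.scale
        n = len(inp.shape_t)
        qshape_t[s, :n] = inp.shape_t
        qshape_v[s, :n] = inp.shape_v
        qlen[s] = n
        period = inp.period
    return (nu_m, nu_p, params.delta_mrna, params.delta_prot, kap, folds,
            sigma_l, lam, kmz, kmc, kin, kout, params.v_gc,
            geom.n_gcs, geom.n_others, geom.v_ext_ml, geom.v_others_ml,
            params.f_ov, params.v_ov_diestrus,
            qbase, qscale, qshape_t, qshape_v, qlen, period)


# ---------------------------------------------------------------------------
# Templates and simulation
# ---------------------------------------------------------------------------

def inputs_from_template(template: dict, overrides: dict | None = None) -> dict:
    """Build the CyclicInput set from a forcing-template config.

    Baselines/scales default to the geometric means of the in vivo
    variability distributions; ``overrides`` may replace any of
    q_base_a/q_scale_a/q_base_t/q_scale_t/q_base_fsh/q_scale_fsh.
    """
    ov = overrides or {}
    defaults = {"q_base_fsh": 330.0, "q_scale_fsh": 1450.0,
                "q_base_a": 1.2, "q_scale_a": 18.0,
                "q_base_t": 3.0, "q_scale_t": 13.0}
    period = float(template.get("cycle_minutes", CYCLE_MINUTES))
    out = {}
    for key, name in (("FSH", "fsh"), ("A", "a"), ("T", "t")):
        shp = template["q_shape"][key]
        out[key] = CyclicInput(
            base=float(ov.get(f"q_base_{name}", defaults[f"q_base_{name}"])),
            scale=float(ov.get(f"q_scale_{name}", defaults[f"q_scale_{name}"])),
            shape_t=np.asarray(shp["t"], float),
            shape_v=np.asarray(shp["v"], float),
            period=period)
    return out


def geometry_from_template(template: dict) -> OvaryGeometry:
    g = template["geometry"]
    return OvaryGeometry(n_gcs=float(g["n_gcs"]), n_others=float(g["n_others"]),
                         v_ext_ml=float(g["v_ext_ml"]),
                         v_others_ml=float(g["v_others_ml"]))


@dataclass
class InVivoTrajectory:
    """In vivo simulation result on a regular output grid."""

    params: ParameterSet
    geometry: OvaryGeometry
    t: np.ndarray
    y: np.ndarray                  # (n, 21)
    fold_schedule: list            # [(t_start, FoldChanges), ...]
    sigma_l: float
    converged: bool
    cycle_drift: float

    def ovary_at(self, t: float) -> InVivoOvary:
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t={t} outside trajectory span")
        yi = np.array([np.interp(t, self.t, self.y[:, j])
                       for j in range(N_STATE)])
        return _unpack_invivo(yi, self.geometry)

    def folds_at(self, t: float) -> FoldChanges:
        fc = IDENTITY_FOLDS
        for ts, f in self.fold_schedule:
            if t >= ts:
                fc = f
        return fc

    def fluxes_at(self, t: float) -> ReactionFluxes:
        ov = self.ovary_at(t)
        return reaction_fluxes(ov.cell, self.params, self.folds_at(t))

    def concentration_table(self):
        """Stage-stamped whole-ovary steroid concentrations (pmoles/ml) and
        the blood-side FSH input rate on the output grid."""
        import pandas as pd
        rows = []
        for k, t in enumerate(self.t):
            ov = _unpack_invivo(self.y[k], self.geometry)
            conc = ov.whole_ovary_concentrations(self.params)
            rows.append({"time_min": t, "stage": stage_of(t).value, **conc})
        return pd.DataFrame(rows)


def simulate_cycle(params: ParameterSet, inputs: dict,
                   geometry: OvaryGeometry | None = None,
                   n_cycles: int = 3, sigma_l: float = 1.0,
                   fold_schedule: list | None = None,
                   points_per_cycle: int = 192,
                   rtol: float = 1e-7, atol: float = 1e-16,
                   max_extra_cycles: int = 4) -> InVivoTrajectory:
    """Simulate ``n_cycles`` estrous cycles (the first is burn-in).

    The ovary starts at the unstimulated gene-expression equilibrium with no
    steroids; a periodic steady cycle is detected when the state at
    successive cycle boundaries changes by less than 0.1% (relative, per
    state above solver noise).  Extra cycles are appended (up to
    ``max_extra_cycles``) if the orbit has not settled.
    """
    if n_cycles < 2:
        raise ValueError("need at least two cycles (first is burn-in)")
    geometry = geometry or OvaryGeometry()
    fold_schedule = sorted(fold_schedule or [], key=lambda p: p[0])
    y0 = np.zeros(N_STATE)
    cell0 = CellState.baseline(params)
    y0[0:3], y0[3:6] = cell0.mrna, cell0.prot

    period = next(iter(inputs.values())).period if inputs else CYCLE_MINUTES

    def integrate(yini, t0, t1):
        grid = np.linspace(t0, t1, max(2, int(round((t1 - t0) / period
                                                    * points_per_cycle)) + 1))
        # split at fold-change switch points inside (t0, t1)
        ts = [t0] + [s for s, _ in fold_schedule if t0 < s < t1] + [t1]
        allt, ally = [], []
        y = yini
        for a, b in zip(ts[:-1], ts[1:]):
            fc = IDENTITY_FOLDS
            for s, f in fold_schedule:
                if a >= s:
                    fc = f
            args = _build_args(params, inputs, fc, sigma_l, geometry)
            sub = grid[(grid >= a) & (grid <= b)]
            t_eval = np.unique(np.concatenate([[a], sub, [b]]))
            sol = solve_ivp(_invivo_rhs_nb, (a, b), y, method="LSODA",
                            t_eval=t_eval, rtol=rtol, atol=atol, args=args)
            if not sol.success:
                raise RuntimeError(f"in vivo integration failed: {sol.message}")
            allt.append(sol.t[:-1])
            ally.append(sol.y[:, :-1].T)
            y = sol.y[:, -1]
        allt.append(np.array([t1]))
        ally.append(y[None, :])
        return np.concatenate(allt), np.vstack(ally), y

    t_all, y_all = [], []
    y = y0
    prev_boundary = None
    drift = np.inf
    converged = False
    cycles_run = 0
    while cycles_run < n_cycles + max_extra_cycles:
        t0c = cycles_run * period
        tt, yy, y = integrate(y, t0c, t0c + period)
        t_all.append(tt if cycles_run == 0 else tt[1:])
        y_all.append(yy if cycles_run == 0 else yy[1:])
        cycles_run += 1
        if prev_boundary is not None:
            scale = np.maximum(np.abs(prev_boundary), np.abs(y))
            mask = scale > 1e-12 * scale.max()
            drift = np.max(np.abs(y - prev_boundary)[mask] / scale[mask])
            if cycles_run >= n_cycles and drift < 1e-3:
                converged = True
                break
        prev_boundary = y.copy()
        # stop exactly at n_cycles if a disruption schedule is active: the
        # perturbed orbit is transient by construction
        if fold_schedule and cycles_run >= n_cycles:
            converged = drift < np.inf
            break
    if not converged and not fold_schedule:
        warnings.warn(f"no periodic steady cycle after {cycles_run} cycles "
                      f"(boundary drift {drift:.2e})", stacklevel=2)
    return InVivoTrajectory(params=params, geometry=geometry,
                            t=np.concatenate(t_all), y=np.vstack(y_all),
                            fold_schedule=fold_schedule, sigma_l=sigma_l,
                            converged=converged, cycle_drift=float(drift))


# ---------------------------------------------------------------------------
# Monte-Carlo prediction
# ---------------------------------------------------------------------------

def _apply_invivo_draw(params: ParameterSet, draw: dict) -> ParameterSet:
    """Overlay one draw from the in vivo variability distributions."""
    kw = {}
    if "f_ov" in draw:
        kw["f_ov"] = draw["f_ov"]
    if "delta_mrna" in draw:
        kw["delta_mrna"] = draw["delta_mrna"]
    if "delta_prot" in draw:
        kw["delta_prot"] = draw["delta_prot"]
    k_out = dict(params.k_out)
    r_oi = dict(params.r_oi)
    for h, suf in ((Hormone.A, "a"), (Hormone.T, "t"),
                   (Hormone.E1, "e1"), (Hormone.E2, "e2")):
        if f"k_out_{suf}" in draw:
            k_out[h] = draw[f"k_out_{suf}"]
        if f"r_oi_{suf}" in draw:
            r_oi[h] = draw[f"r_oi_{suf}"]
    kw["k_out"], kw["r_oi"] = k_out, r_oi
    nu_m = dict(params.nu_mrna)
    nu_p = dict(params.nu_prot)
    for e, suf in ((Enzyme.CYP19, "cyp19"), (Enzyme.HSD17B1, "hsd17b1"),
                   (Enzyme.HSD17B2, "hsd17b2")):
        if f"nu_mrna_{suf}" in draw:
            nu_m[e] = draw[f"nu_mrna_{suf}"]
        if f"nu_prot_{suf}" in draw:
            nu_p[e] = draw[f"nu_prot_{suf}"]
    kw["nu_mrna"], kw["nu_prot"] = nu_m, nu_p
    lam = dict(params.lam)
    xi = dict(params.xi)
    if "lam_hsd17b2_t" in draw:
        lam[(Enzyme.HSD17B2, Hormone.T)] = draw["lam_hsd17b2_t"]
    if "lam_hsd17b2_e2" in draw:
        lam[(Enzyme.HSD17B2, Hormone.E2)] = draw["lam_hsd17b2_e2"]
    if "xi_hsd17b2_t" in draw:
        xi[(Enzyme.HSD17B2, Hormone.T)] = draw["xi_hsd17b2_t"]
    if "xi_hsd17b2_e2" in draw:
        xi[(Enzyme.HSD17B2, Hormone.E2)] = draw["xi_hsd17b2_e2"]
    kw["lam"], kw["xi"] = lam, xi
    return params.replace(**kw)


def _apply_kinetic_row(params: ParameterSet, row: dict) -> ParameterSet:
    """Overlay one posterior kinetic vector (by calibration parameter name)."""
    return params.with_kinetics(
        kappa_cyp19=row.get("kappa_cyp19"),
        kappa_hsd17b1=row.get("kappa_hsd17b1"),
        lam={(Enzyme.CYP19, Hormone.A): row["lam_cyp19_a"],
             (Enzyme.CYP19, Hormone.T): row["lam_cyp19_t"],
             (Enzyme.HSD17B1, Hormone.A): row["lam_hsd17b1_a"],
             (Enzyme.HSD17B1, Hormone.E1): row["lam_hsd17b1_e1"]},
        xi={(Enzyme.CYP19, Hormone.A): row["xi_cyp19_a"],
            (Enzyme.CYP19, Hormone.T): row["xi_cyp19_t"],
            (Enzyme.HSD17B1, Hormone.A): row["xi_hsd17b1_a"],
            (Enzyme.HSD17B1, Hormone.E1): row["xi_hsd17b1_e1"]})


def monte_carlo_predict(posterior_samples, invivo_priors: dict,
                        n: int, seed: int, params: ParameterSet,
                        template: dict, n_cycles: int = 3,
                        fold_schedule: list | None = None,
                        sigma_l: float = 1.0,
                        points_per_cycle: int = 96) -> dict:
    """Monte-Carlo in vivo prediction bands.

    Each draw combines one posterior kinetic vector (a row of
    ``posterior_samples``; pass None to keep ``params`` fixed) with one draw
    from each in vivo variability distribution, then simulates the cyclic
    ovary.  Returns the per-time mean and central 95% band of the
    whole-ovary concentrations over the final cycle.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    geometry = geometry_from_template(template)
    period = float(template.get("cycle_minutes", CYCLE_MINUTES))
    grid = np.linspace((n_cycles - 1) * period, n_cycles * period,
                       points_per_cycle + 1)
    conc = {h.value: np.empty((n, grid.size)) for h in STEROIDS}
    for k in range(n):
        draw = {name: float(spec.sample(1, rng)[0])
                for name, spec in invivo_priors.items()}
        pk = _apply_invivo_draw(params, draw)
        if posterior_samples is not None and len(posterior_samples):
            row = posterior_samples.iloc[rng.integers(len(posterior_samples))]
            pk = _apply_kinetic_row(pk, row)
        inputs = inputs_from_template(template, overrides=draw)
        traj = simulate_cycle(pk, inputs, geometry, n_cycles=n_cycles,
                              sigma_l=sigma_l, fold_schedule=fold_schedule,
                              points_per_cycle=points_per_cycle)
        tab = traj.concentration_table()
        for h in STEROIDS:
            conc[h.value][k] = np.interp(grid, tab["time_min"], tab[h.value])
    out = {"t": grid}
    for h in STEROIDS:
        c = conc[h.value]
        out[h.value] = {"mean": c.mean(axis=0),
                        "lo": np.percentile(c, 2.5, axis=0),
                        "hi": np.percentile(c, 97.5, axis=0),
                        "draws": c}
    return out
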