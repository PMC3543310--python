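"""Two-compartment (granulosa cell + culture medium) in vitro simulation.

All bookkeeping is per cell: medium quantities are total quantities divided
by the number of cells in the assay, and V_med is the medium volume per cell.
Hormones move between medium and cell by simple diffusion with uptake rate
K_in = K_out / R_oi, so the equilibrium concentration ratio medium/cell is
the partition coefficient R_oi.

The gene-expression + FSH-transport subsystem is linear and autonomous
(transcription depends on intracellular FSH, whose exchange with the medium
is itself linear), so it is solved in closed form as sums of exponentials.
Only the nine steroid states (four per compartment plus cumulative tritiated
water) are integrated numerically, with the enzyme trajectories fed in as
exact time functions.  A full 17-state ODE path is retained for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.integrate import odeint, solve_ivp

from .kinetics import (CellState, FoldChanges, IDENTITY_FOLDS, ReactionFluxes,
                       reaction_fluxes, steroid_net_rates)
from .model_core import Enzyme, Hormone, ParameterSet, STEROIDS

_ENZ = (Enzyme.CYP19, Enzyme.HSD17B1, Enzyme.HSD17B2)

# reaction structure in canonical order alpha1..alpha6
_R_ENZ = np.array([0, 1, 2, 0, 1, 2])      # enzyme index per reaction
_R_SUB = np.array([0, 0, 1, 1, 2, 3])      # substrate steroid index
_R_COMP = np.array([1, 2, 3, 0, 0, 1])     # competing steroid index
# net stoichiometry: steroid s gains/loses flux i
_STOICH = np.array([
    [-1, -1, +1, 0, 0, 0],
    [0, +1, -1, -1, 0, 0],
    [+1, 0, 0, 0, -1, +1],
    [0, 0, 0, +1, +1, -1],
], dtype=np.float64)


@dataclass
class InVitroSystem:
    """Declarative description of one in vitro experiment."""

    cells_per_ml: float = 3.0e5
    medium_volume_ml: float = 2.0
    initial_medium_nM: dict = field(default_factory=dict)  # steroid -> nM
    fsh_ng_ml: float = 0.0
    fold_changes: FoldChanges = IDENTITY_FOLDS
    sigma_l: float = 1.0
    duration_min: float = 2880.0

    def __post_init__(self):
        if self.cells_per_ml <= 0 or self.medium_volume_ml <= 0:
            raise ValueError("cell density and medium volume must be positive")
        if self.sigma_l <= 0 or self.duration_min <= 0:
            raise ValueError("sigma_l and duration must be positive")
        for k, v in self.initial_medium_nM.items():
            if v < 0:
                raise ValueError(f"negative initial concentration for {k}")

    @property
    def n_cells(self) -> float:
        return self.cells_per_ml * self.medium_volume_ml

    @property
    def v_med(self) -> float:
        """Medium volume per cell (ml)."""
        return 1.0 / self.cells_per_ml

    def initial_medium_quantities(self) -> np.ndarray:
        """Per-cell medium steroid quantities (pmoles), order (A, T, E1, E2).
        1 nM = 1 pmol/ml."""
        out = np.zeros(4)
        for i, h in enumerate(STEROIDS):
            out[i] = self.initial_medium_nM.get(h.value, 0.0) * self.v_med
        return out

    @property
    def fsh_med0(self) -> float:
        """Per-cell medium FSH quantity (pg); 1 ng/ml = 1000 pg/ml."""
        return self.fsh_ng_ml * 1000.0 * self.v_med

    @classmethod
    def from_config(cls, cfg: dict) -> "InVitroSystem":
        exp = cfg.get("experiment", cfg)
        fc = exp.get("fold_changes", {})
        return cls(
            cells_per_ml=float(exp["cells_per_ml"]),
            medium_volume_ml=float(exp["medium_volume_ml"]),
            initial_medium_nM={k: float(v)
                               for k, v in exp.get("initial_medium_nM", {}).items()},
            fsh_ng_ml=float(exp.get("fsh_ng_ml", 0.0)),
            fold_changes=FoldChanges(float(fc.get("f_cyp19", 1.0)),
                                     float(fc.get("f_hsd17b1", 1.0)),
                                     float(fc.get("f_m", 1.0))),
            sigma_l=float(exp.get("sigma_l", 1.0)),
            duration_min=float(exp.get("duration_min", 2880.0)),
        )


# ---------------------------------------------------------------------------
# Closed-form gene expression and FSH transport
# ---------------------------------------------------------------------------

class GeneSolution:
    """Exact solution of the linear FSH-transport + gene-expression subsystem.

    FSH_GC(t) = F_inf + (F0 - F_inf) exp(-k_f t); each enzyme's mRNA and
    protein are sums of exponentials in exp(-delta_mRNA t), exp(-delta_prot t)
    and exp(-k_f t).
    """

    def __init__(self, params: ParameterSet, fc: FoldChanges, sigma_l: float,
                 fsh_total: float, v_med: float, fsh_gc0: float = 0.0,
                 mrna0: np.ndarray | None = None,
                 prot0: np.ndarray | None = None):
        dm, dp = params.delta_mrna, params.delta_prot
        kin_f = params.k_in(Hormone.FSH)
        kout_f = params.k_out[Hormone.FSH]
        kf = kin_f / v_med + kout_f / params.v_gc
        if min(abs(dm - dp), abs(kf - dm), abs(kf - dp)) < 1e-9 * max(dm, dp, kf):
            raise ValueError("degenerate rate constants; use the full ODE path")
        self.rates = np.array([dm, dp, kf])
        self.fsh_total = fsh_total
        self.f_inf = (kin_f * fsh_total / v_med) / kf
        self.f0 = fsh_gc0

        m0 = np.array([params.mrna0[e] for e in _ENZ]) if mrna0 is None else mrna0
        p0 = np.array([params.prot0[e] for e in _ENZ]) if prot0 is None else prot0
        folds = (fc.f_cyp19, fc.f_hsd17b1, 1.0)
        kappas = (params.kappa[Enzyme.CYP19], params.kappa[Enzyme.HSD17B1], 0.0)

        # coefficient layout: value(t) = c0 + c1 e^{-dm t} + c2 e^{-dp t} + c3 e^{-kf t}
        self.mcoef = np.zeros((3, 4))
        self.pcoef = np.zeros((3, 4))
        for j, enz in enumerate(_ENZ):
            base = sigma_l * folds[j] * params.nu_mrna[enz]
            b0 = base * (1.0 + kappas[j] * self.f_inf)
            b1 = base * kappas[j] * (self.f0 - self.f_inf)
            np_j = params.nu_prot[enz]
            m_kf = b1 / (dm - kf)
            c_m = m0[j] - b0 / dm - m_kf
            self.mcoef[j] = (b0 / dm, c_m, 0.0, m_kf)
            e0 = np_j * b0 / (dm * dp)
            e1 = np_j * c_m / (dp - dm)
            e3 = np_j * b1 / ((dm - kf) * (dp - kf))
            e2 = p0[j] - e0 - e1 - e3
            self.pcoef[j] = (e0, e1, e2, e3)

    def _eval(self, coef, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        ex = np.exp(-np.multiply.outer(self.rates, np.atleast_1d(t)))  # (3, n)
        out = coef[:, [0]] + coef[:, 1:] @ ex
        return out[:, 0] if scalar else out

    def mrna(self, t):
        return self._eval(self.mcoef, t)

    def protein(self, t):
        return self._eval(self.pcoef, t)

    def fsh_gc(self, t):
        t = np.asarray(t, dtype=float)
        return self.f_inf + (self.f0 - self.f_inf) * np.exp(-self.rates[2] * t)

    def fsh_med(self, t):
        return self.fsh_total - self.fsh_gc(t)


# ---------------------------------------------------------------------------
# Compiled steroid subsystem
# ---------------------------------------------------------------------------

@njit(cache=False)
def _fluxes_nb(sgc, enz, lam, kmz, kmc):
    """Six competitive MM fluxes from clipped intracellular quantities."""
    out = np.zeros(6)
    for i in range(6):
        z = sgc[_R_SUB[i]]
        if z <= 0.0:
            continue
        c = sgc[_R_COMP[i]]
        if c < 0.0:
            c = 0.0
        out[i] = lam[i] * enz[_R_ENZ[i]] * z / (kmz[i] * (1.0 + c / kmc[i]) + z)
    return out


@njit(cache=False)
def _enzymes_at(t, ecoef, erates):
    enz = np.empty(3)
    e1 = np.exp(-erates[0] * t)
    e2 = np.exp(-erates[1] * t)
    e3 = np.exp(-erates[2] * t)
    for j in range(3):
        enz[j] = ecoef[j, 0] + ecoef[j, 1] * e1 + ecoef[j, 2] * e2 + ecoef[j, 3] * e3
    return enz


@njit(cache=False)
def _steroid_rhs_nb(t, y, lam, kmz, kmc, kin, kout, v_gc, v_med, ecoef, erates):
    """RHS of the 9-state steroid subsystem.

    y = [A_gc, T_gc, E1_gc, E2_gc, A_med, T_med, E1_med, E2_med, T2O].
    """
    enz = _enzymes_at(t, ecoef, erates)
    sgc = np.empty(4)
    for s in range(4):
        sgc[s] = y[s] if y[s] > 0.0 else 0.0
    fl = _fluxes_nb(sgc, enz, lam, kmz, kmc)
    dy = np.zeros(9)
    for s in range(4):
        transport_in = kin[s] * y[4 + s] / v_med
        transport_out = kout[s] * y[s] / v_gc
        net = 0.0
        for i in range(6):
            net += _STOICH[s, i] * fl[i]
        dy[s] = transport_in - transport_out + net
        dy[4 + s] = transport_out - transport_in
    dy[8] = fl[0]
    return dy


def _pack_reaction_params(params: ParameterSet, fc: FoldChanges):
    lam = np.empty(6)
    kmz = np.empty(6)
    kmc = np.empty(6)
    from .model_core import REACTIONS
    for i, (enz, sub, _prod, comp) in enumerate(REACTIONS):
        scale = fc.f_m if enz is Enzyme.CYP19 else 1.0
        lam[i] = params.lam[(enz, sub)]
        kmz[i] = scale * params.xi[(enz, sub)]
        kmc[i] = scale * params.xi[(enz, comp)]
    return lam, kmz, kmc


def _transport_arrays(params: ParameterSet):
    kin = np.array([params.k_in(h) for h in STEROIDS])
    kout = np.array([params.k_out[h] for h in STEROIDS])
    return kin, kout


# ---------------------------------------------------------------------------
# Full 17-state reference RHS (cross-check path)
# ---------------------------------------------------------------------------

#: full state layout: [mRNA(3), prot(3), steroids_GC(4), FSH_GC,
#:                     steroids_med(4), FSH_med, T2O]
FULL_STATE_SIZE = 17


def pack_full_state(cell: CellState, med: np.ndarray, fsh_med: float) -> np.ndarray:
    y = np.empty(FULL_STATE_SIZE)
    y[0:3] = cell.mrna
    y[3:6] = cell.prot
    y[6:10] = cell.steroids
    y[10] = cell.fsh
    y[11:15] = med
    y[15] = fsh_med
    y[16] = cell.t2o
    return y


def invitro_rhs(t: float, y: np.ndarray, params: ParameterSet,
                v_med: float, fc: FoldChanges = IDENTITY_FOLDS,
                sigma_l: float = 1.0) -> np.ndarray:
    """Full in vitro right-hand side on the packed 17-state vector.

    Combines gene expression, diffusion transport for the four steroids and
    FSH (transport only), the six metabolic fluxes, and tritiated-water
    accumulation.  Used as the reference/cross-check path; the production
    integrator solves the linear subsystem in closed form instead.
    """
    from .kinetics import gene_expression_rhs
    cell = CellState(mrna=y[0:3].copy(), prot=y[3:6].copy(),
                     steroids=y[6:10].copy(), fsh=y[10], t2o=y[16])
    dmrna, dprot = gene_expression_rhs(cell, params, fc, sigma_l)
    fl = reaction_fluxes(cell, params, fc)
    net = steroid_net_rates(fl)
    dy = np.empty_like(y)
    dy[0:3] = dmrna
    dy[3:6] = dprot
    kin, kout = _transport_arrays(params)
    for s in range(4):
        tin = kin[s] * y[11 + s] / v_med
        tout = kout[s] * y[6 + s] / params.v_gc
        dy[6 + s] = tin - tout + net[s]
        dy[11 + s] = tout - tin
    kin_f = params.k_in(Hormone.FSH)
    kout_f = params.k_out[Hormone.FSH]
    tin = kin_f * y[15] / v_med
    tout = kout_f * y[10] / params.v_gc
    dy[10] = tin - tout
    dy[15] = tout - tin
    dy[16] = fl.alpha[0]
    return dy


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class InVitroTrajectory:
    """Simulation result with exact gene-expression reconstruction and dense
    steroid output for interpolation."""

    system: InVitroSystem
    params: ParameterSet
    t: np.ndarray
    steroids_gc: np.ndarray    # (n, 4)
    steroids_med: np.ndarray   # (n, 4)
    t2o: np.ndarray            # (n,)
    genes: GeneSolution
    _dense: object = None      # scipy OdeSolution over the steroid states

    @property
    def mrna(self) -> np.ndarray:
        return self.genes.mrna(self.t).T

    @property
    def protein(self) -> np.ndarray:
        return self.genes.protein(self.t).T

    @property
    def fsh_gc(self) -> np.ndarray:
        return np.asarray(self.genes.fsh_gc(self.t))

    def state_at(self, t: float) -> CellState:
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t={t} outside trajectory span")
        if self._dense is not None:
            y = self._dense(t)
        else:
            y = np.array([np.interp(t, self.t, col) for col in
                          np.column_stack([self.steroids_gc, self.steroids_med,
                                           self.t2o]).T])
        return CellState(mrna=self.genes.mrna(t), prot=self.genes.protein(t),
                         steroids=np.maximum(y[0:4], 0.0),
                         fsh=float(self.genes.fsh_gc(t)), t2o=max(y[8], 0.0))

    def fluxes_at(self, t: float) -> ReactionFluxes:
        return reaction_fluxes(self.state_at(t), self.params,
                               self.system.fold_changes)

    def total_steroids(self) -> np.ndarray:
        """Per-time-point total (cell + medium) steroid content, pmoles."""
        return self.steroids_gc.sum(axis=1) + self.steroids_med.sum(axis=1)

    def to_frame(self):
        """Long-format table (time, compartment, species, quantity,
        concentration)."""
        import pandas as pd
        rows = []
        v_gc, v_med = self.params.v_gc, self.system.v_med
        names = [h.value for h in STEROIDS]
        for k, t in enumerate(self.t):
            for i, nm in enumerate(names):
                rows.append((t, "GC", nm, self.steroids_gc[k, i],
                             self.steroids_gc[k, i] / v_gc))
                rows.append((t, "medium", nm, self.steroids_med[k, i],
                             self.steroids_med[k, i] / v_med))
            rows.append((t, "GC", "FSH", self.fsh_gc[k], self.fsh_gc[k] / v_gc))
            for j, enz in enumerate(_ENZ):
                rows.append((t, "GC", f"mRNA_{enz.value}", self.mrna[k, j], np.nan))
                rows.append((t, "GC", f"prot_{enz.value}", self.protein[k, j], np.nan))
            rows.append((t, "GC", "T2O", self.t2o[k], np.nan))
        return pd.DataFrame(rows, columns=["time_min", "compartment", "species",
                                           "quantity", "concentration"])


def simulate_invitro(system: InVitroSystem, params: ParameterSet,
                     t_grid: np.ndarray | None = None,
                     rtol: float = 1e-8, atol: float = 1e-14,
                     dense: bool = True) -> InVitroTrajectory:
    """Integrate the in vitro system from treatment start (t = 0).

    Cells start at their unstimulated gene-expression equilibrium with no
    intracellular steroids; the medium carries the declared initial steroid
    and FSH content.  Stiff-capable (LSODA); states span many orders of
    magnitude, hence the small absolute tolerance.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, system.duration_min, 97)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase from 0")
    v_med = system.v_med
    if v_med <= params.v_gc:
        raise ValueError("medium volume per cell must exceed the cell volume")

    genes = GeneSolution(params, system.fold_changes, system.sigma_l,
                         fsh_total=system.fsh_med0, v_med=v_med)
    lam, kmz, kmc = _pack_reaction_params(params, system.fold_changes)
    kin, kout = _transport_arrays(params)
    y0 = np.zeros(9)
    y0[4:8] = system.initial_medium_quantities()

    sol = solve_ivp(
        _steroid_rhs_nb, (0.0, float(t_grid[-1])), y0, method="LSODA",
        t_eval=t_grid, dense_output=dense, rtol=rtol, atol=atol,
        args=(lam, kmz, kmc, kin, kout, params.v_gc, v_med,
              genes.pcoef, genes.rates))
    if not sol.success:
        raise RuntimeError(f"in vitro integration failed: {sol.message}")
    return InVitroTrajectory(
        system=system, params=params, t=sol.t,
        steroids_gc=np.maximum(sol.y[0:4].T, 0.0),
        steroids_med=np.maximum(sol.y[4:8].T, 0.0),
        t2o=np.maximum(sol.y[8], 0.0),
        genes=genes, _dense=sol.sol if dense else None)


def simulate_invitro_full(system: InVitroSystem, params: ParameterSet,
                          t_grid: np.ndarray | None = None,
                          rtol: float = 1e-8, atol: float = 1e-14):
    """Reference integration of the full 17-state ODE (no closed forms).

    Returns (t, y) with the layout of :func:`pack_full_state`.  Used to
    cross-validate the split integration scheme.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, system.duration_min, 97)
    y0 = pack_full_state(CellState.baseline(params),
                         system.initial_medium_quantities(), system.fsh_med0)
    sol = solve_ivp(
        invitro_rhs, (0.0, float(t_grid[-1])), y0, method="LSODA",
        t_eval=np.asarray(t_grid, dtype=float), rtol=rtol, atol=atol,
        args=(params, system.v_med, system.fold_changes, system.sigma_l))
    if not sol.success:
        raise RuntimeError(f"full in vitro integration failed: {sol.message}")
    return sol.t, sol.y


def tritiated_water_assay(traj: InVitroTrajectory):
    """Cumulative tritiated-water release (pmoles/cell) versus time.

    One labelled water molecule is released per aromatization of labelled A,
    so the series is the running time-integral of the A->E1 flux and is
    monotone non-decreasing.
    """
    import pandas as pd
    return pd.Series(traj.t2o, index=pd.Index(traj.t, name="time_min"),
                     name="T2O_pmoles")


# fast path for the calibration likelihood ----------------------------------

_solve_counter = {"n": 0}


def fast_final_state(params: ParameterSet, fc: FoldChanges, sigma_l: float,
                     v_med: float, med0: np.ndarray, fsh_med0: float,
                     duration: float, rtol: float = 1e-6,
                     atol: float = 1e-16) -> np.ndarray:
    """Endpoint-only integration used by the calibration likelihood.

    Returns the 9-vector [steroids_GC(4), steroids_med(4), T2O] at
    ``duration`` minutes.  Looser relative tolerance than the default
    simulator: prediction error is kept far below measurement noise.
    """
    genes = GeneSolution(params, fc, sigma_l, fsh_total=fsh_med0, v_med=v_med)
    lam, kmz, kmc = _pack_reaction_params(params, fc)
    kin, kout = _transport_arrays(params)
    y0 = np.zeros(9)
    y0[4:8] = med0
    _solve_counter["n"] += 1
    out = odeint(_steroid_rhs_nb, y0, np.array([0.0, duration]),
                 args=(lam, kmz, kmc, kin, kout, params.v_gc, v_med,
                       genes.pcoef, genes.rates),
                 rtol=rtol, atol=atol, tfirst=True, mxstep=100000)
    return out[-1]
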