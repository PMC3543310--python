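"""Right-hand-side building blocks for the granulosa-cell model.

Gene-expression mass balances, endocrine-disruptor fold-change application,
and the six competitive Michaelis-Menten steroid interconversion fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (Enzyme, Hormone, ParameterSet, REACTIONS,
                         REACTION_LABELS, STEROIDS)

_ENZ = (Enzyme.CYP19, Enzyme.HSD17B1, Enzyme.HSD17B2)


@dataclass
class CellState:
    """State of one granulosa cell.

    mrna, prot: pg, ordered (Cyp19, Hsd17b1, Hsd17b2).
    steroids: pmoles, ordered (A, T, E1, E2).
    fsh: pg.  t2o: cumulative tritiated water, pmoles (non-decreasing).
    """

    mrna: np.ndarray
    prot: np.ndarray
    steroids: np.ndarray
    fsh: float = 0.0
    t2o: float = 0.0

    def __post_init__(self):
        self.mrna = np.asarray(self.mrna, dtype=float)
        self.prot = np.asarray(self.prot, dtype=float)
        self.steroids = np.asarray(self.steroids, dtype=float)
        if self.mrna.shape != (3,) or self.prot.shape != (3,):
            raise ValueError("mrna and prot must each have three entries")
        if self.steroids.shape != (4,):
            raise ValueError("steroids must have four entries (A, T, E1, E2)")

    @classmethod
    def baseline(cls, params: ParameterSet) -> "CellState":
        """Cell at its unstimulated gene-expression equilibrium, steroid-free."""
        return cls(
            mrna=np.array([params.mrna0[e] for e in _ENZ]),
            prot=np.array([params.prot0[e] for e in _ENZ]),
            steroids=np.zeros(4),
        )


@dataclass(frozen=True)
class FoldChanges:
    """Multiplicative disruptor effects: f on mRNA synthesis of the two
    FSH-inducible enzymes and f_M on the aromatase Km (both substrates).
    The identity element is all ones."""

    f_cyp19: float = 1.0
    f_hsd17b1: float = 1.0
    f_m: float = 1.0

    def __post_init__(self):
        if min(self.f_cyp19, self.f_hsd17b1, self.f_m) <= 0:
            raise ValueError("fold-changes must be strictly positive")

    @property
    def is_identity(self) -> bool:
        return self.f_cyp19 == self.f_hsd17b1 == self.f_m == 1.0


IDENTITY_FOLDS = FoldChanges()


@dataclass(frozen=True)
class ReactionFluxes:
    """The six biotransformation rates alpha1..alpha6, pmoles/min/cell."""

    alpha: np.ndarray  # shape (6,)

    @property
    def labels(self):
        return REACTION_LABELS

    def __getitem__(self, i):
        return self.alpha[i]

    def relative(self) -> np.ndarray:
        """Fluxes relative to the reference A->E1 aromatization (alpha1).
        NaN when the reference flux is zero."""
        a1 = self.alpha[0]
        if a1 == 0:
            return np.full(6, np.nan)
        return self.alpha / a1


def km_fold_change(activity_fold: float) -> float:
    """Km fold f_M from a measured aromatase activity fold-change.

    Direct competitive inhibition raises the apparent Km; since activity is
    inversely proportional to Km, f_M is the reciprocal of the activity fold.
    """
    if activity_fold <= 0:
        raise ValueError("activity fold-change must be strictly positive")
    return 1.0 / activity_fold


def mrna_fold_change(treated_equilibrium: float, control_equilibrium: float) -> float:
    """Transcription fold-change f from measured treated/control mRNA levels."""
    if control_equilibrium <= 0:
        raise ValueError("control mRNA level must be strictly positive")
    return treated_equilibrium / control_equilibrium


_STEROID_INDEX = {h: i for i, h in enumerate(STEROIDS)}


def reaction_fluxes(state: CellState, params: ParameterSet,
                    fc: FoldChanges = IDENTITY_FOLDS) -> ReactionFluxes:
    """Evaluate the six competitive Michaelis-Menten fluxes at a cell state.

    For reaction i of enzyme eps converting substrate Z with competing
    substrate C (the enzyme's other substrate):

        alpha_i = lam[eps,Z] * eps * Z / (Km_Z * (1 + C/Km_C) + Z)

    with Km = f_M * xi for both aromatase substrates and Km = xi otherwise.
    Quantities are clipped at zero, so degenerate states give zero flux.
    """
    s = np.maximum(state.steroids, 0.0)
    prot = np.maximum(state.prot, 0.0)
    enz_qty = {e: prot[i] for i, e in enumerate(_ENZ)}
    out = np.empty(6)
    for i, (enz, sub, _prod, comp) in enumerate(REACTIONS):
        km_scale = fc.f_m if enz is Enzyme.CYP19 else 1.0
        km_z = km_scale * params.xi[(enz, sub)]
        km_c = km_scale * params.xi[(enz, comp)]
        z = s[_STEROID_INDEX[sub]]
        c = s[_STEROID_INDEX[comp]]
        denom = km_z * (1.0 + c / km_c) + z
        out[i] = 0.0 if z == 0.0 else (
            params.lam[(enz, sub)] * enz_qty[enz] * z / denom)
    return ReactionFluxes(out)


def steroid_net_rates(fluxes: ReactionFluxes) -> np.ndarray:
    """Net metabolic production rate of (A, T, E1, E2) from the six fluxes.

    A gains alpha3 and loses alpha1 + alpha2; T gains alpha2 and loses
    alpha3 + alpha4; E1 gains alpha1 + alpha6 and loses alpha5; E2 gains
    alpha4 + alpha5 and loses alpha6.  The sum is identically zero: the
    fluxes only interconvert the four steroids.
    """
    a = fluxes.alpha
    return np.array([
        a[2] - a[0] - a[1],
        a[1] - a[2] - a[3],
        a[0] + a[5] - a[4],
        a[3] + a[4] - a[5],
    ])


def t2o_rate(fluxes: ReactionFluxes) -> float:
    """Tritiated-water formation rate: one labelled water molecule per
    aromatization of labelled A, i.e. alpha1.  Aromatization of T releases
    no label from A."""
    return float(fluxes.alpha[0])


def gene_expression_rhs(state: CellState, params: ParameterSet,
                        fc: FoldChanges = IDENTITY_FOLDS,
                        sigma_l: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Time-derivatives of the three mRNA and three protein quantities.

    Cyp19 and Hsd17b1 transcription is FSH-inducible and disruptor-sensitive:

        d mRNA/dt = sigma_L * f * nu_mRNA * (1 + kappa * FSH_GC)
                    - delta_mRNA * mRNA

    Hsd17b2 transcription carries the study effect only (no FSH or disruptor
    term).  Translation for all three enzymes:

        d prot/dt = nu_prot * mRNA - delta_prot * prot
    """
    if sigma_l <= 0:
        raise ValueError("sigma_l must be strictly positive")
    folds = (fc.f_cyp19, fc.f_hsd17b1, 1.0)
    dmrna = np.empty(3)
    for i, enz in enumerate(_ENZ):
        synth = sigma_l * folds[i] * params.nu_mrna[enz]
        if enz is not Enzyme.HSD17B2:
            synth *= 1.0 + params.kappa[enz] * state.fsh
        dmrna[i] = synth - params.delta_mrna * state.mrna[i]
    dprot = np.array([params.nu_prot[e] for e in _ENZ]) * state.mrna \
        - params.delta_prot * state.prot
    return dmrna, dprot


def mrna_equilibrium(params: ParameterSet, enzyme: Enzyme,
                     fc: FoldChanges = IDENTITY_FOLDS, sigma_l: float = 1.0,
                     fsh_gc: float = 0.0) -> float:
    """mRNA fixed point sigma_L * f * nu * (1 + kappa*FSH) / delta_mRNA."""
    folds = {Enzyme.CYP19: fc.f_cyp19, Enzyme.HSD17B1: fc.f_hsd17b1,
             Enzyme.HSD17B2: 1.0}
    synth = sigma_l * folds[enzyme] * params.nu_mrna[enzyme]
    if enzyme is not Enzyme.HSD17B2:
        synth *= 1.0 + params.kappa[enzyme] * fsh_gc
    return synth / params.delta_mrna
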