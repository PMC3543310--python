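"""Synthetic in vitro calibration datasets.

Generates data collections with exactly the statistical structure the
calibration assumes: a per-study multiplicative transcription random effect
sigma_L ~ LN(mu0, Sigma1), and lognormal measurement noise with log-scale SD
Sigma2 (mRNA/protein endpoints) or Sigma3 (hormone endpoints) around the
model predictions.  The default designs imitate the kind of endpoints the
in vitro literature provides: 4-h mRNA quantities and FSH-induction
fold-changes, 48-h protein quantities, and 48-h hormone accumulations in
the medium (with the tritiated-water aromatase readout), with and without
FSH at 20 ng/ml.

Identifiability caveat: with these endpoint sets the aromatase Km for T
(the competition-side constant) is only weakly informed and its posterior
stays close to the prior, mirroring its wide calibrated interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_calibration import (CalibrationDatum, Condition,
                                LikelihoodEvaluator, SampledParameterVector,
                                KINETIC_NAMES, parameter_names)
from .model_core import ParameterSet

_ENZ_NAMES = ("Cyp19", "Hsd17b1", "Hsd17b2")


@dataclass(frozen=True)
class StudyDesign:
    """Endpoints measured by one (synthetic) study.

    ``endpoints`` is a list of (endpoint_class, endpoint, Condition).
    Every design carries at least one unstimulated control condition or a
    fold-change endpoint (which embeds its own control).
    """

    study: int
    endpoints: tuple
    replicates: int = 3

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        has_control = any(
            (c.fsh_ng_ml == 0 and c.f_cyp19 == c.f_hsd17b1 == c.f_m == 1.0)
            or ep.startswith("mrna_fold_")
            for _cls, ep, c in self.endpoints)
        if not has_control:
            raise ValueError(f"study {self.study} lacks a control condition")


def default_designs(n_studies: int = 10, replicates: int = 3) -> list[StudyDesign]:
    """Ten studies mirroring the calibration corpus structure."""
    if n_studies < 2:
        raise ValueError("need at least two studies")
    c_ctrl4 = Condition(time_min=240.0)
    c_fsh4 = Condition(fsh_ng_ml=20.0, time_min=240.0)
    c_ctrl48 = Condition(time_min=2880.0)
    c_fsh48 = Condition(fsh_ng_ml=20.0, time_min=2880.0)
    c_horm = Condition(initial_a_nm=200.0, time_min=2880.0)
    c_horm_fsh = Condition(fsh_ng_ml=20.0, initial_a_nm=200.0, time_min=2880.0)

    def expression(s):
        eps = [("mrna_protein", f"mrna_{e}", c) for e in _ENZ_NAMES
               for c in (c_ctrl4, c_fsh4)]
        return StudyDesign(s, tuple(eps), replicates)

    def protein(s):
        eps = [("mrna_protein", f"prot_{e}", c) for e in _ENZ_NAMES
               for c in (c_ctrl48, c_fsh48)]
        return StudyDesign(s, tuple(eps), replicates)

    def fold(s):
        eps = [("mrna_protein", "mrna_fold_Cyp19", c_fsh4),
               ("mrna_protein", "mrna_fold_Hsd17b1", c_fsh4)]
        return StudyDesign(s, tuple(eps), replicates)

    def hormone(s, cond):
        eps = [("hormone", ep, cond)
               for ep in ("med_A", "med_T", "med_E1", "med_E2", "t2o")]
        # an unstimulated mRNA reading anchors the study's own sigma_L
        # without an extra hormone-condition simulation
        eps.append(("mrna_protein", "mrna_Cyp19", c_ctrl4))
        return StudyDesign(s, tuple(eps), replicates)

    makers = [expression, expression, expression, expression,
              protein, protein, fold, fold,
              lambda s: hormone(s, c_horm), lambda s: hormone(s, c_horm_fsh)]
    return [makers[(s - 1) % len(makers)](s) for s in range(1, n_studies + 1)]


def generate_study(truth: SampledParameterVector, params: ParameterSet,
                   design: StudyDesign, sigma_l: float,
                   rng: np.random.Generator,
                   cells_per_ml: float = 3.0e5,
                   medium_volume_ml: float = 2.0) -> list[CalibrationDatum]:
    """Simulate one study's endpoints and apply lognormal measurement noise.

    With Sigma2 = Sigma3 = 0 the data equal the noiseless model predictions.
    Deterministic given the generator state.
    """
    probe = [CalibrationDatum(design.study, cls, ep, c, 1.0)
             for cls, ep, c in design.endpoints]
    ev = LikelihoodEvaluator(probe, params, cells_per_ml, medium_volume_ml)
    gene_pred = ev.predict_gene(design.study, truth.kinetic, sigma_l)
    horm_cache = {cond: ev.predict_hormones(cond, truth.kinetic, sigma_l)
                  for cond, _slot in ev._horm[design.study]}
    out = []
    gi = 0
    for cls, ep, cond in design.endpoints:
        if ep in LikelihoodEvaluator._HORMONE_MAP:
            pred = horm_cache[cond][ep]
        else:
            pred = float(gene_pred[gi])
            gi += 1
        sd = truth.sigma3 if cls == "hormone" else truth.sigma2
        for _r in range(design.replicates):
            noise = np.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0
            out.append(CalibrationDatum(design.study, cls, ep, cond,
                                        float(pred * noise)))
    return out


def generate_collection(truth: SampledParameterVector, params: ParameterSet,
                        designs: list[StudyDesign] | None = None,
                        seed: int = 0,
                        cells_per_ml: float = 3.0e5,
                        medium_volume_ml: float = 2.0):
    """Generate a multi-study collection plus its sealed truth record.

    Study effects are drawn independently per study from LN(mu0, Sigma1).
    Returns (data, truth_record); the truth record holds everything needed
    to score parameter recovery, keyed by calibration parameter name.
    """
    designs = designs or default_designs()
    if len(designs) < 2:
        raise ValueError("need at least two studies")
    rng = np.random.default_rng(seed)
    sigma_l = np.exp(rng.normal(np.log(truth.mu0), truth.sigma1, len(designs)))
    data: list[CalibrationDatum] = []
    for d, sl in zip(designs, sigma_l):
        data.extend(generate_study(truth, params, d, float(sl), rng,
                                   cells_per_ml, medium_volume_ml))
    record = dict(zip(KINETIC_NAMES, (float(v) for v in truth.kinetic)))
    record.update({"mu0": truth.mu0, "sigma1": truth.sigma1,
                   "sigma2": truth.sigma2, "sigma3": truth.sigma3,
                   "seed": int(seed)})
    for i, sl in enumerate(sigma_l):
        record[f"sigma_l_{designs[i].study}"] = float(sl)
    return data, record


def truth_from_map(preset: dict) -> SampledParameterVector:
    """Build the generating truth from a calibrated preset's MAP column."""
    p = preset["parameters"]
    s = preset["statistical"]
    kin = np.array([
        p["kappa"]["Cyp19"], p["kappa"]["Hsd17b1"],
        p["lam"]["Cyp19,A"], p["lam"]["Cyp19,T"],
        p["lam"]["Hsd17b1,A"], p["lam"]["Hsd17b1,E1"],
        p["xi"]["Cyp19,A"], p["xi"]["Cyp19,T"],
        p["xi"]["Hsd17b1,A"], p["xi"]["Hsd17b1,E1"],
    ], dtype=float)
    return SampledParameterVector(
        kinetic=kin, mu0=float(s["mu0"]), sigma1=float(s["sigma1"]),
        sigma_l=np.asarray(s["sigma_l"], float),
        sigma2=float(s["sigma2"]), sigma3=float(s["sigma3"]))


# ---------------------------------------------------------------------------
# Tabular IO (matches the calibration data file format)
# ---------------------------------------------------------------------------

_COLUMNS = ["study", "endpoint_class", "endpoint", "fsh_ng_ml",
            "initial_A_nM", "time_min", "f_cyp19", "f_hsd17b1", "f_m", "value"]


def data_to_frame(data: list[CalibrationDatum]) -> pd.DataFrame:
    rows = [(d.study, d.endpoint_class, d.endpoint, d.condition.fsh_ng_ml,
             d.condition.initial_a_nm, d.condition.time_min,
             d.condition.f_cyp19, d.condition.f_hsd17b1, d.condition.f_m,
             d.value) for d in data]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_data(df: pd.DataFrame) -> list[CalibrationDatum]:
    out = []
    for row in df.itertuples(index=False):
        cond = Condition(fsh_ng_ml=float(row.fsh_ng_ml),
                         initial_a_nm=float(row.initial_A_nM),
                         time_min=float(row.time_min),
                         f_cyp19=float(row.f_cyp19),
                         f_hsd17b1=float(row.f_hsd17b1),
                         f_m=float(row.f_m))
        out.append(CalibrationDatum(int(row.study), str(row.endpoint_class),
                                    str(row.endpoint), cond, float(row.value)))
    return out
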