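"""Counterfactual treatment recommendation from a Cox log-risk model.

For a proportional-hazards model with arm-specific log-risk h_arm(x), the
log hazard ratio of arm i versus arm j for the same patient is

    rec_ij(x) = log( lambda(t; x, i) / lambda(t; x, j) ) = h_i(x) - h_j(x)

because the baseline hazard cancels. A positive rec_ij(x) means arm i
carries the higher death risk, so arm j is preferred; the recommended arm
is the one minimizing h_arm(x). Patients whose received therapy equals the
recommendation form the "recommended" group, the rest the
"anti-recommended" group, and the two groups are compared by Kaplan-Meier,
log-rank and a univariate Cox fit (anti-recommended as reference, so an
HR below 1 indicates the recommendations carry survival benefit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import RiskModel
from .survival import CoxFit, SurvivalCurve, cox_fit, km_estimate, logrank_test

__all__ = [
    "RecommendationResult",
    "RecommendationValidation",
    "rec_value",
    "rec_values",
    "recommend",
    "classify_concordance",
    "validate_recommendation",
]

log = logging.getLogger(__name__)


@dataclass
class RecommendationResult:
    """Per-patient counterfactual log-risks and the derived recommendation."""

    table: pd.DataFrame   # id, h_<arm>..., rec_<i>_vs_<j>..., recommended_arm,
                          # received_arm, concordant, tie_flag
    arms: tuple

    @property
    def concordant_fraction(self) -> float:
        return float(self.table["concordant"].mean())


@dataclass
class RecommendationValidation:
    curves: dict                  # group label -> SurvivalCurve
    logrank_p: float
    cox: CoxFit                   # recommended vs anti-recommended (reference)
    group_sizes: dict

    @property
    def hr(self) -> float:
        return float(self.cox.hr[0])

    @property
    def hr_ci95(self) -> tuple[float, float]:
        return float(self.cox.ci95[0, 0]), float(self.cox.ci95[0, 1])


def rec_values(model: RiskModel, df: pd.DataFrame, arm_i, arm_j) -> np.ndarray:
    """Vectorised rec_ij(x) = h_i(x) - h_j(x) over a cohort table."""
    return model.predict_for_arm(df, arm_i) - model.predict_for_arm(df, arm_j)


def rec_value(model: RiskModel, patient: pd.Series | pd.DataFrame, arm_i, arm_j) -> float:
    """rec_ij(x) for a single patient record."""
    row = patient.to_frame().T if isinstance(patient, pd.Series) else patient
    return float(rec_values(model, row, arm_i, arm_j)[0])


def recommend(model: RiskModel, patient: pd.Series | pd.DataFrame, arms) -> str:
    """The arm minimizing predicted log-risk (label-order tie-break)."""
    if len(arms) < 2:
        raise ValueError("need at least two arms to recommend among")
    row = patient.to_frame().T if isinstance(patient, pd.Series) else patient
    arms = sorted(arms)
    h = np.array([model.predict_for_arm(row, a)[0] for a in arms])
    return arms[int(np.argmin(h))]


def classify_concordance(
    model: RiskModel,
    df: pd.DataFrame,
    arms,
    received: np.ndarray | pd.Series | None = None,
) -> RecommendationResult:
    """Label every patient recommended (concordant) or anti-recommended.

    ``received`` defaults to the cohort's ``arm`` column; for cascaded
    models whose arms are derived labels (e.g. surgery / no-surgery), pass
    the mapped labels explicitly.
    """
    arms = tuple(sorted(arms))
    received = df["arm"] if received is None else received
    received = np.asarray(received, dtype=object)
    unknown = ~np.isin(received, arms)
    if unknown.any():
        raise ValueError(
            f"received arm(s) {sorted(set(received[unknown]))} outside {arms}"
        )
    h = {a: model.predict_for_arm(df, a) for a in arms}
    stacked = np.column_stack([h[a] for a in arms])
    best_idx = np.argmin(stacked, axis=1)
    recommended = np.asarray(arms, dtype=object)[best_idx]
    sorted_h = np.sort(stacked, axis=1)
    tie_flag = sorted_h[:, 0] == sorted_h[:, 1]

    out = pd.DataFrame({"id": df["id"].to_numpy()})
    for a in arms:
        out[f"h_{a}"] = h[a]
    for i, ai in enumerate(arms):
        for aj in arms[i + 1:]:
            out[f"rec_{ai}_vs_{aj}"] = h[ai] - h[aj]
    out["recommended_arm"] = recommended
    out["received_arm"] = received
    out["concordant"] = (recommended == received).astype(int)
    out["tie_flag"] = tie_flag.astype(int)
    n_tie = int(tie_flag.sum())
    if n_tie:
        log.info("%d patients have exactly tied log-risks; tie-broken by label order", n_tie)
    return RecommendationResult(table=out, arms=arms)


def validate_recommendation(
    result: RecommendationResult,
    times,
    events,
    adjust_design: np.ndarray | None = None,
) -> RecommendationValidation:
    """Survival comparison of the recommended vs anti-recommended groups.

    The default Cox fit is unadjusted (group membership only); pass a
    covariate design matrix via ``adjust_design`` for an adjusted hazard
    ratio. The reported HR is always the group term's.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    conc = result.table["concordant"].to_numpy().astype(bool)
    sizes = {"recommended": int(conc.sum()), "anti-recommended": int((~conc).sum())}
    if min(sizes.values()) == 0:
        log.warning("one recommendation group is empty; validation skipped")
        raise ValueError("both recommendation groups must be non-empty")
    curves = {
        "recommended": km_estimate(t[conc], e[conc]),
        "anti-recommended": km_estimate(t[~conc], e[~conc]),
    }
    lr = logrank_test(t, e, np.where(conc, "recommended", "anti-recommended"))
    design = conc.astype(float)[:, None]
    terms = ["recommended"]
    if adjust_design is not None:
        extra = np.atleast_2d(np.asarray(adjust_design, float))
        design = np.column_stack([design, extra])
        terms = terms + [f"adj{j}" for j in range(extra.shape[1])]
    fit = cox_fit(design, t, e, terms=terms)
    return RecommendationValidation(
        curves=curves, logrank_p=lr.p, cox=fit, group_sizes=sizes
    )
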