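"""Synthetic registry-style cohorts of de novo metastatic breast cancer (dnMBC).

The real study population this emulates is a cancer-registry cohort of women
whose breast cancer is metastatic at first diagnosis, treated with one of
three strategies:

* ``CW`` — chemotherapy without surgery,
* ``NS`` — neoadjuvant systemic therapy followed by surgery,
* ``SC`` — surgery followed by chemotherapy.

The generator draws categorical covariates from stated marginals, assigns a
treatment arm from a covariate-dependent multinomial logit (so arms are
confounded, as in observational registry data), and draws event times from a
proportional-hazards model

    lambda(t; x, arm) = lambda0(t) * exp(h_arm(x)),
    h_arm(x) = beta_treatment[arm] + sum_f beta_main[f, x_f]
               + sum_f beta_interaction[arm, f, x_f]

with a Weibull (or exponential) baseline, independent exponential
loss-to-follow-up, and administrative censoring at a follow-up horizon with
an optional uniform accrual offset. Because every record carries its true
log-risk under *each* arm, downstream estimators and recommenders can be
validated against ground truth.

Randomness: one ``numpy`` Generator per cohort, consumed in a fixed field
order — covariates (factor by factor), arm, event time, dropout, accrual
offset, cause of death — so that adding fields later cannot silently shift
existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CovariateScheme",
    "HazardSpec",
    "AssignmentSpec",
    "CohortTable",
    "generate_cohort",
    "true_log_risk",
    "true_optimal_arm",
    "true_optimal_arms",
    "write_cohort",
    "read_cohort",
    "default_scenario",
    "null_scenario",
    "recovery_scenario",
]

TREATMENT_LEVELS = ("CW", "NS", "SC")

_RESERVED_COLUMNS = {"id", "arm", "time_months", "event_os", "event_bcss"}


class CohortSchemaError(ValueError):
    """A cohort file or table violates the declared schema."""


@dataclass(frozen=True)
class CovariateScheme:
    """Covariate vocabulary: ordered factors with level labels and marginals."""

    factors: tuple[tuple[str, tuple[str, ...], tuple[float, ...]], ...]
    treatment_levels: tuple[str, ...] = TREATMENT_LEVELS

    def __post_init__(self) -> None:
        if len(self.treatment_levels) != 3:
            raise ValueError("exactly 3 treatment levels required")
        for name, levels, probs in self.factors:
            if len(levels) != len(set(levels)):
                raise ValueError(f"duplicate level labels in factor {name!r}")
            if len(levels) != len(probs):
                raise ValueError(f"levels/probabilities length mismatch in {name!r}")
            p = np.asarray(probs, dtype=float)
            if (p < 0).any():
                raise ValueError(f"negative marginal probability in {name!r}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"marginals of {name!r} sum to {p.sum()}, not 1")
            if name in _RESERVED_COLUMNS:
                raise ValueError(f"factor name {name!r} collides with a reserved column")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.factors)

    def levels(self, factor: str) -> tuple[str, ...]:
        for name, levels, _ in self.factors:
            if name == factor:
                return levels
        raise KeyError(factor)


@dataclass(frozen=True)
class HazardSpec:
    """Proportional-hazards event model with censoring.

    ``baseline_family`` is ``"exponential"`` (rate per month) or ``"weibull"``
    (shape, scale in months). Coefficients are keyed ``(factor, level)`` for
    main effects, ``arm`` for treatment and ``(arm, factor, level)`` for
    interactions; reference levels simply carry no key (coefficient 0).
    """

    baseline_family: str = "exponential"
    baseline_rate: float = 0.02           # exponential: events per month
    baseline_shape: float = 1.0           # weibull shape k
    baseline_scale: float = 50.0          # weibull scale (months)
    beta_main: dict = field(default_factory=dict)
    beta_treatment: dict = field(default_factory=dict)
    beta_interaction: dict = field(default_factory=dict)
    bcss_fraction: float = 0.85
    admin_censor_months: float = 120.0
    accrual_months: float = 0.0           # uniform accrual window before the horizon
    dropout_rate: float = 0.0             # exponential loss-to-follow-up per month

    def __post_init__(self) -> None:
        if self.baseline_family not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline family {self.baseline_family!r}")
        if self.baseline_family == "exponential" and self.baseline_rate <= 0:
            raise ValueError("exponential baseline rate must be > 0")
        if self.baseline_family == "weibull" and (
            self.baseline_shape <= 0 or self.baseline_scale <= 0
        ):
            raise ValueError("weibull shape and scale must be > 0")
        if not 0.0 <= self.bcss_fraction <= 1.0:
            raise ValueError("bcss_fraction must lie in [0, 1]")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be > 0")
        if self.accrual_months < 0 or self.accrual_months > self.admin_censor_months:
            raise ValueError("accrual_months must lie in [0, admin_censor_months]")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")

    def validate_against(self, scheme: CovariateScheme) -> None:
        for (factor, level) in self.beta_main:
            if level not in scheme.levels(factor):
                raise KeyError(f"unknown level {level!r} of factor {factor!r} in beta_main")
        for arm in self.beta_treatment:
            if arm not in scheme.treatment_levels:
                raise KeyError(f"unknown arm {arm!r} in beta_treatment")
        for (arm, factor, level) in self.beta_interaction:
            if arm not in scheme.treatment_levels:
                raise KeyError(f"unknown arm {arm!r} in beta_interaction")
            if level not in scheme.levels(factor):
                raise KeyError(
                    f"unknown level {level!r} of factor {factor!r} in beta_interaction"
                )


@dataclass(frozen=True)
class AssignmentSpec:
    """Multinomial-logit treatment assignment.

    ``intercepts[arm]`` and ``gamma[(arm, factor, level)]`` are logit
    coefficients relative to the reference arm (all-zero, conventionally CW).
    """

    intercepts: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)
    reference_arm: str = "CW"

    def validate_against(self, scheme: CovariateScheme) -> None:
        if self.reference_arm not in scheme.treatment_levels:
            raise KeyError(f"reference arm {self.reference_arm!r} not a treatment level")
        for arm in self.intercepts:
            if arm not in scheme.treatment_levels:
                raise KeyError(f"unknown arm {arm!r} in intercepts")
        for (arm, factor, level) in self.gamma:
            if arm not in scheme.treatment_levels:
                raise KeyError(f"unknown arm {arm!r} in gamma")
            if level not in scheme.levels(factor):
                raise KeyError(f"unknown level {level!r} of factor {factor!r} in gamma")


@dataclass
class CohortTable:
    """A generated (or loaded) cohort: one row per patient."""

    scheme: CovariateScheme
    df: pd.DataFrame
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def oracle_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("true_log_risk_")]

    def validate(self) -> None:
        df = self.df
        required = ["id", "arm", "time_months", "event_os", "event_bcss"]
        for col in required + list(self.scheme.factor_names):
            if col not in df.columns:
                raise CohortSchemaError(f"missing column {col!r}")
        known = set(required) | set(self.scheme.factor_names) | {
            f"true_log_risk_{a}" for a in self.scheme.treatment_levels
        } | {"triplet_id"}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise CohortSchemaError(f"unknown columns {unknown}")
        if df["id"].duplicated().any():
            raise CohortSchemaError("duplicate patient ids")
        if (df["time_months"] <= 0).any():
            raise CohortSchemaError("time_months must be > 0 for every patient")
        if ((df["event_bcss"] == 1) & (df["event_os"] == 0)).any():
            raise CohortSchemaError("event_bcss=1 requires event_os=1")
        bad_arm = ~df["arm"].isin(self.scheme.treatment_levels)
        if bad_arm.any():
            raise CohortSchemaError(f"unknown arm labels {sorted(df.loc[bad_arm, 'arm'].unique())}")
        for name, levels, _ in self.scheme.factors:
            bad = ~df[name].isin(levels)
            if bad.any():
                raise CohortSchemaError(
                    f"unknown levels {sorted(df.loc[bad, name].unique())} in factor {name!r}"
                )


def _baseline_inverse_cumhaz(hazard: HazardSpec, u: np.ndarray, log_risk: np.ndarray) -> np.ndarray:
    """Event times by inverse-CDF: S(t|h) = exp(-H0(t) e^h) with U ~ Uniform(0,1)."""
    target = -np.log(u) / np.exp(log_risk)  # required baseline cumulative hazard
    if hazard.baseline_family == "exponential":
        return target / hazard.baseline_rate
    k, s = hazard.baseline_shape, hazard.baseline_scale
    return s * target ** (1.0 / k)


def true_log_risk(
    scheme: CovariateScheme, hazard: HazardSpec, covariates: pd.DataFrame, arm: str
) -> np.ndarray:
    """Ground-truth log-risk h_arm(x) for each row of ``covariates``."""
    h = np.full(len(covariates), hazard.beta_treatment.get(arm, 0.0), dtype=float)
    for name in scheme.factor_names:
        col = covariates[name].to_numpy()
        for level in scheme.levels(name):
            b = hazard.beta_main.get((name, level), 0.0)
            b += hazard.beta_interaction.get((arm, name, level), 0.0)
            if b != 0.0:
                h[col == level] += b
    return h


def generate_cohort(
    scheme: CovariateScheme,
    hazard: HazardSpec,
    assign: AssignmentSpec,
    n: int,
    seed: int,
) -> CohortTable:
    """Draw a cohort of ``n`` patients; bit-reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    hazard.validate_against(scheme)
    assign.validate_against(scheme)
    rng = np.random.default_rng(seed)

    # 1. covariates, one draw per factor in scheme order
    data: dict[str, np.ndarray] = {}
    for name, levels, probs in scheme.factors:
        idx = rng.choice(len(levels), size=n, p=np.asarray(probs, float))
        data[name] = np.asarray(levels, dtype=object)[idx]
    cov = pd.DataFrame(data)

    # 2. treatment arm via multinomial logit
    arms = scheme.treatment_levels
    logits = np.zeros((n, len(arms)))
    for j, arm in enumerate(arms):
        if arm == assign.reference_arm:
            continue
        logits[:, j] += assign.intercepts.get(arm, 0.0)
        for name in scheme.factor_names:
            col = cov[name].to_numpy()
            for level in scheme.levels(name):
                g = assign.gamma.get((arm, name, level), 0.0)
                if g != 0.0:
                    logits[col == level, j] += g
    expl = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs_arm = expl / expl.sum(axis=1, keepdims=True)
    u_arm = rng.random(n)
    arm_idx = (probs_arm.cumsum(axis=1) < u_arm[:, None]).sum(axis=1)
    arm_col = np.asarray(arms, dtype=object)[arm_idx]

    # ground-truth log-risks under every arm (no randomness consumed)
    lr = {arm: true_log_risk(scheme, hazard, cov, arm) for arm in arms}
    h_received = np.choose(arm_idx, [lr[a] for a in arms])

    # 3. event time, 4. dropout, 5. accrual offset, 6. cause of death
    u_event = rng.random(n)
    raw_event = _baseline_inverse_cumhaz(hazard, u_event, h_received)
    if hazard.dropout_rate > 0:
        raw_dropout = rng.exponential(1.0 / hazard.dropout_rate, size=n)
    else:
        rng.random(n)  # keep the stream layout fixed
        raw_dropout = np.full(n, np.inf)
    if hazard.accrual_months > 0:
        admin = hazard.admin_censor_months - rng.random(n) * hazard.accrual_months
    else:
        rng.random(n)
        admin = np.full(n, hazard.admin_censor_months)
    u_cause = rng.random(n)

    observed = np.minimum(np.minimum(raw_event, raw_dropout), admin)
    event_os = (raw_event <= np.minimum(raw_dropout, admin)).astype(np.int64)
    event_bcss = (event_os == 1) & (u_cause < hazard.bcss_fraction)
    time_months = np.maximum(np.ceil(observed), 1.0).astype(np.int64)

    df = pd.DataFrame({"id": np.arange(n, dtype=np.int64)})
    for name in scheme.factor_names:
        df[name] = cov[name]
    df["arm"] = arm_col
    df["time_months"] = time_months
    df["event_os"] = event_os
    df["event_bcss"] = event_bcss.astype(np.int64)
    for arm in arms:
        df[f"true_log_risk_{arm}"] = lr[arm]

    cohort = CohortTable(scheme=scheme, df=df, seed=seed)
    cohort.validate()
    return cohort


def true_optimal_arm(record: pd.Series | dict, arms: tuple[str, ...] | list[str]) -> str:
    """Arm with minimal true log-risk among ``arms``; label-order tie-break."""
    arms = sorted(arms)
    values = []
    for arm in arms:
        key = f"true_log_risk_{arm}"
        if key not in record or record[key] is None or (
            isinstance(record[key], float) and math.isnan(record[key])
        ):
            raise KeyError(f"record has no ground-truth log-risk for arm {arm!r}")
        values.append(record[key])
    return arms[int(np.argmin(values))]


def true_optimal_arms(df: pd.DataFrame, arms: tuple[str, ...] | list[str]) -> np.ndarray:
    """Vectorised :func:`true_optimal_arm` over a cohort table."""
    arms = sorted(arms)
    cols = []
    for arm in arms:
        key = f"true_log_risk_{arm}"
        if key not in df.columns:
            raise KeyError(f"cohort has no ground-truth log-risk column for arm {arm!r}")
        cols.append(df[key].to_numpy(float))
    stacked = np.column_stack(cols)
    if np.isnan(stacked).any():
        raise KeyError("ground-truth log-risk contains missing values")
    return np.asarray(arms, dtype=object)[np.argmin(stacked, axis=1)]


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort as UTF-8 CSV with a header row."""
    cohort.validate()
    cohort.df.to_csv(path, index=False)


def read_cohort(path, scheme: CovariateScheme | None = None) -> CohortTable:
    """Read a cohort CSV; oracle columns are optional, unknown columns are errors.

    When no scheme is given, factors are inferred from the non-reserved
    columns with empirical level frequencies as marginals.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise CohortSchemaError(f"malformed cohort file {path}: {exc}") from exc
    for col in ("id", "arm", "time_months", "event_os", "event_bcss"):
        if col not in df.columns:
            raise CohortSchemaError(f"malformed cohort file: missing column {col!r}")
    if scheme is None:
        arms = tuple(sorted(df["arm"].unique()))
        if len(arms) != 3:
            arms = TREATMENT_LEVELS
        factors = []
        for col in df.columns:
            if col in _RESERVED_COLUMNS or col.startswith("true_log_risk_") or col == "triplet_id":
                continue
            counts = df[col].astype(str).value_counts(normalize=True).sort_index()
            factors.append((col, tuple(counts.index), tuple(counts.to_numpy())))
        scheme = CovariateScheme(factors=tuple(factors), treatment_levels=arms)
    cohort = CohortTable(scheme=scheme, df=df)
    cohort.validate()
    return cohort


# --------------------------------------------------------------------------
# Named scenarios.  These parameter sets define the study conditions the
# test-suite and the acceptance runs operate under; they are fixed design
# choices of the package, not tuning knobs.
# --------------------------------------------------------------------------

def _default_scheme() -> CovariateScheme:
    return CovariateScheme(
        factors=(
            ("age_group", ("<40", "40-49", "50-59", "60-69", "70-79", "80+"),
             (0.10, 0.20, 0.26, 0.26, 0.14, 0.04)),
            ("subtype", ("HR+/HER2-", "HR+/HER2+", "HR-/HER2+", "HR-/HER2-"),
             (0.48, 0.19, 0.11, 0.22)),
            ("race", ("White", "Black", "Other"), (0.72, 0.18, 0.10)),
            ("histology", ("IDC", "ILC", "Mixed", "Other"), (0.75, 0.08, 0.05, 0.12)),
            ("grade", ("I", "II", "III/IV"), (0.06, 0.38, 0.56)),
            ("t_stage", ("T1", "T2", "T3", "T4"), (0.15, 0.35, 0.22, 0.28)),
            ("n_stage", ("N0", "N1", "N2", "N3"), (0.25, 0.45, 0.12, 0.18)),
            ("marital", ("Married", "Unmarried"), (0.55, 0.45)),
            ("income", ("<50k", "50-60k", "60-70k", ">=70k"), (0.25, 0.25, 0.25, 0.25)),
            ("metastases", ("Bone only", "Liver only", "Lung only", "Brain", "Multiple", "Other"),
             (0.32, 0.08, 0.09, 0.05, 0.30, 0.16)),
        ),
    )


def _default_beta_main() -> dict:
    return {
        ("age_group", "40-49"): 0.05,
        ("age_group", "50-59"): 0.25,
        ("age_group", "60-69"): 0.34,
        ("age_group", "70-79"): 0.47,
        ("age_group", "80+"): 0.85,
        ("subtype", "HR+/HER2+"): -0.40,
        ("subtype", "HR-/HER2+"): -0.20,
        ("subtype", "HR-/HER2-"): 0.95,
        ("race", "Black"): 0.25,
        ("race", "Other"): -0.02,
        ("histology", "Other"): 0.20,
        ("grade", "II"): 0.20,
        ("grade", "III/IV"): 0.52,
        ("t_stage", "T2"): 0.10,
        ("t_stage", "T3"): 0.22,
        ("t_stage", "T4"): 0.34,
        ("marital", "Unmarried"): 0.13,
        ("income", "60-70k"): -0.11,
        ("income", ">=70k"): -0.25,
        ("metastases", "Liver only"): 0.28,
        ("metastases", "Lung only"): 0.04,
        ("metastases", "Brain"): 0.85,
        ("metastases", "Multiple"): 0.70,
        ("metastases", "Other"): 0.30,
    }


def _default_assignment() -> AssignmentSpec:
    # CW is the bulk arm (~3/4), NS/SC each ~1/8; NS skews young / high-T /
    # HER2+, SC skews low-income / lower-T, CW takes the complex metastatic
    # presentations — the qualitative imbalance pattern of the registry.
    return AssignmentSpec(
        intercepts={"NS": -2.25, "SC": -1.9},
        gamma={
            ("NS", "age_group", "70-79"): -0.45,
            ("NS", "age_group", "80+"): -1.40,
            ("NS", "t_stage", "T3"): 0.45,
            ("NS", "t_stage", "T4"): 0.55,
            ("NS", "subtype", "HR+/HER2+"): 0.45,
            ("NS", "subtype", "HR-/HER2+"): 0.45,
            ("SC", "income", "<50k"): 0.40,
            ("SC", "t_stage", "T3"): -0.30,
            ("SC", "t_stage", "T4"): -0.50,
            ("NS", "metastases", "Bone only"): 0.45,
            ("NS", "metastases", "Liver only"): 0.40,
            ("NS", "metastases", "Lung only"): 0.40,
            ("SC", "metastases", "Bone only"): 0.40,
            ("SC", "metastases", "Liver only"): 0.40,
            ("SC", "metastases", "Lung only"): 0.35,
        },
    )


def default_scenario() -> tuple[CovariateScheme, HazardSpec, AssignmentSpec]:
    """Registry-like scenario with heterogeneous treatment effects.

    Surgery (NS/SC) is protective on average (log-HR -0.69 and -0.43 vs CW)
    but not universally: for patients aged 80+ or with well-differentiated
    (grade I) tumours the interactions overshoot the main effects, making
    surgery clearly harmful; for brain metastases they exactly cancel them,
    so no strategy is truly better in that stratum. Sequencing also matters:
    SC loses part of its benefit for T3/T4 and grade III/IV disease, where
    neoadjuvant-first is the stronger option.
    """
    scheme = _default_scheme()
    hazard = HazardSpec(
        baseline_family="weibull",
        baseline_shape=1.1,
        baseline_scale=120.0,
        beta_main=_default_beta_main(),
        beta_treatment={"NS": -0.69, "SC": -0.43},
        beta_interaction={
            # surgery clearly harmful for the very old and for indolent disease
            ("NS", "age_group", "80+"): 1.25,
            ("SC", "age_group", "80+"): 1.00,
            ("NS", "grade", "I"): 1.15,
            ("SC", "grade", "I"): 0.95,
            # brain metastases: benefit exactly cancelled (true null stratum)
            ("NS", "metastases", "Brain"): 0.69,
            ("SC", "metastases", "Brain"): 0.43,
            # surgery-first loses ground in locally advanced / aggressive disease
            ("SC", "t_stage", "T3"): 0.30,
            ("SC", "t_stage", "T4"): 0.40,
            ("SC", "grade", "III/IV"): 0.20,
        },
        bcss_fraction=0.85,
        admin_censor_months=120.0,
        accrual_months=120.0,
        dropout_rate=0.002,
    )
    return scheme, hazard, _default_assignment()


def null_scenario() -> tuple[CovariateScheme, HazardSpec, AssignmentSpec]:
    """Calibration null: no treatment effects and neutral, balanced assignment.

    Covariate main effects are kept, but treatment carries no effect and the
    arm is assigned independently of covariates with P(CW) = 1/2 and
    P(NS) = P(SC) = 1/4, i.e. surgery and no-surgery equally likely. Under
    covariate-dependent assignment an *unadjusted* recommended-vs-anti
    survival comparison is confounded even when treatment does nothing, so
    a neutral assignment is required for the comparison to be truly null;
    see the methods note.
    """
    scheme, hazard, _ = default_scenario()
    hazard = replace(hazard, beta_treatment={}, beta_interaction={})
    assign = AssignmentSpec(intercepts={"NS": -math.log(2.0), "SC": -math.log(2.0)})
    return scheme, hazard, assign


def recovery_scenario() -> tuple[CovariateScheme, HazardSpec, AssignmentSpec]:
    """Compact interaction-free scenario for coefficient-recovery checks.

    A main-effects Cox model is correctly specified here, so the fitted
    coefficients estimate exactly the generating ones.
    """
    scheme = CovariateScheme(
        factors=(
            ("subtype", ("HR+/HER2-", "HR+/HER2+", "HR-/HER2+", "HR-/HER2-"),
             (0.48, 0.19, 0.11, 0.22)),
            ("grade", ("I", "II", "III/IV"), (0.10, 0.40, 0.50)),
            ("t_stage", ("T1", "T2", "T3", "T4"), (0.15, 0.35, 0.22, 0.28)),
            ("metastases", ("Bone only", "Visceral", "Brain"), (0.45, 0.45, 0.10)),
        ),
    )
    hazard = HazardSpec(
        baseline_family="exponential",
        baseline_rate=0.02,
        beta_main={
            ("subtype", "HR+/HER2+"): -0.40,
            ("subtype", "HR-/HER2+"): -0.20,
            ("subtype", "HR-/HER2-"): 0.95,
            ("grade", "II"): 0.20,
            ("grade", "III/IV"): 0.52,
            ("t_stage", "T2"): 0.10,
            ("t_stage", "T3"): 0.22,
            ("t_stage", "T4"): 0.34,
            ("metastases", "Visceral"): 0.45,
            ("metastases", "Brain"): 0.90,
        },
        beta_treatment={"NS": -0.69, "SC": -0.43},
        bcss_fraction=0.85,
        admin_censor_months=120.0,
        accrual_months=0.0,
        dropout_rate=0.002,
    )
    assign = AssignmentSpec(
        intercepts={"NS": -1.1, "SC": -1.1},
        gamma={
            ("NS", "t_stage", "T3"): 0.4,
            ("NS", "t_stage", "T4"): 0.5,
            ("SC", "grade", "I"): 0.3,
        },
    )
    return scheme, hazard, assign
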