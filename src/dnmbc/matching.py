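"""Propensity-score estimation and 1:1:2 three-arm matching.

The design mirrors a registry comparison of three treatment strategies in
which arms are matched 1 (NS) : 1 (SC) : 2 (CW) by nearest-neighbour
matching without replacement on the logit of the propensity score, with a
caliper expressed in standard deviations of that logit.

Because three-group matching has no single canonical algorithm, matching is
sequential and two-stage:

1. each NS subject is matched to its nearest unused SC subject on the
   NS-vs-SC propensity logit;
2. each surviving (NS, SC) pair is matched to its two nearest unused CW
   subjects on the surgery-vs-CW propensity logit, the pair represented by
   the logit of its NS member; pairs that cannot find two CW subjects
   within the caliper are dropped entirely.

Subjects are processed hardest-first (descending logit); the seed only
breaks exact distance ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .cohort import CohortTable

__all__ = [
    "PropensityFit",
    "MatchResult",
    "BalanceReport",
    "estimate_propensity",
    "match_112",
    "matched_cohort",
    "balance_check",
]

log = logging.getLogger(__name__)

_CLIP = 1e-6


@dataclass
class PropensityFit:
    terms: list[str]
    coef: np.ndarray            # includes intercept first
    ids: np.ndarray             # subject ids, both arms
    scores: np.ndarray          # P(treated | x), clipped to (0, 1)
    logit_scores: np.ndarray
    separation: bool = False


@dataclass
class MatchResult:
    triplets: list[tuple]       # (ns_id, sc_id, cw_id, cw_id)
    unmatched: dict             # arm -> list of ids
    caliper_used: dict          # stage -> caliper on the logit scale

    @property
    def n_triplets(self) -> int:
        return len(self.triplets)

    def matched_ids(self) -> set:
        out: set = set()
        for tr in self.triplets:
            out.update(tr)
        return out


@dataclass
class BalanceReport:
    table: pd.DataFrame         # columns: factor, p, test, max_smd

    @property
    def min_p(self) -> float:
        return float(self.table["p"].min()) if len(self.table) else 1.0


def _one_hot(
    df: pd.DataFrame, factors, scheme, level_merge: dict | None = None
) -> tuple[np.ndarray, list[str]]:
    """Full-rank one-hot (first level of each factor is the reference).

    ``level_merge`` maps ``(factor, level) -> merged label`` so levels with
    similar prognosis can be pooled before the propensity model is fit.
    """
    level_merge = level_merge or {}
    cols, names = [], []
    for f in factors:
        raw_levels = scheme.levels(f)
        mapping = {lv: level_merge.get((f, lv), lv) for lv in raw_levels}
        levels = list(dict.fromkeys(mapping.values()))  # keep first-seen order
        vals = np.asarray([mapping[v] for v in df[f]], dtype=object)
        for level in levels[1:]:
            cols.append((vals == level).astype(float))
            names.append(f"{f}={level}")
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names


def estimate_propensity(
    cohort: CohortTable,
    treated_label,
    control_label,
    covariates: list[str] | None = None,
    level_merge: dict | None = None,
) -> PropensityFit:
    """Logistic propensity model for membership in ``treated_label``.

    ``treated_label`` / ``control_label`` may be a single arm or a tuple of
    arms pooled together (e.g. ``("NS", "SC")`` for surgery-vs-CW).
    """
    df = cohort.df
    scheme = cohort.scheme
    if covariates is None:
        covariates = list(scheme.factor_names)
    treated = (treated_label,) if isinstance(treated_label, str) else tuple(treated_label)
    control = (control_label,) if isinstance(control_label, str) else tuple(control_label)
    for arm in treated + control:
        if not (df["arm"] == arm).any():
            raise ValueError(f"arm {arm!r} absent from cohort")

    sub = df[df["arm"].isin(treated + control)]
    y = sub["arm"].isin(treated).to_numpy(int)
    x, names = _one_hot(sub, covariates, scheme, level_merge)
    keep = [j for j in range(x.shape[1]) if x[:, j].std() > 0]
    x = x[:, keep]
    names = [names[j] for j in keep]

    if x.shape[1] == 0:
        p0 = y.mean()
        scores = np.full(len(sub), p0)
        coef = np.array([np.log(p0 / (1 - p0))])
    else:
        model = LogisticRegression(
            C=np.inf, solver="newton-cholesky", tol=1e-8, max_iter=50
        )
        model.fit(x, y)
        coef = np.r_[model.intercept_, model.coef_.ravel()]
        scores = model.predict_proba(x)[:, 1]

    separation = bool((scores <= _CLIP).any() or (scores >= 1 - _CLIP).any())
    if separation:
        log.warning("propensity model near-separated; clipping fitted probabilities")
    scores = np.clip(scores, _CLIP, 1 - _CLIP)
    return PropensityFit(
        terms=["(intercept)"] + names,
        coef=coef,
        ids=sub["id"].to_numpy(),
        scores=scores,
        logit_scores=np.log(scores / (1 - scores)),
        separation=separation,
    )


def _greedy_match(
    need_logits: np.ndarray,
    pool_logits: np.ndarray,
    caliper: float,
    k: int,
    tie_rand_pool: np.ndarray,
    order: np.ndarray | None = None,
) -> list[list[int] | None]:
    """Greedy nearest-neighbour: for each 'need' row (processed in descending
    logit order unless an explicit order is given) pick its k nearest unused
    pool rows within the caliper. Returns pool index lists aligned with the
    original 'need' order."""
    if order is None:
        order = np.argsort(-need_logits, kind="stable")
    used = np.zeros(pool_logits.size, dtype=bool)
    out: list[list[int] | None] = [None] * need_logits.size
    for i in order:
        dist = np.abs(pool_logits - need_logits[i])
        dist[used] = np.inf
        cand = np.flatnonzero(dist <= caliper)
        if cand.size < k:
            continue
        # nearest first; exact distance ties broken by the seeded jitter
        sel = cand[np.lexsort((tie_rand_pool[cand], dist[cand]))[:k]]
        used[sel] = True
        out[i] = list(sel)
    return out


def match_112(
    cohort: CohortTable,
    covariates: list[str] | None = None,
    caliper_sd: float = 0.05,
    seed: int = 0,
    caliper_scale: str = "sd",
    greedy_order: str = "descending",
    level_merge: dict | None = None,
) -> MatchResult:
    """1:1:2 (NS : SC : CW) nearest-neighbour matching without replacement.

    ``caliper_sd`` is interpreted in standard deviations of each stage's
    logit scores (``caliper_scale="absolute"`` switches to raw logit units).
    ``greedy_order`` is ``"descending"`` (hardest-to-match first) or
    ``"random"`` (seeded). ``level_merge`` pools covariate levels with
    similar prognosis before the propensity models are fit.
    """
    if caliper_scale not in ("sd", "absolute"):
        raise ValueError(f"unknown caliper scale {caliper_scale!r}")
    if greedy_order not in ("descending", "random"):
        raise ValueError(f"unknown greedy order {greedy_order!r}")
    df = cohort.df
    for arm in cohort.scheme.treatment_levels:
        if not (df["arm"] == arm).any():
            raise ValueError(f"arm {arm!r} is empty")
    rng = np.random.default_rng(seed)

    # stage 1: NS vs SC
    fit1 = estimate_propensity(cohort, "NS", "SC", covariates, level_merge)
    is_ns = df.set_index("id").loc[fit1.ids, "arm"].to_numpy() == "NS"
    ns_ids, ns_logit = fit1.ids[is_ns], fit1.logit_scores[is_ns]
    sc_ids, sc_logit = fit1.ids[~is_ns], fit1.logit_scores[~is_ns]
    sd1 = fit1.logit_scores.std()
    cal1 = caliper_sd * sd1 if caliper_scale == "sd" else caliper_sd
    tie1 = rng.random(sc_ids.size)
    order1 = rng.permutation(ns_ids.size) if greedy_order == "random" else None
    stage1 = _greedy_match(ns_logit, sc_logit, cal1, 1, tie1, order1)
    pairs = [(ns_ids[i], sc_ids[m[0]]) for i, m in enumerate(stage1) if m is not None]

    # stage 2: (NS, SC) pair vs 2x CW, pair represented by its NS member
    fit2 = estimate_propensity(cohort, ("NS", "SC"), "CW", covariates, level_merge)
    logit2 = dict(zip(fit2.ids.tolist(), fit2.logit_scores.tolist()))
    cw_mask = df.set_index("id").loc[fit2.ids, "arm"].to_numpy() == "CW"
    cw_ids = fit2.ids[cw_mask]
    cw_logit = fit2.logit_scores[cw_mask]
    sd2 = fit2.logit_scores.std()
    cal2 = caliper_sd * sd2 if caliper_scale == "sd" else caliper_sd
    pair_logit = np.array([logit2[ns] for ns, _ in pairs]) if pairs else np.empty(0)
    tie2 = rng.random(cw_ids.size)
    order2 = rng.permutation(pair_logit.size) if greedy_order == "random" else None
    stage2 = _greedy_match(pair_logit, cw_logit, cal2, 2, tie2, order2)

    triplets = []
    matched_ns, matched_sc = set(), set()
    for (ns, sc), m in zip(pairs, stage2):
        if m is None:
            continue
        triplets.append((ns, sc, cw_ids[m[0]], cw_ids[m[1]]))
        matched_ns.add(ns)
        matched_sc.add(sc)
    used_cw = {cw for tr in triplets for cw in tr[2:]}
    unmatched = {
        "NS": sorted(set(ns_ids.tolist()) - matched_ns),
        "SC": sorted(set(sc_ids.tolist()) - matched_sc),
        "CW": sorted(set(cw_ids.tolist()) - used_cw),
    }
    if not triplets:
        log.warning("caliper %.4g produced zero complete triplets", caliper_sd)
    return MatchResult(
        triplets=triplets,
        unmatched=unmatched,
        caliper_used={"stage1": float(cal1), "stage2": float(cal2)},
    )


def matched_cohort(cohort: CohortTable, result: MatchResult) -> CohortTable:
    """Restrict the cohort to matched subjects, adding a ``triplet_id`` column."""
    rows = []
    for k, tr in enumerate(result.triplets):
        for pid in tr:
            rows.append((pid, k))
    key = pd.DataFrame(rows, columns=["id", "triplet_id"])
    df = cohort.df.merge(key, on="id", how="inner").reset_index(drop=True)
    return CohortTable(scheme=cohort.scheme, df=df, seed=cohort.seed)


def _fisher_or_mc_p(table: np.ndarray, seed: int) -> tuple[float, str]:
    """Exact 2x2 Fisher; otherwise a seeded Monte Carlo permutation chi-square."""
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1]), "fisher"
    rng = np.random.default_rng(seed)
    obs = stats.chi2_contingency(table, correction=False)[0]
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0).astype(int))
    n_mc = 2000
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        sim = np.zeros_like(table)
        np.add.at(sim, (rows, perm), 1)
        if stats.chi2_contingency(sim, correction=False)[0] >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_mc + 1), "mc-permutation"


def balance_check(
    cohort: CohortTable,
    factors: list[str] | None = None,
    seed: int = 0,
) -> BalanceReport:
    """Across-arm balance of every factor in a (matched) cohort.

    Per factor: a chi-square test of the arm x level contingency table
    (no continuity correction), with an exact/permutation fallback when any
    expected cell count is below 5 and the total n is at most 200, plus the
    largest pairwise standardized mean difference over the factor's
    indicator columns.
    """
    df = cohort.df
    arms = sorted(df["arm"].unique())
    if len(arms) < 2:
        raise ValueError("balance check needs at least two arms")
    if factors is None:
        factors = list(cohort.scheme.factor_names)

    rows = []
    for f in factors:
        levels = [lv for lv in cohort.scheme.levels(f) if (df[f] == lv).any()]
        if len(levels) < 2:
            rows.append((f, 1.0, "degenerate", 0.0))
            continue
        table = np.array([
            [((df["arm"] == a) & (df[f] == lv)).sum() for lv in levels] for a in arms
        ], dtype=float)
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any() and table.sum() <= 200:
            p, kind = _fisher_or_mc_p(table, seed)
        else:
            p = float(stats.chi2_contingency(table, correction=False)[1])
            kind = "chi2"
        # max pairwise SMD over indicator columns
        max_smd = 0.0
        props = table / table.sum(axis=1, keepdims=True)
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                p1, p2 = props[i], props[j]
                denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    smd = np.abs(p1 - p2) / denom
                smd = smd[np.isfinite(smd)]
                if smd.size:
                    max_smd = max(max_smd, float(smd.max()))
        rows.append((f, p, kind, max_smd))
    return BalanceReport(table=pd.DataFrame(rows, columns=["factor", "p", "test", "max_smd"]))
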