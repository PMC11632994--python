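"""Survival-analysis core: Kaplan-Meier, log-rank, BH, Cox PH, Harrell's C.

Everything here operates on plain numpy arrays (times in months, 0/1 event
flags) so the routines can serve both the classical analyses and the neural
risk model without conversion layers.

Conventions, stated once:

* at tied times, events are processed before censorings (the standard
  product-limit convention);
* the Cox partial likelihood handles tied event times with the Efron
  approximation by default (Breslow available);
* confidence intervals and p-values for Cox fits are Wald-type, from the
  inverse observed information;
* the log-rank statistic is referred to a chi-square with (groups - 1)
  degrees of freedom, no continuity correction;
* the bootstrap is subject-level percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "CoxFit",
    "ConcordanceResult",
    "km_estimate",
    "logrank_test",
    "bh_adjust",
    "cox_fit",
    "concordance",
    "bootstrap_ci",
]


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with risk-set bookkeeping."""

    times: np.ndarray      # distinct event times, strictly increasing
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # risk-set size just before each event time
    events: np.ndarray     # deaths at each event time
    censored: np.ndarray   # censorings in [t_i, t_{i+1})

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxFit:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray       # (p, 2) on the hazard-ratio scale
    p: np.ndarray
    loglik: float
    converged: bool
    message: str = ""

    def linear_predictor(self, design: np.ndarray) -> np.ndarray:
        return np.asarray(design, float) @ self.coef


@dataclass
class ConcordanceResult:
    c: float
    n_pairs: int
    ci95: tuple[float, float] | None = None
    resamples: int = 0


def _check_time_event(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t <= 0).any():
        raise ValueError("all times must be positive")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t, e = _check_time_event(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size

    event_times, out_surv, out_risk, out_d, out_c = [], [], [], [], []
    s = 1.0
    i = 0
    at_risk = n
    while i < n:
        ti = t[i]
        j = i
        d = c = 0
        while j < n and t[j] == ti:
            d += e[j]
            c += 1 - e[j]
            j += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            event_times.append(ti)
            out_surv.append(s)
            out_risk.append(at_risk)
            out_d.append(d)
            out_c.append(c)
        elif out_c:
            out_c[-1] += c
        at_risk -= d + c
        i = j
    return SurvivalCurve(
        times=np.asarray(event_times, float),
        survival=np.asarray(out_surv, float),
        at_risk=np.asarray(out_risk, float),
        events=np.asarray(out_d, float),
        censored=np.asarray(out_c, float),
    )


def logrank_test(times, events, group_labels) -> LogrankResult:
    """k-sample log-rank test over the pooled event times."""
    t, e = _check_time_event(times, events)
    g = np.asarray(group_labels)
    groups = np.unique(g)
    k = groups.size
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")
    for lab in groups:
        if (g == lab).sum() == 0:  # pragma: no cover - unique() precludes it
            raise ValueError(f"group {lab!r} is empty")

    membership = (g[:, None] == groups[None, :]).astype(float)  # (n, k)
    event_times = np.unique(t[e == 1])
    obs_minus_exp = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in event_times:
        at_risk = t >= ti
        n_i = at_risk.sum()
        n_ig = membership[at_risk].sum(axis=0)
        died = (t == ti) & (e == 1)
        d_i = died.sum()
        d_ig = membership[died].sum(axis=0)
        exp_g = d_i * n_ig / n_i
        obs_minus_exp += d_ig - exp_g
        if n_i > 1:
            frac = n_ig / n_i
            hyper = d_i * (n_i - d_i) / (n_i - 1)
            cov += hyper * (np.diag(frac) - np.outer(frac, frac))
    v = obs_minus_exp[:-1]
    cmat = cov[:-1, :-1]
    try:
        chi2 = float(v @ np.linalg.solve(cmat, v))
    except np.linalg.LinAlgError:
        chi2 = float(v @ np.linalg.pinv(cmat) @ v)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogrankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _cox_loglik_deriv(beta, x, t, e, ties):
    """Partial log-likelihood, score and information (Efron or Breslow ties).

    Subjects are pre-sorted by descending time so the risk set at each event
    time is a prefix; running sums S0, S1, S2 accumulate exp(h), exp(h)x and
    exp(h)xx' over that prefix.
    """
    n, p = x.shape
    eta = x @ beta
    shift = eta.max()
    w = np.exp(eta - shift)

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))

    # group boundaries of tied times (t sorted descending)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    stops = np.r_[starts[1:], n]
    for i, j in zip(starts, stops):
        wg = w[i:j]
        xg = x[i:j]
        s0 += wg.sum()
        s1 += wg @ xg
        s2 += np.einsum("i,ij,ik->jk", wg, xg, xg)
        death = slice(i, j)
        dmask = e[death] == 1
        d = int(dmask.sum())
        if d > 0:
            xd = x[death][dmask]
            wd = w[death][dmask]
            loglik += eta[death][dmask].sum()
            if ties == "breslow":
                mean = s1 / s0
                loglik -= d * (np.log(s0) + shift)
                score += xd.sum(axis=0) - d * mean
                info += d * (s2 / s0 - np.outer(mean, mean))
            else:  # efron
                ws0 = wd.sum()
                ws1 = (wd[:, None] * xd).sum(axis=0)
                ws2 = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
                for ell in range(d):
                    f = ell / d
                    a0 = s0 - f * ws0
                    a1 = s1 - f * ws1
                    a2 = s2 - f * ws2
                    mean = a1 / a0
                    loglik -= np.log(a0) + shift
                    score -= mean
                    info += a2 / a0 - np.outer(mean, mean)
                score += xd.sum(axis=0)
    return loglik, score, info


def cox_fit(design, times, events, ties: str = "efron", terms=None) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson with step-halving.

    ``design`` is a numeric matrix (typically full-rank one-hot indicator
    columns with reference levels dropped). Convergence is declared when the
    max absolute score falls below 1e-8 or the relative log-likelihood change
    below 1e-9; at most 100 iterations. Standard errors come from the
    inverse observed information; CIs and p-values are Wald-type.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    x = np.atleast_2d(np.asarray(design, dtype=float))
    if x.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    t, e = _check_time_event(times, events)
    n, p = x.shape
    if t.size != n:
        raise ValueError("design and times must have equal length")
    if n <= p:
        raise ValueError(f"n={n} subjects cannot identify {p} coefficients")
    if e.sum() == 0:
        raise ValueError("no events: partial likelihood is undefined")
    col_sd = x.std(axis=0)
    if (col_sd == 0).any():
        raise ValueError("design contains a constant column (drop reference levels)")
    if terms is None:
        terms = [f"x{j}" for j in range(p)]

    order = np.argsort(-t, kind="stable")
    xs, ts, es = x[order], t[order], e[order]

    beta = np.zeros(p)
    loglik, score, info = _cox_loglik_deriv(beta, xs, ts, es, ties)
    converged = False
    message = "max iterations reached"
    for _ in range(100):
        if np.max(np.abs(score)) < 1e-8:
            converged, message = True, "score converged"
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            converged, message = False, "singular information matrix"
            break
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik_deriv(new_beta, xs, ts, es, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < loglik) and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik_deriv(new_beta, xs, ts, es, ties)
            halvings += 1
        rel_change = abs(new_ll - loglik) / max(abs(loglik), 1.0)
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if rel_change < 1e-9:
            converged, message = True, "loglik converged"
            break
        if np.max(np.abs(beta)) > 50:
            converged, message = False, "monotone likelihood (divergent coefficient)"
            break
    # a flat likelihood reached at an extreme coefficient means the optimum
    # sits at infinity (monotone likelihood), not at an interior point
    if converged and np.max(np.abs(beta)) > 15:
        converged = False
        message = "monotone likelihood (divergent coefficient)"

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged, message = False, "singular information matrix"

    z = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        hr = np.exp(beta)
        ci = np.column_stack([np.exp(beta - z * se), np.exp(beta + z * se)])
        pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return CoxFit(
        terms=list(terms), coef=beta, se=se, hr=hr, ci95=ci,
        p=pvals, loglik=float(loglik), converged=converged, message=message,
    )


def concordance(times, events, risk_scores) -> ConcordanceResult:
    """Harrell's C over comparable pairs.

    A pair is comparable when the shorter time carries an event (at tied
    times: one event and one censoring, the event counted as shorter; two
    tied events are not comparable). Concordant = higher risk with the
    shorter time; tied risk scores credit 1/2.
    """
    t, e = _check_time_event(times, events)
    r = np.asarray(risk_scores, dtype=float)
    if r.shape != t.shape:
        raise ValueError("risk_scores must match times in length")

    n_pairs = 0
    n_conc = 0.0
    # block-wise O(n^2) with vectorised comparisons
    block = 512
    n = t.size
    for start in range(0, n, block):
        sl = slice(start, min(start + block, n))
        ti, ei, ri = t[sl, None], e[sl, None], r[sl, None]
        # i shorter with event
        comp = ((ti < t[None, :]) & (ei == 1)) | (
            (ti == t[None, :]) & (ei == 1) & (e[None, :] == 0)
        )
        n_pairs += int(comp.sum())
        n_conc += float(((ri > r[None, :]) & comp).sum())
        n_conc += 0.5 * float(((ri == r[None, :]) & comp).sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    return ConcordanceResult(c=n_conc / n_pairs, n_pairs=n_pairs)


def bootstrap_ci(data, statistic_fn, resamples: int, seed: int, level: float = 0.95):
    """Subject-level percentile bootstrap interval for ``statistic_fn``.

    ``data`` is an array or a tuple of equal-length arrays resampled jointly.
    A resample on which the statistic raises is redrawn, with a hard cap of
    10x ``resamples`` attempts in total.
    """
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    arrays = data if isinstance(data, (tuple, list)) else (data,)
    arrays = [np.asarray(a) for a in arrays]
    n = arrays[0].shape[0]
    rng = np.random.default_rng(seed)
    stats_out = []
    attempts = 0
    while len(stats_out) < resamples:
        if attempts >= 10 * resamples:
            raise RuntimeError("statistic undefined on too many bootstrap resamples")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            stats_out.append(float(statistic_fn(*(a[idx] for a in arrays))))
        except (ValueError, ZeroDivisionError, np.linalg.LinAlgError):
            continue
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats_out, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
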