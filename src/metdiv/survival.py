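"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, concordance.

Model fitting is delegated to lifelines (Efron handling of ties, Wald CIs
on the log-hazard scale, Harrell's concordance). A fast vectorized
two-group log-rank statistic is provided for the resampling-heavy callers
(cutpoint scans, stability curves); it computes the identical
observed-minus-expected chi-square and is cross-checked against lifelines
in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

from .exceptions import DegenerateDataError, MetdivError, ValidationError


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate."""

    times: np.ndarray          # event-time grid (including t=0)
    survival: np.ndarray       # S(t) step values on the grid
    at_risk: np.ndarray        # subjects at risk entering each grid time
    censor_times: np.ndarray   # censoring marks
    max_time: float
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) read from the step function.

        Beyond observed follow-up the estimate is undefined (NaN) unless
        the curve already reached 0 (the risk set was exhausted by
        events), in which case it stays 0.
        """
        if t < 0:
            raise ValidationError("t must be >= 0")
        if t > self.max_time:
            return 0.0 if self.survival[-1] == 0.0 else np.nan
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError("empty input")
    if (times <= 0).any():
        raise ValidationError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    ev = kmf.event_table
    at_risk = ev["at_risk"].reindex(grid).to_numpy(dtype=float)
    return KMEstimate(
        times=grid, survival=surv, at_risk=at_risk,
        censor_times=np.sort(times[events == 0]),
        max_time=float(times.max()), n=len(times),
    )


def landmark_survival(km: KMEstimate, t_months: float) -> float:
    """Survival proportion at a landmark time (e.g. 60 months = 5 years).

    NaN when the landmark lies beyond observed follow-up.
    """
    return km.survival_at(t_months)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    df: int


def logrank_test(times, events, groups) -> LogrankResult:
    """k-group log-rank test (chi-square with k−1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    if (counts == 0).any():
        raise ValidationError("empty group")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(statistic=float(res.test_statistic), p=float(res.p_value), df=len(labels) - 1)


def logrank_2group(times, events, in_group) -> LogrankResult:
    """Vectorized two-group log-rank (same statistic as :func:`logrank_test`).

    ``in_group`` is a boolean mask for one of the two groups. Degenerate
    data (no events, or one group empty of risk variation) yields
    statistic 0, p 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(in_group, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = len(t)
    _, idx = np.unique(t, return_index=True)
    d_tot = np.add.reduceat(e.astype(float), idx)
    d1 = np.add.reduceat((e & g).astype(float), idx)
    n_risk = (n - idx).astype(float)
    g_removed = np.concatenate(([0.0], np.cumsum(np.add.reduceat(g.astype(float), idx))))[:-1]
    n1_risk = g.sum() - g_removed
    has_event = d_tot > 0
    d, d1, nr, n1 = d_tot[has_event], d1[has_event], n_risk[has_event], n1_risk[has_event]
    if len(d) == 0:
        return LogrankResult(0.0, 1.0, 1)
    frac = n1 / nr
    o_minus_e = d1.sum() - (d * frac).sum()
    ok = nr > 1
    var = (d[ok] * frac[ok] * (1 - frac[ok]) * (nr[ok] - d[ok]) / (nr[ok] - 1)).sum()
    if var <= 0:
        return LogrankResult(0.0, 1.0, 1)
    chi2 = o_minus_e**2 / var
    return LogrankResult(float(chi2), float(stats.chi2.sf(chi2, 1)), 1)


@dataclass(frozen=True)
class SurvivalFit:
    """One fitted Cox model (per-covariate HRs, CIs, p) plus concordance."""

    endpoint: str
    covariates: tuple
    hr: dict
    ci_low: dict
    ci_high: dict
    p: dict
    concordance: float
    n: int
    n_events: int
    logrank_p: float = field(default=np.nan)  # grouped single-covariate analyses
    penalized: bool = field(default=False)    # ridge fallback used (separation)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": list(self.covariates),
            "hr": [self.hr[c] for c in self.covariates],
            "ci_low": [self.ci_low[c] for c in self.covariates],
            "ci_high": [self.ci_high[c] for c in self.covariates],
            "p": [self.p[c] for c in self.covariates],
        })


def cox_fit(data: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str], endpoint: str = "OS",
            penalizer: float = 0.0) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CI and p).

    ``data`` holds one row per patient. Covariates should be numeric
    (binary group indicators for dichotomized scores). Raises
    :class:`MetdivError` on non-convergence with lifelines' diagnostics
    attached; low event counts (< 5 per covariate) draw a warning.
    ``penalizer`` adds an L2 (ridge) penalty — useful when complete
    separation makes the unpenalized likelihood monotone.
    """
    if not covariates:
        raise ValidationError("need >= 1 covariate")
    df = data[list(covariates) + [duration_col, event_col]].dropna()
    n_events = int(df[event_col].sum())
    if len(df) < 2:
        raise ValidationError("need >= 2 subjects")
    if n_events < 5 * len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariate(s); "
            "estimates may be unstable", stacklevel=2,
        )
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise MetdivError(f"Cox fit failed to converge: {err}") from err
    s = cph.summary
    return SurvivalFit(
        endpoint=endpoint,
        covariates=tuple(covariates),
        hr={c: float(s.loc[c, "exp(coef)"]) for c in covariates},
        ci_low={c: float(s.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_high={c: float(s.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        p={c: float(s.loc[c, "p"]) for c in covariates},
        concordance=float(cph.concordance_index_),
        n=len(df),
        n_events=n_events,
        penalized=penalizer > 0,
    )


def cox_fit_robust(data: pd.DataFrame, duration_col: str, event_col: str,
                   covariates: list[str], endpoint: str = "OS",
                   fallback_penalizer: float = 0.1) -> SurvivalFit:
    """:func:`cox_fit`, retried with a ridge penalty on non-convergence.

    Complete separation (e.g. an optimal cutpoint isolating a small
    all-event group) makes the partial likelihood monotone; the penalized
    refit keeps the estimate finite and the result carries
    ``penalized=True``.
    """
    try:
        return cox_fit(data, duration_col, event_col, covariates, endpoint=endpoint)
    except MetdivError:
        warnings.warn("Cox fit did not converge (possible separation); "
                      f"refitting with ridge penalizer {fallback_penalizer}",
                      stacklevel=2)
        return cox_fit(data, duration_col, event_col, covariates,
                       endpoint=endpoint, penalizer=fallback_penalizer)


def grouped_univariate_fit(times, events, labels, name: str = "group",
                           endpoint: str = "OS") -> SurvivalFit:
    """Univariate Cox on a binary high/low grouping, with log-rank p attached.

    ``labels`` holds 'low'/'high' (or 0/1); hazard ratio is high vs low.
    """
    lab = np.asarray(labels)
    if lab.dtype.kind in "OUS":
        ind = (lab == "high").astype(int)
    else:
        ind = lab.astype(int)
    df = pd.DataFrame({name: ind, "t": np.asarray(times, dtype=float),
                       "e": np.asarray(events, dtype=int)})
    fit = cox_fit_robust(df, "t", "e", [name], endpoint=endpoint)
    lr = logrank_2group(df["t"], df["e"], ind.astype(bool))
    return SurvivalFit(**{**vars(fit), "logrank_p": lr.p})


def select_multivariate_factors(univariate_fits) -> list[str]:
    """Covariates eligible for the multivariate model: univariate p < 0.05.

    Accepts ``(name, p)`` pairs or single-covariate :class:`SurvivalFit`
    objects; input order is preserved.
    """
    out = []
    for item in univariate_fits:
        if isinstance(item, SurvivalFit):
            name = item.covariates[0]
            p = item.p[name]
        else:
            name, p = item
        if p < 0.05:
            out.append(name)
    return out


def concordance(risk_scores, times, events) -> float:
    """Harrell's C for a risk score (higher score = higher hazard).

    1.0 for a perfectly rank-predictive risk score, ~0.5 for noise.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise DegenerateDataError("no events: no comparable pairs")
    # lifelines' convention: higher prediction = longer survival
    return float(concordance_index(times, -np.asarray(risk_scores, dtype=float), events))
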