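"""Survival and contingency statistics: Kaplan-Meier, log-rank, Cox
(including treatment x group interaction), and Pearson chi-square.

Cox models use Efron tie handling and Wald inference; chi-square tests use
no continuity correction. All p-values are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as lls
from lifelines.exceptions import ConvergenceError

logger = logging.getLogger(__name__)


@dataclass
class SurvivalSummary:
    """One Cox model term: hazard ratio, 95% Wald CI, p, and model sizes."""

    term: str
    hr: float
    ci95: tuple
    p: float
    n: int
    events: int
    coef: float = np.nan
    se: float = np.nan


class KMCurve:
    """Product-limit estimator with Greenwood variance; S(0) = 1."""

    def __init__(self, kmf: KaplanMeierFitter):
        self._kmf = kmf

    def at(self, t: float) -> float:
        """Survival probability at time t (last value carried forward)."""
        return float(self._kmf.predict(t))

    def survival_table(self) -> pd.DataFrame:
        return self._kmf.survival_function_


def km_estimate(times, events) -> KMCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate: empty input")
    if np.any(times < 0):
        raise ValueError("km_estimate: negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return KMCurve(kmf)


def logrank_test(times_a, events_a, times_b, events_b):
    """Standard 1-df log-rank chi-square and two-sided p."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("logrank_test: both groups need >= 1 subject")
    if events_a.sum() + events_b.sum() == 0:
        logger.warning("logrank_test: no events in either group; p = 1")
        return 0.0, 1.0
    res = lls.logrank_test(times_a, times_b, events_a, events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(design: pd.DataFrame, times, events, robust: bool = False) -> dict:
    """Cox proportional-hazards fit; returns {term: SurvivalSummary}.

    ``design`` holds numeric covariate columns (categoricals must already
    be dummy-coded). Efron handling of tied event times; Wald CI and p per
    term. Errors on constant covariates, non-convergence, and monotone
    likelihood (perfect separation).
    """
    design = pd.DataFrame(design).reset_index(drop=True)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if design.shape[0] != times.size:
        raise ValueError("design rows must match times")
    for col in design.columns:
        if design[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    n_events = int(events.sum())
    if n_events < design.shape[1]:
        raise ValueError(
            f"{n_events} events cannot identify {design.shape[1]} terms")
    df = design.copy()
    df["_T"], df["_E"] = times, events.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_T", event_col="_E", robust=robust,
                fit_options={"max_steps": 100})
    except ConvergenceError as exc:
        raise RuntimeError(
            "Cox model did not converge in 100 iterations; check for "
            "monotone likelihood (perfect separation) or collinearity"
        ) from exc
    coefs = cph.params_
    if np.any(np.abs(coefs) > 15):
        raise RuntimeError(
            "Cox fit shows monotone likelihood (a coefficient diverged); "
            "a covariate perfectly separates the events — remove or merge it"
        )
    out = {}
    summ = cph.summary
    for term in design.columns:
        row = summ.loc[term]
        out[term] = SurvivalSummary(
            term=term,
            hr=float(row["exp(coef)"]),
            ci95=(float(row["exp(coef) lower 95%"]),
                  float(row["exp(coef) upper 95%"])),
            p=float(row["p"]),
            n=len(df),
            events=n_events,
            coef=float(row["coef"]),
            se=float(row["se(coef)"]),
        )
    return out


def interaction_pvalue(treatment, group, adjusters, times, events) -> float:
    """Wald p of the treatment x group product term in an adjusted Cox model.

    The model contains treatment, group, their product, and the adjuster
    columns. ``adjusters`` may be None/empty for the unadjusted test.
    """
    treatment = np.asarray(treatment, dtype=float)
    group = np.asarray(group, dtype=float)
    if len(np.unique(group)) < 2:
        raise ValueError("group is constant; interaction undefined")
    if len(np.unique(treatment)) < 2:
        raise ValueError("treatment is constant; interaction undefined")
    design = pd.DataFrame({
        "treatment": treatment,
        "group": group,
        "treatment_x_group": treatment * group,
    })
    if adjusters is not None and len(getattr(adjusters, "columns", [])) > 0:
        adj = pd.DataFrame(adjusters).reset_index(drop=True)
        for col in adj.columns:
            design[col] = adj[col].to_numpy(dtype=float)
    summ = cox_fit(design, times, events)
    return summ["treatment_x_group"].p


def chisq_independence(table):
    """Pearson chi-square of independence, no continuity correction.

    ``table`` is an r x c array of non-negative counts (r, c >= 2).
    Returns (statistic, df, p).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column in contingency table")
    stat, p, dof, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def km_rfs_comparison(times, events, treated, label: str = "") -> dict:
    """Convenience bundle: per-arm KM at 36 months, log-rank p, Cox HR for
    treatment. Used for the within-stratum validation contrasts."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    treated = np.asarray(treated, dtype=bool)
    stat, p_lr = logrank_test(times[treated], events[treated],
                              times[~treated], events[~treated])
    cox = cox_fit(pd.DataFrame({"act": treated.astype(float)}), times, events)["act"]
    return {
        "label": label,
        "n": int(times.size),
        "events": int(events.sum()),
        "rfs36_act": km_estimate(times[treated], events[treated]).at(36.0),
        "rfs36_noact": km_estimate(times[~treated], events[~treated]).at(36.0),
        "logrank_stat": stat,
        "logrank_p": p_lr,
        "hr": cox.hr,
        "ci_low": cox.ci95[0],
        "ci_high": cox.ci95[1],
        "cox_p": cox.p,
    }
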