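"""Propensity-score construction and 1:rho nearest-neighbor matching.

The propensity score is the modeled probability of receiving chemotherapy
given baseline covariates. Covariates are screened by univariate logistic
regression, the score is fit by multivariable logistic regression, and
treated patients are matched to controls greedily (closest logit-PS,
without replacement, within a caliper). A fractional ratio such as 1.5 is
realized by variable matching: per-treated quotas alternate 2 and 1 so the
aggregate control count is ceil(ratio x treated).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .survstats import chisq_independence

logger = logging.getLogger(__name__)

#: Age grouping used for categorical covariates and balance tables.
AGE_BINS = ((0, 55, "<55"), (55, 65, "55-65"), (65, 75, "65-75"),
            (75, math.inf, ">75"))


def age_category(age: float) -> str:
    for lo, hi, lab in AGE_BINS:
        if lo <= age < hi or (hi == math.inf and age >= lo):
            return lab
    raise ValueError(f"age {age} outside bins")


def _design_for(clinical: pd.DataFrame, covariates) -> pd.DataFrame:
    """Dummy-code categorical covariates; age enters as the 4-level category."""
    cols = {}
    for cov in covariates:
        if cov == "age_years":
            cat = clinical["age_years"].astype(float).map(age_category)
            dummies = pd.get_dummies(cat, prefix="age", drop_first=True)
        else:
            dummies = pd.get_dummies(clinical[cov].astype(str), prefix=cov,
                                     drop_first=True)
        for c in dummies.columns:
            cols[c] = dummies[c].astype(float)
    return pd.DataFrame(cols, index=clinical.index)


def _logit_lr_pvalue(y: np.ndarray, design: pd.DataFrame) -> float:
    """Likelihood-ratio p for a covariate block in logistic regression."""
    X1 = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    m1 = sm.Logit(y, X1).fit(disp=0, maxiter=200)
    m0 = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0, maxiter=200)
    lr = 2.0 * (m1.llf - m0.llf)
    df = design.shape[1]
    import scipy.stats
    return float(scipy.stats.chi2.sf(max(lr, 0.0), df))


def select_ps_covariates(clinical: pd.DataFrame, candidates, alpha: float = 0.05):
    """Keep covariates univariately associated with treatment at p < alpha.

    Covariates with >= 50% missingness are not considered. Quasi-separated
    covariates are kept with a warning (their association is extreme, not
    absent).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate covariate list")
    y = clinical["act"].astype(int).to_numpy()
    selected = []
    for cov in candidates:
        col = clinical[cov]
        if col.isna().mean() >= 0.5:
            logger.warning("select_ps_covariates: %s dropped (>=50%% missing)", cov)
            continue
        ok = col.notna()
        design = _design_for(clinical.loc[ok], [cov])
        if design.shape[1] == 0:
            continue
        try:
            p = _logit_lr_pvalue(y[ok.to_numpy()], design)
        except Exception as exc:
            logger.warning("select_ps_covariates: %s kept despite separation (%s)",
                           cov, exc)
            selected.append(cov)
            continue
        if p < alpha:
            selected.append(cov)
    return selected


def fit_propensity(clinical: pd.DataFrame, covariates) -> pd.Series:
    """Multivariable logistic PS in (0, 1), indexed by sample_id.

    Patients with a missing selected covariate are excluded (logged)."""
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates for the propensity model")
    complete = clinical[covariates].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("fit_propensity: %d patients dropped for missing covariates",
                    n_dropped)
    sub = clinical.loc[complete]
    design = _design_for(sub, covariates)
    if design.shape[1] == 0:
        raise ValueError(f"covariates {covariates} carry no variation")
    for c in design.columns:
        if design[c].nunique() <= 1:
            raise ValueError(f"constant covariate column {c!r}")
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    y = sub["act"].astype(int).to_numpy()
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("propensity logistic regression did not converge")
    ps = np.clip(res.predict(X), 1e-12, 1 - 1e-12)
    return pd.Series(ps, index=sub["sample_id"].astype(str).to_numpy(),
                     name="propensity")


@dataclass
class MatchResult:
    matched_treated: list
    matched_controls: list
    pairing: dict            # treated id -> list of control ids
    unmatched_treated: list
    ratio: float
    caliper: float


def _quotas(n_treated: int, ratio: float):
    """Per-treated control quotas with cumulative targets ceil(ratio * i)."""
    quotas, prev = [], 0
    for i in range(1, n_treated + 1):
        tgt = math.ceil(ratio * i)
        quotas.append(tgt - prev)
        prev = tgt
    return quotas


def match_nearest(ps: pd.Series, treated: pd.Series, ratio: float = 1.5,
                  caliper: float = None) -> MatchResult:
    """Greedy nearest-neighbor matching on logit PS, without replacement.

    Treated patients are processed in descending PS (ties by id); each
    receives its quota of nearest unmatched controls whose logit PS lies
    within the caliper (default 0.2 x SD of logit PS). Controls outside the
    caliper are skipped; a treated patient with no admissible control is
    reported unmatched.
    """
    ps = pd.Series(ps)
    treated = pd.Series(treated).astype(bool)
    treated = treated.reindex(ps.index)
    t_ids = ps.index[treated].tolist()
    c_ids = ps.index[~treated].tolist()
    if not t_ids or not c_ids:
        raise ValueError("both arms must be non-empty")
    logit = np.log(ps / (1 - ps))
    if caliper is None:
        caliper = 0.2 * float(logit.std(ddof=1))
    order = sorted(t_ids, key=lambda i: (-ps[i], i))
    quotas = _quotas(len(order), ratio)
    available = set(c_ids)
    pairing, unmatched = {}, []
    for tid, quota in zip(order, quotas):
        picks = []
        pool = sorted(available, key=lambda c: (abs(logit[c] - logit[tid]), c))
        for cid in pool:
            if len(picks) >= quota:
                break
            if abs(logit[cid] - logit[tid]) <= caliper:
                picks.append(cid)
        if not picks:
            unmatched.append(tid)
            continue
        for cid in picks:
            available.discard(cid)
        pairing[tid] = picks
    if not pairing:
        logger.warning("match_nearest: no treated patient matched within caliper")
    matched_controls = [c for picks in pairing.values() for c in picks]
    return MatchResult(
        matched_treated=list(pairing.keys()),
        matched_controls=matched_controls,
        pairing=pairing,
        unmatched_treated=unmatched,
        ratio=ratio,
        caliper=float(caliper),
    )


def _counts_by_arm(clinical: pd.DataFrame, cov: str):
    if cov == "age_years":
        values = clinical["age_years"].astype(float).map(age_category)
        levels = [b[2] for b in AGE_BINS]
    else:
        values = clinical[cov].astype(str)
        levels = sorted(values.dropna().unique())
    act = clinical["act"].astype(bool)
    rows = []
    kept_levels = []
    for lev in levels:
        a = int(((values == lev) & act).sum())
        b = int(((values == lev) & ~act).sum())
        if a + b == 0:
            logger.warning("balance_table: level %s of %s empty, dropped", lev, cov)
            continue
        rows.append([a, b])
        kept_levels.append(lev)
    return np.array(rows), kept_levels


def balance_table(clinical: pd.DataFrame, match: MatchResult, covariates) -> pd.DataFrame:
    """Chi-square balance p-values before and after matching, per covariate."""
    clinical = clinical.copy()
    clinical.index = clinical["sample_id"].astype(str)
    matched_ids = list(match.matched_treated) + list(match.matched_controls)
    after = clinical.loc[matched_ids]
    rows = []
    for cov in covariates:
        sub_before = clinical[clinical[cov].notna()] if cov != "age_years" \
            else clinical[clinical["age_years"].notna()]
        sub_after = after[after[cov].notna()] if cov != "age_years" \
            else after[after["age_years"].notna()]
        tb, _ = _counts_by_arm(sub_before, cov)
        ta, _ = _counts_by_arm(sub_after, cov)
        p_before = chisq_independence(tb)[2] if tb.shape[0] >= 2 else np.nan
        p_after = chisq_independence(ta)[2] if ta.shape[0] >= 2 else np.nan
        rows.append({"covariate": cov, "p_before": p_before, "p_after": p_after})
    return pd.DataFrame(rows)
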