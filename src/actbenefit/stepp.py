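"""Subpopulation Treatment Effect Pattern Plot (STEPP) over predictive scores.

Patients are ordered by predictive score and grouped into overlapping
sliding windows of ``n2`` patients sharing ``n1`` neighbors. Within each
window the treatment effect is re-estimated (36-month Kaplan-Meier RFS per
arm and a window-wise Cox hazard ratio for treatment), revealing whether
the benefit of chemotherapy concentrates at high scores. A score cutoff is
then chosen as the lowest window median above which every window favors
treatment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import CohortDataset
from .survstats import cox_fit, km_estimate

logger = logging.getLogger(__name__)


@dataclass
class SteppWindow:
    member_ids: list
    median_score: float
    rfs36_act: float
    rfs36_noact: float
    rfs_diff: float
    hr_act: float           # NaN when undefined (empty arm / no events)
    hr_ci: tuple
    flagged: bool = False


@dataclass
class SteppProfile:
    windows: list
    n2: int
    n1: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "median_score": w.median_score,
            "rfs36_act": w.rfs36_act,
            "rfs36_noact": w.rfs36_noact,
            "diff": w.rfs_diff,
            "hr": w.hr_act,
            "ci_low": w.hr_ci[0],
            "ci_high": w.hr_ci[1],
            "n": len(w.member_ids),
            "flagged": w.flagged,
        } for w in self.windows])


def build_windows(scores, sample_ids, n2: int, n1: int):
    """Rank-contiguous sliding windows over score-sorted patients.

    Step between window starts is ``n2 - n1`` so consecutive windows share
    ``n1`` patients; the last window is right-aligned to include the
    top-ranked patient. Score ties are broken by sample id so windows are
    reproducible. Returns a list of index arrays into the input order.
    """
    scores = np.asarray(scores, dtype=float)
    sample_ids = list(sample_ids)
    n = len(scores)
    if len(sample_ids) != n:
        raise ValueError("scores and sample_ids must align")
    if n2 > n:
        logger.warning("build_windows: n2=%d > n=%d, using a single window", n2, n)
        n2 = n
        n1 = 0
    if not 0 <= n1 < n2:
        raise ValueError("need 0 <= n1 < n2")
    order = sorted(range(n), key=lambda i: (scores[i], sample_ids[i]))
    step = n2 - n1
    starts = list(range(0, n - n2 + 1, step))
    if starts[-1] + n2 < n:
        starts.append(n - n2)
    return [np.array(order[s: s + n2], dtype=int) for s in starts]


def _km_at36(times, events):
    km = km_estimate(times, events)
    return km.at(36.0)


def stepp_profile(dataset: CohortDataset, scores, n2: int, n1: int) -> SteppProfile:
    """Per-window 36-month RFS per arm, difference (ACT - no ACT), and Cox HR."""
    scores = np.asarray(scores, dtype=float)
    ids = dataset.sample_ids
    times = np.array([r.rfs_months for r in dataset.clinical])
    events = np.array([r.relapse_event for r in dataset.clinical], dtype=bool)
    act = np.array([r.act for r in dataset.clinical], dtype=bool)
    windows = []
    for idx in build_windows(scores, ids, n2, n1):
        w_act = act[idx]
        median = float(np.median(scores[idx]))
        member_ids = [ids[i] for i in idx]
        if w_act.all() or (~w_act).all():
            windows.append(SteppWindow(member_ids, median, np.nan, np.nan,
                                       np.nan, np.nan, (np.nan, np.nan),
                                       flagged=True))
            continue
        s_act = _km_at36(times[idx][w_act], events[idx][w_act])
        s_no = _km_at36(times[idx][~w_act], events[idx][~w_act])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summ = cox_fit(pd.DataFrame({"act": w_act.astype(float)}),
                               times[idx], events[idx])["act"]
            hr, ci = summ.hr, summ.ci95
            flagged = False
        except Exception as exc:  # no events / separation inside a window
            logger.warning("stepp window at median %.3f: HR undefined (%s)",
                           median, exc)
            hr, ci, flagged = np.nan, (np.nan, np.nan), True
        windows.append(SteppWindow(member_ids, median, s_act, s_no,
                                   s_act - s_no, hr, ci, flagged=flagged))
    return SteppProfile(windows=windows, n2=n2, n1=n1)


def default_window_sizes(n: int):
    """n2 = max(40, n/4) overlapping by half, capped at the cohort size."""
    n2 = min(n, max(40, n // 4))
    n1 = n2 // 2
    return n2, n1


def select_cutoff(profile: SteppProfile, criterion: str = "hr-below-one") -> Optional[float]:
    """Smallest window-median m such that every window with median >= m has HR < 1.

    Windows with an undefined HR never satisfy the criterion. Returns None
    (with a warning) when no window qualifies.
    """
    if criterion != "hr-below-one":
        raise ValueError(f"unknown cutoff criterion {criterion!r}")
    if not profile.windows:
        raise ValueError("empty STEPP profile")
    wins = sorted(profile.windows, key=lambda w: w.median_score)
    cutoff = None
    for w in reversed(wins):
        if np.isfinite(w.hr_act) and w.hr_act < 1.0:
            cutoff = w.median_score
        else:
            break
    if cutoff is None:
        logger.warning("select_cutoff: no window suffix with HR < 1; cutoff undefined")
    return cutoff


def stratify_patients(scores, cutoff: float):
    """score > cutoff (strict) -> 'predicted-benefit', else 'predicted-futile'."""
    if cutoff is None:
        raise ValueError("cutoff is undefined")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > cutoff, "predicted-benefit", "predicted-futile")
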