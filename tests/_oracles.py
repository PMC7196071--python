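"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is written from the definition, not from the code under test:
AUC as explicit pair counting, the rank-sum null by enumerating group
assignments pair-by-pair, log-rank by permutation, quantile normalization
as the mean-of-sorted-vectors map.
"""

from itertools import combinations

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """AUC as the fraction of positive-negative pairs ranked concordantly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def rank_sum_enumeration_p(x, y) -> float:
    """Exact two-sided rank-sum p by looping pairs for every assignment."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    m, n = len(x), len(y)

    def u_of(group):
        rest = pooled.copy()
        for v in group:
            rest.remove(v)
        u = 0.0
        for a in group:
            for b in rest:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    center = m * n / 2.0
    dev_obs = abs(u_of(x) - center)
    hits = total = 0
    for combo in combinations(range(m + n), m):
        group = [pooled[i] for i in combo]
        if abs(u_of(group) - center) >= dev_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def logrank_statistic(times, events, group):
    """Log-rank chi-square from the definition (observed vs expected at
    each distinct event time, hypergeometric variance)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=int)
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (group == 1)).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return obs_minus_exp**2 / var


def logrank_permutation_p(times, events, group):
    """Exact permutation p of the log-rank statistic (small n only)."""
    group = np.asarray(group, dtype=int)
    n = len(group)
    n1 = int(group.sum())
    obs = logrank_statistic(times, events, group)
    hits = total = 0
    for combo in combinations(range(n), n1):
        g = np.zeros(n, dtype=int)
        g[list(combo)] = 1
        if logrank_statistic(times, events, g) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def quantile_normalize_reference(values: np.ndarray) -> np.ndarray:
    """Mean-of-sorted-vectors quantile normalization for tie-free columns."""
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j])
        out[order, j] = target
    return out
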