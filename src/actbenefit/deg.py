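"""Differential-expression screen between benefit and futile patients.

Per-gene two-sided Wilcoxon rank-sum test. Small balanced groups (both
sizes <= 10, no ties) use the exact null distribution; otherwise the
tie-corrected normal approximation. Genes passing ``p < alpha`` become the
candidate pool for the GA wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix
from .labeling import BENEFIT, FUTILE

logger = logging.getLogger(__name__)


@dataclass
class DegResult:
    """Per-gene rank-sum statistics, sorted by evidence strength."""

    table: pd.DataFrame   # columns: gene, statistic, p, direction, shift, candidate
    alpha: float

    @property
    def candidate_genes(self) -> list:
        return self.table.loc[self.table["candidate"], "gene"].tolist()


def exact_rank_sum_p(x, y):
    """Exact two-sided rank-sum test by enumerating group assignments.

    Handles ties (which contribute half a concordance to U). Intended for
    both group sizes <= 10; the null enumerates every way of assigning the
    pooled values to the two groups.
    """
    from itertools import combinations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    m, n = len(x), len(y)
    # pairwise win matrix: 1 if i beats j, 0.5 on ties
    gt = (pooled[:, None] > pooled[None, :]).astype(float)
    gt += 0.5 * (pooled[:, None] == pooled[None, :])
    idx_all = np.arange(m + n)
    u_obs = gt[np.ix_(idx_all[:m], idx_all[m:])].sum()
    center = m * n / 2.0
    dev_obs = abs(u_obs - center)
    count = total = 0
    for combo in combinations(range(m + n), m):
        sel = np.array(combo)
        rest = np.setdiff1d(idx_all, sel, assume_unique=True)
        u = gt[np.ix_(sel, rest)].sum()
        count += abs(u - center) >= dev_obs - 1e-9
        total += 1
    return float(u_obs), count / total


def wilcoxon_screen(matrix: ExpressionMatrix, labels, alpha: float = 0.001) -> DegResult:
    """Rank-sum screen of every gene between the two label classes.

    ``labels`` is a benefit/futile sequence aligned to ``matrix.sample_ids``.
    Constant genes get p = 1 and are flagged in the ``constant`` column.
    The output is sorted by p ascending, then |mean shift| descending, then
    gene id; ``candidate`` marks p < alpha.
    """
    labels = np.asarray(labels)
    if len(labels) != matrix.n_samples:
        raise ValueError("labels must align with matrix samples")
    mask_b = labels == BENEFIT
    mask_f = labels == FUTILE
    if mask_b.sum() < 2 or mask_f.sum() < 2:
        raise ValueError("each label class needs >= 2 members")
    xb = matrix.values[:, mask_b]
    xf = matrix.values[:, mask_f]
    n_b, n_f = xb.shape[1], xf.shape[1]

    constant = np.ptp(matrix.values, axis=1) == 0
    use_exact = n_b <= 10 and n_f <= 10

    stat = np.empty(matrix.n_genes)
    pval = np.empty(matrix.n_genes)
    if use_exact:
        for i in range(matrix.n_genes):
            stat[i], pval[i] = exact_rank_sum_p(xb[i], xf[i])
    else:
        res = scipy.stats.mannwhitneyu(xb, xf, alternative="two-sided",
                                       method="asymptotic", axis=1)
        stat, pval = np.asarray(res.statistic), np.asarray(res.pvalue)
    pval = np.where(constant, 1.0, pval)

    shift = xb.mean(axis=1) - xf.mean(axis=1)
    direction = np.where(shift >= 0, "higher-in-benefit", "higher-in-futile")
    table = pd.DataFrame({
        "gene": matrix.gene_ids,
        "statistic": stat,
        "p": pval,
        "direction": direction,
        "shift": shift,
        "constant": constant,
        "candidate": pval < alpha,
    })
    table["_abs_shift"] = table["shift"].abs()
    table = (table.sort_values(["p", "_abs_shift", "gene"],
                               ascending=[True, False, True])
                  .drop(columns="_abs_shift")
                  .reset_index(drop=True))
    logger.info("wilcoxon_screen: %d / %d genes pass p < %g",
                int(table["candidate"].sum()), matrix.n_genes, alpha)
    return DegResult(table=table, alpha=alpha)
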