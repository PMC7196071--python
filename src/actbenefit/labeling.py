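"""Benefit/futile training labels from treatment and 3-year relapse status.

A patient whose outcome is concordant with chemotherapy helping is labeled
"benefit": relapse-free past the threshold on treatment, or early relapse
without treatment. The discordant combinations are "futile". Patients
censored before the threshold have unknown 3-year relapse status and
cannot be labeled; by default they are excluded from training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import ClinicalRecord, CohortDataset

logger = logging.getLogger(__name__)

BENEFIT = "benefit"
FUTILE = "futile"
UNLABELABLE = "unlabelable"

#: Exclusion policies for patients that cannot be cleanly labeled.
#: "censored-early" removes patients censored before the threshold (the
#: self-consistent reading of the labeling rule); "early-relapse" instead
#: removes patients who relapsed before the threshold, the literal reading
#: of an ambiguous alternative.
EXCLUSION_POLICIES = ("censored-early", "early-relapse")


def assign_benefit_label(record: ClinicalRecord, threshold_months: float = 36.0) -> str:
    """Total labeling function of (rfs, relapse_event, act, threshold).

    benefit:  rfs > threshold with ACT, or relapse before threshold without ACT
    futile:   rfs > threshold without ACT, or relapse before threshold with ACT
    unlabelable: censored before the threshold, or rfs exactly at it
    """
    rfs, event, act = record.rfs_months, record.relapse_event, record.act
    if rfs > threshold_months:
        return BENEFIT if act else FUTILE
    if rfs < threshold_months and event:
        return FUTILE if act else BENEFIT
    return UNLABELABLE


@dataclass
class LabeledCohort:
    dataset: CohortDataset
    labels: list                 # aligned to dataset sample order
    exclusion_report: dict       # reason -> count


def label_cohort(dataset: CohortDataset, threshold_months: float = 36.0,
                 exclusion_policy: str = "censored-early") -> LabeledCohort:
    """Label every patient; exclude the ones the policy removes.

    Returns the labeled subset (aligned to expression columns) and a report
    counting exclusions per reason. Fails if either label class ends up with
    fewer than 2 patients, since every downstream test is then undefined.
    """
    if exclusion_policy not in EXCLUSION_POLICIES:
        raise ValueError(f"unknown exclusion policy {exclusion_policy!r}")
    report = {"censored_before_threshold": 0, "at_threshold": 0,
              "early_relapse_removed": 0}
    keep_ids, labels = [], []
    for rec in dataset.clinical:
        if exclusion_policy == "early-relapse" and \
                rec.relapse_event and rec.rfs_months < threshold_months:
            report["early_relapse_removed"] += 1
            continue
        lab = assign_benefit_label(rec, threshold_months)
        if lab == UNLABELABLE:
            if rec.rfs_months == threshold_months:
                report["at_threshold"] += 1
            else:
                report["censored_before_threshold"] += 1
            continue
        keep_ids.append(rec.sample_id)
        labels.append(lab)
    n_benefit = labels.count(BENEFIT)
    n_futile = labels.count(FUTILE)
    if n_benefit < 2 or n_futile < 2:
        raise ValueError(
            f"need >= 2 patients per label, got {n_benefit} benefit / "
            f"{n_futile} futile"
        )
    excluded = sum(report.values())
    if excluded:
        logger.info("label_cohort: excluded %d patients (%s)", excluded, report)
    return LabeledCohort(dataset.subset(keep_ids), labels, report)
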