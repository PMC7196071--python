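"""Generate a synthetic stage II-III colorectal ACT cohort and inspect it.

The generator plants a small set of predictive genes whose shared signal
switches the chemotherapy effect on relapse hazard above a score
threshold, plus prognostic-only genes, batch shifts, and stage-dependent
treatment assignment.
"""
import numpy as np

from actbenefit import SyntheticConfig, generate_cohort
from actbenefit.synthetic import analytic_censoring_fraction

config = SyntheticConfig(n_patients=400, n_genes=100)
dataset, truth = generate_cohort(config, seed=1)

events = np.array([r.relapse_event for r in dataset.clinical])
act = np.array([r.act for r in dataset.clinical])
stage3 = np.array([r.tnm_stage == "III" for r in dataset.clinical])

print(f"cohort: {dataset.n_samples} patients x {dataset.expression.n_genes} genes")
print(f"predictive genes: {truth.predictive_genes}")
print(f"prognostic genes: {truth.prognostic_genes}")
print(f"treated: {act.mean():.2f}   stage III: {stage3.mean():.2f}   "
      f"relapse events: {events.mean():.2f}")
print(f"censoring observed {1 - events.mean():.3f} vs analytic "
      f"{analytic_censoring_fraction(truth.hazard, config.censor_min, config.censor_max):.3f}")
print(f"treated fraction by stage: "
      f"II {act[~stage3].mean():.2f}, III {act[stage3].mean():.2f}")
# The planted benefit stratum is the top (1 - tau) of the biomarker score;
# only treated patients inside it get the hazard reduction.
print(f"true benefit stratum: {truth.benefit.mean():.2f} of patients")
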