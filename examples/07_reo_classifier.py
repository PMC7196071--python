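"""Relative-expression-ordering (REO) gene-pair risk calls.

A REO signature is a list of gene pairs; within each patient, expression
of the first gene exceeding the second votes "high risk". At least half
the votes makes the patient high risk. Only within-patient orderings
matter, so the call survives any monotone normalization.
"""
import numpy as np

from actbenefit import SyntheticConfig, classify_reo, generate_cohort

dataset, _ = generate_cohort(SyntheticConfig(n_patients=8, n_genes=20,
                                             n_predictive=2, n_prognostic=2),
                             seed=7)
# synthetic example signature: six pairs over the simulated gene ids
signature = [("G0000", "G0001"), ("G0002", "G0003"), ("G0004", "G0005"),
             ("G0006", "G0007"), ("G0008", "G0009"), ("G0010", "G0011")]
calls = classify_reo(dataset.expression, signature, vote_threshold=0.5)
print(calls.to_string())

shifted = dataset.expression
shifted.values[:] = 2 * shifted.values + 5  # monotone per-patient transform
assert (classify_reo(shifted, signature) == calls).all()
print("\ncalls unchanged under a monotone transform of expression")
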