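"""Select a gene panel with the GA wrapper and fit the calibrated SVM.

The GA evolves binary gene-inclusion chromosomes scored by 5-fold
cross-validated AUC of an RBF-SVM (TNM stage is always included as a
feature). The best panel is refit on all labeled patients with Platt
sigmoid calibration so each patient gets a benefit probability.
"""
from dataclasses import replace

from actbenefit import (GaConfig, generate_cohort, ga_select, label_cohort,
                        predict_scores, train_final_model, wilcoxon_screen)
from actbenefit.experiments import E2E_STRONG_CONFIG

config = replace(E2E_STRONG_CONFIG, n_patients=400, n_batches=1, batch_shift=0.0)
dataset, truth = generate_cohort(config, seed=2)
labeled = label_cohort(dataset)
deg = wilcoxon_screen(labeled.dataset.expression, labeled.labels, alpha=0.05)
candidates = deg.candidate_genes
print(f"{len(candidates)} candidate genes from the screen: {candidates}")

ga_cfg = GaConfig(population_size=20, p_crossover=0.10, p_mutation=0.30,
                  iterations=100, cv_folds=5, seed=2, parsimony=0.002)
chromosome, trace = ga_select(labeled.dataset, labeled.labels, candidates, ga_cfg)
print(f"GA best cross-validated AUC: {trace.best_fitness[-1]:.3f} "
      f"after {ga_cfg.iterations} generations")

model = train_final_model(labeled.dataset, labeled.labels, chromosome,
                          candidates, seed=2)
print(f"selected genes: {model.selected_genes} (+ TNM stage)")
print(f"planted genes:  {truth.predictive_genes}")
print(f"SVM hyperparameters: C = {model.cost_c}, gamma = {model.gamma_g:.4f}")
scores = predict_scores(model, dataset)
print(f"benefit scores: min {scores.min():.3f}, median "
      f"{sorted(scores)[len(scores)//2]:.3f}, max {scores.max():.3f}")
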