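import numpy as np
import pytest

from actbenefit import (Chromosome, GaConfig, compute_auc, cv_fitness,
                        ga_select, load_model, predict_scores, save_model,
                        train_final_model, tune_hyperparams)
from actbenefit.svmga import FitnessEngine, build_features, stratified_folds
from ._oracles import auc_pair_counting


class TestAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert compute_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert compute_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("n", range(2, 13))
    def test_matches_pair_counting_oracle_exhaustively(self, n):
        rng = np.random.default_rng(n)
        for _ in range(30):
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # force ties
            assert compute_auc(scores, labels) == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12)


class TestFoldsAndFitness:
    def test_folds_are_pure_function_of_inputs(self, separable):
        dataset, labels = separable
        y = np.array([1 if l == "benefit" else 0 for l in labels])
        f1 = stratified_folds(dataset.sample_ids, y, 5, seed=3)
        f2 = stratified_folds(dataset.sample_ids, y, 5, seed=3)
        for (a1, b1), (a2, b2) in zip(f1, f2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)

    def test_engine_kernel_matches_direct_computation(self, separable):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        engine = FitnessEngine(dataset, labels, genes, include_stage=False)
        bits = np.array([True, False, True, False, True])
        gamma = 0.3
        K = engine.kernel(bits, gamma)
        X, _, _ = build_features(dataset, [g for g, b in zip(genes, bits) if b],
                                 include_stage=False)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        np.testing.assert_allclose(K, np.exp(-gamma * d2), atol=1e-12)

    def test_planted_gene_fitness_high_and_deterministic(self, separable):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        chrom = Chromosome(np.array([1, 0, 0, 0, 0], dtype=bool),
                           include_stage=False)
        fit1 = cv_fitness(chrom, dataset, labels, genes, c=1.0, gamma=0.2, seed=0)
        fit2 = cv_fitness(chrom, dataset, labels, genes, c=1.0, gamma=0.2, seed=0)
        assert fit1 > 0.9
        assert fit1 == fit2

    def test_permuted_labels_fitness_near_half(self, separable):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        chrom = Chromosome(np.ones(5, dtype=bool), include_stage=False)
        fits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = list(rng.permutation(labels))
            fits.append(cv_fitness(chrom, dataset, shuffled, genes,
                                   c=1.0, gamma=0.2, seed=seed))
        assert abs(np.mean(fits) - 0.5) < 0.1


class TestTuning:
    def test_single_point_grid_returned(self, separable):
        dataset, labels = separable
        c, g = tune_hyperparams(dataset, labels, dataset.expression.gene_ids,
                                grid=[(2.0, 0.125)], seed=1)
        assert (c, g) == (2.0, 0.125)

    def test_separable_toy_reaches_high_auc(self, separable):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        c, g = tune_hyperparams(dataset, labels, genes, seed=1)
        chrom = Chromosome(np.ones(len(genes), dtype=bool))
        assert cv_fitness(chrom, dataset, labels, genes, c, g, seed=1) >= 0.95

    def test_deterministic_choice(self, separable):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        assert tune_hyperparams(dataset, labels, genes, seed=5) == \
            tune_hyperparams(dataset, labels, genes, seed=5)

    def test_empty_grid_errors(self, separable):
        dataset, labels = separable
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparams(dataset, labels, dataset.expression.gene_ids,
                             grid=[])


class TestGa:
    def test_zero_iterations_returns_best_initial(self, separable):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        cfg = GaConfig(iterations=0, seed=2, cost_c=1.0, gamma_g=0.2)
        chrom, trace = ga_select(dataset, labels, genes, cfg)
        assert len(trace.generations) == 1
        assert trace.best_fitness[0] == trace.gen_best_fitness[0]

    def test_best_so_far_nondecreasing_and_deterministic(self, separable):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        cfg = GaConfig(iterations=15, seed=4, cost_c=1.0, gamma_g=0.2)
        chrom1, trace1 = ga_select(dataset, labels, genes, cfg)
        chrom2, trace2 = ga_select(dataset, labels, genes, cfg)
        best = trace1.best_fitness
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        np.testing.assert_array_equal(chrom1.bits, chrom2.bits)
        assert trace1.to_frame().equals(trace2.to_frame())

    def test_finds_separating_gene(self, separable):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        cfg = GaConfig(iterations=25, seed=0, cost_c=1.0, gamma_g=0.2,
                       parsimony=0.01)
        chrom, _ = ga_select(dataset, labels, genes, cfg)
        assert chrom.bits[0]  # g0 is the separating gene

    def test_empty_candidates_error(self, separable):
        dataset, labels = separable
        with pytest.raises(ValueError, match="empty"):
            ga_select(dataset, labels, [], GaConfig())

    def test_chromosome_needs_a_gene(self):
        with pytest.raises(ValueError, match="at least one"):
            Chromosome(np.zeros(4, dtype=bool))


class TestFinalModel:
    def _fit(self, separable, seed=0):
        dataset, labels = separable
        genes = dataset.expression.gene_ids
        chrom = Chromosome(np.array([1, 0, 0, 0, 0], dtype=bool))
        model = train_final_model(dataset, labels, chrom, genes,
                                  c=4.0, gamma=0.25, seed=seed)
        return dataset, labels, model

    def test_training_auc_perfect_on_separable_toy(self, separable):
        dataset, labels, model = self._fit(separable)
        scores = predict_scores(model, dataset)
        y = np.array([1 if l == "benefit" else 0 for l in labels])
        assert compute_auc(scores, y) == 1.0
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_benefit_point_scores_above_half(self, separable):
        dataset, labels, model = self._fit(separable)
        scores = predict_scores(model, dataset)
        assert scores[0] > 0.5          # deep in the benefit region
        assert scores[-1] < 0.5

    def test_refit_same_seed_identical(self, separable):
        d1, l1, m1 = self._fit(separable, seed=3)
        d2, l2, m2 = self._fit(separable, seed=3)
        assert m1.selected_genes == m2.selected_genes
        assert np.max(np.abs(predict_scores(m1, d1) -
                             predict_scores(m2, d1))) < 1e-9

    def test_roundtrip_preserves_scores(self, separable, tmp_path):
        dataset, labels, model = self._fit(separable)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert np.max(np.abs(predict_scores(model, dataset) -
                             predict_scores(back, dataset))) < 1e-9

    def test_patient_permutation_permutes_scores(self, separable):
        dataset, labels, model = self._fit(separable)
        scores = predict_scores(model, dataset)
        perm = list(reversed(dataset.sample_ids))
        permuted = predict_scores(model, dataset.subset(perm))
        np.testing.assert_allclose(permuted, scores[::-1], atol=1e-12)

    def test_missing_model_gene_listed(self, separable):
        dataset, labels, model = self._fit(separable)
        model.selected_genes = ["NOPE"]
        with pytest.raises(KeyError, match="NOPE"):
            predict_scores(model, dataset)

    def test_manual_decision_matches_sklearn(self, separable):
        from sklearn.svm import SVC

        dataset, labels, model = self._fit(separable)
        X, _, _ = build_features(dataset, model.selected_genes,
                                 include_stage=model.include_stage,
                                 means=model.feature_means,
                                 sds=model.feature_sds)
        y = np.array([1 if l == "benefit" else 0 for l in labels])
        svc = SVC(C=model.cost_c, gamma=model.gamma_g).fit(X, y)
        np.testing.assert_allclose(model.decision_values(X),
                                   svc.decision_function(X), atol=1e-9)
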