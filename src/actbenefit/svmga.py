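"""Genetic-algorithm wrapper feature selection around an RBF-SVM.

The classifier distinguishes benefit from futile patients. Feature subsets
(binary chromosomes over the candidate genes, TNM stage forced in by
default) are scored by 5-fold cross-validated AUC; the GA evolves them by
fitness-proportional selection, single-point crossover, one-bit mutation
and elitism. The best chromosome is refit on all labeled data with Platt
sigmoid calibration so the model emits a benefit probability per patient.

Cross-validated fitness is the expensive inner loop, so the engine
precomputes per-feature pairwise squared differences once; the RBF kernel
of any chromosome is then a weighted sum over that stack and the SVM is
fit with a precomputed kernel. Results are identical to refitting on raw
features, only much faster.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import CohortDataset, TrainedBenefitModel
from .labeling import BENEFIT

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- AUC

def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC; tied scores contribute half a concordance each."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUC")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


# ---------------------------------------------------------------- features

def encode_labels(labels) -> np.ndarray:
    """benefit -> 1, futile -> 0."""
    return np.asarray([1 if l == BENEFIT else 0 for l in labels], dtype=int)


def build_features(dataset: CohortDataset, genes: Sequence[str],
                   include_stage: bool = True,
                   means: Optional[Sequence[float]] = None,
                   sds: Optional[Sequence[float]] = None):
    """Samples x features matrix: z-scored expression (+ stage III flag).

    When ``means``/``sds`` are given (scoring with a trained model) they are
    applied; otherwise they are estimated from the data and returned.
    """
    idx = dataset.expression.gene_index(list(genes))
    X = dataset.expression.values[idx].T.astype(float)
    if means is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0)
        sds = np.where(sds == 0, 1.0, sds)
    else:
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
    Xz = (X - means) / sds
    if include_stage:
        stage = np.array([1.0 if r.tnm_stage == "III" else 0.0
                          for r in dataset.clinical])
        Xz = np.column_stack([Xz, stage])
    return Xz, np.asarray(means, dtype=float), np.asarray(sds, dtype=float)


def stratified_folds(sample_ids: Sequence[str], y: np.ndarray,
                     folds: int, seed: int):
    """Deterministic stratified folds, a pure function of (seed, ids, y).

    Fold assignment is computed on id-sorted order, so it is invariant to
    the row order of the input files. If a class has fewer members than
    ``folds`` the split count is reduced (never below 2).
    """
    y = np.asarray(y)
    min_class = int(min(np.bincount(y, minlength=2)))
    if min_class < 2:
        raise ValueError("need >= 2 members of each class for stratified CV")
    n_splits = min(folds, min_class)
    if n_splits < folds:
        logger.warning("stratified_folds: reducing folds %d -> %d", folds, n_splits)
    order = np.argsort(np.asarray(sample_ids, dtype=str))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**32))
    out = []
    for tr, te in skf.split(order[:, None], y[order]):
        out.append((np.sort(order[tr]), np.sort(order[te])))
    return out


# ---------------------------------------------------------------- GA types

@dataclass
class Chromosome:
    """Binary inclusion vector over the candidate genes."""

    bits: np.ndarray
    include_stage: bool = True

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1:
            raise ValueError("bits must be a 1-D binary vector")
        if not self.bits.any():
            raise ValueError("chromosome must select at least one gene")

    def selected(self, candidates: Sequence[str]) -> list:
        return [g for g, b in zip(candidates, self.bits) if b]


@dataclass
class GaConfig:
    population_size: int = 20
    p_crossover: float = 0.10
    p_mutation: float = 0.30
    iterations: int = 200
    cv_folds: int = 5
    seed: int = 0
    elitism: int = 1
    include_stage: bool = True
    cost_c: Optional[float] = None
    gamma_g: Optional[float] = None
    #: Fitness penalty per selected gene. 0 disables it; small positive
    #: values push the GA toward compact panels when the AUC surface is flat.
    parsimony: float = 0.0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")

    def hash(self) -> str:
        doc = json.dumps(dataclasses_dict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


def dataclasses_dict(cfg) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)


@dataclass
class GaTrace:
    """Per-generation fitness history of a GA run."""

    generations: list = field(default_factory=list)
    best_fitness: list = field(default_factory=list)      # best-so-far
    gen_best_fitness: list = field(default_factory=list)  # best in generation
    mean_fitness: list = field(default_factory=list)
    best_bits: list = field(default_factory=list)         # best-in-generation, "0101…"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "generation": self.generations,
            "best_fitness": self.best_fitness,
            "gen_best_fitness": self.gen_best_fitness,
            "mean_fitness": self.mean_fitness,
            "best_bits": self.best_bits,
        })


# ---------------------------------------------------------------- fitness

class FitnessEngine:
    """Cross-validated AUC fitness with a precomputed RBF-distance stack.

    For z-scored features x, the RBF kernel of a chromosome b is
    K = exp(-gamma * sum_{j in b} (x_ij - x_kj)^2), so the per-feature
    squared-difference matrices are computed once and any chromosome's
    kernel is a tensor contraction. SVMs are then fit per fold with
    ``kernel='precomputed'`` — numerically identical to refitting on the
    selected columns.
    """

    def __init__(self, dataset: CohortDataset, labels, candidates: Sequence[str],
                 include_stage: bool = True, folds: int = 5, seed: int = 0):
        self.candidates = list(candidates)
        self.include_stage = include_stage
        self.y = encode_labels(labels)
        X, self.means, self.sds = build_features(dataset, self.candidates,
                                                 include_stage=include_stage)
        self.X = X
        # per-feature pairwise squared differences (p_total x n x n)
        diffs = X.T[:, :, None] - X.T[:, None, :]
        self.D = diffs ** 2
        self.n_genes = len(self.candidates)
        self.folds = stratified_folds(dataset.sample_ids, self.y, folds, seed)
        self._cache: dict = {}
        self.n_evaluations = 0

    def _feature_mask(self, bits: np.ndarray) -> np.ndarray:
        mask = np.asarray(bits, dtype=bool)
        if self.include_stage:
            mask = np.append(mask, True)
        return mask

    def kernel(self, bits: np.ndarray, gamma: float) -> np.ndarray:
        mask = self._feature_mask(bits)
        return np.exp(-gamma * self.D[mask].sum(axis=0))

    def fitness(self, bits: np.ndarray, c: float, gamma: float) -> float:
        """Mean out-of-fold AUC of the RBF-SVM on the selected features."""
        bits = np.asarray(bits, dtype=bool)
        if not bits.any():
            raise ValueError("chromosome selects no features")
        key = (bits.tobytes(), float(c), float(gamma))
        if key in self._cache:
            return self._cache[key]
        K = self.kernel(bits, gamma)
        aucs = []
        for tr, te in self.folds:
            svc = SVC(C=c, kernel="precomputed")
            svc.fit(K[np.ix_(tr, tr)], self.y[tr])
            dec = svc.decision_function(K[np.ix_(te, tr)])
            aucs.append(compute_auc(dec, self.y[te]))
        value = float(np.mean(aucs))
        self._cache[key] = value
        self.n_evaluations += 1
        return value


def default_grid(n_features: int):
    """(c, gamma) grid around the libsvm-style gamma = 1/p heuristic."""
    base = 1.0 / max(n_features, 1)
    return [(c, g * base)
            for c in (0.25, 1.0, 4.0, 16.0)
            for g in (0.25, 0.5, 1.0, 2.0)]


def tune_hyperparams(dataset: CohortDataset, labels, features: Sequence[str],
                     grid=None, folds: int = 5, seed: int = 0,
                     include_stage: bool = True):
    """Grid search maximizing mean CV AUC; ties go to smaller c, then gamma."""
    features = list(features)
    if grid is None:
        grid = default_grid(len(features) + (1 if include_stage else 0))
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    engine = FitnessEngine(dataset, labels, features,
                           include_stage=include_stage, folds=folds, seed=seed)
    bits = np.ones(len(features), dtype=bool)
    best = None
    for c, g in sorted(grid):
        auc = engine.fitness(bits, c, g)
        if best is None or auc > best[0] + 1e-12:
            best = (auc, c, g)
    logger.info("tune_hyperparams: c=%g gamma=%g (CV AUC %.3f)",
                best[1], best[2], best[0])
    return best[1], best[2]


def cv_fitness(chromosome: Chromosome, dataset: CohortDataset, labels,
               candidates: Sequence[str], c: float, gamma: float,
               folds: int = 5, seed: int = 0) -> float:
    """Mean out-of-fold AUC for one chromosome (standalone convenience)."""
    engine = FitnessEngine(dataset, labels, list(candidates),
                           include_stage=chromosome.include_stage,
                           folds=folds, seed=seed)
    return engine.fitness(chromosome.bits, c, gamma)


# ---------------------------------------------------------------- GA

def _ensure_nonempty(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(len(bits))] = True
    return bits


def ga_select(dataset: CohortDataset, labels, candidates: Sequence[str],
              config: GaConfig):
    """Evolve gene subsets by cross-validated SVM AUC.

    Initial bits are on with probability 4/n_candidates (at least one bit
    per chromosome). Each generation: roulette-wheel parent selection,
    single-point crossover with probability ``p_crossover`` per pair,
    one-bit mutation with probability ``p_mutation`` per offspring, and the
    best individual carried over unchanged. Returns the best-ever
    chromosome and the full fitness trace.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate gene list is empty")
    rng = np.random.default_rng(config.seed)
    engine = FitnessEngine(dataset, labels, candidates,
                           include_stage=config.include_stage,
                           folds=config.cv_folds, seed=config.seed)
    c, gamma = config.cost_c, config.gamma_g
    if c is None or gamma is None:
        c, gamma = tune_hyperparams(dataset, labels, candidates,
                                    folds=config.cv_folds, seed=config.seed,
                                    include_stage=config.include_stage)
    m = len(candidates)
    p_on = min(1.0, 4.0 / m)
    pop = rng.random((config.population_size, m)) < p_on
    pop = np.array([_ensure_nonempty(row, rng) for row in pop])

    trace = GaTrace()
    best_bits, best_fit = None, -np.inf

    def adjusted(row, raw):
        return raw - config.parsimony * int(row.sum())

    def record(gen, fits):
        nonlocal best_bits, best_fit
        i = int(np.argmax(fits))
        if fits[i] > best_fit:
            best_fit = float(fits[i])
            best_bits = pop[i].copy()
        trace.generations.append(gen)
        trace.best_fitness.append(best_fit)
        trace.gen_best_fitness.append(float(fits[i]))
        trace.mean_fitness.append(float(np.mean(fits)))
        trace.best_bits.append("".join("1" if b else "0" for b in pop[i]))

    def evaluate(rows):
        return np.array([adjusted(row, engine.fitness(row, c, gamma))
                         for row in rows])

    fits = evaluate(pop)
    record(0, fits)

    for gen in range(1, config.iterations + 1):
        new_pop = []
        if config.elitism > 0:
            elite_idx = np.argsort(fits)[::-1][: config.elitism]
            new_pop.extend(pop[i].copy() for i in elite_idx)
        total = fits.sum()
        probs = fits / total if total > 0 else np.full(len(fits), 1.0 / len(fits))
        while len(new_pop) < config.population_size:
            pa, pb = rng.choice(len(pop), size=2, p=probs)
            ca, cb = pop[pa].copy(), pop[pb].copy()
            if rng.random() < config.p_crossover and m > 1:
                cut = int(rng.integers(1, m))
                ca = np.concatenate([pop[pa][:cut], pop[pb][cut:]])
                cb = np.concatenate([pop[pb][:cut], pop[pa][cut:]])
            for child in (ca, cb):
                if rng.random() < config.p_mutation:
                    j = int(rng.integers(m))
                    child[j] = ~child[j]
                new_pop.append(_ensure_nonempty(child, rng))
        pop = np.array(new_pop[: config.population_size])
        fits = evaluate(pop)
        record(gen, fits)

    chrom = Chromosome(best_bits, include_stage=config.include_stage)
    logger.info("ga_select: best fitness %.4f with %d genes after %d generations "
                "(%d distinct evaluations)", best_fit, int(best_bits.sum()),
                config.iterations, engine.n_evaluations)
    return chrom, trace


# ---------------------------------------------------------------- final model

def _fit_platt(decision: np.ndarray, y: np.ndarray):
    """Platt sigmoid P(benefit|f) = 1 / (1 + exp(A f + B)) by regularized MLE."""
    decision = np.asarray(decision, dtype=float)
    if np.ptp(decision) == 0:
        raise ValueError("calibration failure: decision values are degenerate")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        z = ab[0] * decision + ab[1]
        # log p = -log(1+e^z), log(1-p) = z - log(1+e^z)
        lse = np.logaddexp(0.0, z)
        return float(np.sum(t * lse - (1.0 - t) * (z - lse)))

    x0 = np.array([-1.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = scipy.optimize.minimize(nll, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12,
                                           "maxiter": 2000})
    return float(res.x[0]), float(res.x[1])


def train_final_model(dataset: CohortDataset, labels, chromosome: Chromosome,
                      candidates: Sequence[str], c: Optional[float] = None,
                      gamma: Optional[float] = None, folds: int = 5,
                      seed: int = 0, training_summary: Optional[dict] = None
                      ) -> TrainedBenefitModel:
    """Refit the selected panel on all labeled data, with Platt calibration.

    Hyperparameters are re-tuned on the final panel unless given. The
    calibration sigmoid is fit on out-of-fold decision values so it is not
    biased by resubstitution optimism.
    """
    genes = chromosome.selected(candidates)
    if not genes:
        raise ValueError("chromosome selects no genes")
    if c is None or gamma is None:
        c, gamma = tune_hyperparams(dataset, labels, genes, folds=folds,
                                    seed=seed, include_stage=chromosome.include_stage)
    y = encode_labels(labels)
    X, means, sds = build_features(dataset, genes,
                                   include_stage=chromosome.include_stage)
    svc = SVC(C=c, gamma=gamma, kernel="rbf")
    svc.fit(X, y)
    # out-of-fold decision values for calibration
    dec = np.empty(len(y))
    for tr, te in stratified_folds(dataset.sample_ids, y, folds, seed):
        cv_svc = SVC(C=c, gamma=gamma, kernel="rbf")
        cv_svc.fit(X[tr], y[tr])
        dec[te] = cv_svc.decision_function(X[te])
    a, b = _fit_platt(dec, y)
    summary = dict(training_summary or {})
    summary.setdefault("seed", seed)
    summary["cv_auc_decision"] = compute_auc(dec, y)
    model = TrainedBenefitModel(
        selected_genes=genes,
        include_stage=chromosome.include_stage,
        cost_c=float(c),
        gamma_g=float(gamma),
        feature_means=list(map(float, means)),
        feature_sds=list(map(float, sds)),
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_,
        intercept=float(svc.intercept_[0]),
        calibration={"A": a, "B": b},
        training_summary=summary,
    )
    return model


def predict_scores(model: TrainedBenefitModel, dataset: CohortDataset) -> np.ndarray:
    """Calibrated benefit probability in [0, 1] per patient."""
    missing = [g for g in model.selected_genes
               if g not in set(dataset.expression.gene_ids)]
    if missing:
        raise KeyError(f"model genes missing from expression matrix: {missing}")
    X, _, _ = build_features(dataset, model.selected_genes,
                             include_stage=model.include_stage,
                             means=model.feature_means, sds=model.feature_sds)
    return model.calibrated_scores(X)
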