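"""Synthetic stage II-III colorectal-cancer cohorts with a planted
treatment-modulating gene signal.

The generator emulates the statistical structure the pipeline assumes:
log2-scale expression with per-batch shifts, a small set of predictive
genes whose shared signal modulates the chemotherapy effect on relapse
hazard through a threshold (benefit only above the tau-th quantile of the
biomarker score), prognostic-only genes, stage-dependent treatment
assignment, and administrative censoring.

Default parameters mirror a merged stage II-III colorectal ACT cohort:
44% of patients treated and 43% stage III; a baseline exponential relapse
hazard of 0.02 per month (three-year relapse probability ~0.51 in the
untreated reference, in line with the 60-69% relapse seen in futile
strata); uniform administrative censoring on 40-100 months (median
follow-up ~70 months, as in an RNA-seq validation cohort); and a
stage-III treatment odds multiplier of 8 reflecting how strongly adjuvant
chemotherapy concentrates in stage III.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import ClinicalRecord, CohortDataset, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    n_patients: int = 400
    n_genes: int = 100
    n_predictive: int = 3
    n_prognostic: int = 5
    treat_fraction: float = 0.44
    stage3_fraction: float = 0.43
    baseline_hazard: float = 0.02          # per month
    beta_stage: float = 0.4                # log-HR of stage III
    beta_prog: float = 0.4                 # log-HR per SD of prognostic score
    alpha_treat: float = 0.25              # main treatment log-HR (net harm
                                           # outside the benefit stratum)
    gamma_interaction: float = -1.2        # extra treatment log-HR above tau
    tau: float = 0.7                       # benefit threshold quantile
    censor_min: float = 40.0               # months
    censor_max: float = 100.0
    n_batches: int = 3
    batch_shift: float = 1.0
    stage_act_odds: float = 8.0            # treatment odds multiplier, stage III

    def __post_init__(self):
        for name in ("treat_fraction", "stage3_fraction", "tau"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_predictive + self.n_prognostic > self.n_genes:
            raise ValueError("n_predictive + n_prognostic exceeds n_genes")
        if self.censor_max <= 36.0:
            raise ValueError("censor_max must exceed 36 months")
        if self.censor_min >= self.censor_max:
            raise ValueError("censor_min must be below censor_max")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class SyntheticTruth:
    predictive_genes: list
    prognostic_genes: list
    benefit: np.ndarray            # per-patient true benefit indicator
    biomarker: np.ndarray          # standardized predictive-gene score
    hazard: np.ndarray             # realized per-patient relapse hazard
    threshold_value: float         # biomarker value at the tau quantile


def _standardized_mean(rows: np.ndarray) -> np.ndarray:
    z = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, keepdims=True)
    s = z.mean(axis=0)
    return (s - s.mean()) / s.std()


def generate_cohort(config: SyntheticConfig, seed: int):
    """Draw one cohort; byte-identical for identical (config, seed)."""
    rng = np.random.default_rng(seed)
    n, g = config.n_patients, config.n_genes
    gene_ids = [f"G{i:04d}" for i in range(g)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    special = rng.choice(g, size=config.n_predictive + config.n_prognostic,
                         replace=False)
    pred_idx = np.sort(special[: config.n_predictive])
    prog_idx = np.sort(special[config.n_predictive:])

    baseline = rng.uniform(4.0, 10.0, size=g)
    signal = baseline[:, None] + rng.normal(0.0, 1.0, size=(g, n))

    biomarker = _standardized_mean(signal[pred_idx]) if config.n_predictive \
        else np.zeros(n)
    prognostic = _standardized_mean(signal[prog_idx]) if config.n_prognostic \
        else np.zeros(n)
    threshold_value = float(np.quantile(biomarker, config.tau))
    benefit = biomarker > threshold_value

    stage3 = rng.random(n) < config.stage3_fraction
    base_logit = np.log(config.treat_fraction / (1 - config.treat_fraction))
    logit = base_logit + np.log(config.stage_act_odds) * \
        (stage3.astype(float) - config.stage3_fraction)
    act = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    log_hr = (config.beta_stage * stage3
              + config.beta_prog * prognostic
              + act * (config.alpha_treat + config.gamma_interaction * benefit))
    hazard = config.baseline_hazard * np.exp(log_hr)
    relapse_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(config.censor_min, config.censor_max, size=n)
    rfs = np.minimum(relapse_time, censor_time)
    event = relapse_time <= censor_time

    batch = rng.integers(0, config.n_batches, size=n)
    shift = config.batch_shift * (batch - (config.n_batches - 1) / 2.0)
    observed = signal + shift[None, :]

    age = np.clip(np.round(rng.normal(66.0, 10.0, size=n)), 30, 92)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    site = np.where(rng.random(n) < 0.92, "colon", "rectum")
    n_stage = np.where(stage3, np.where(rng.random(n) < 0.6, "N1", "N2"), "N0")
    t_stage = rng.choice(["T2", "T3", "T4"], size=n, p=[0.2, 0.65, 0.15])

    records = [
        ClinicalRecord(
            sample_id=sample_ids[i],
            act=bool(act[i]),
            rfs_months=float(np.round(rfs[i], 3)),
            relapse_event=bool(event[i]),
            tnm_stage="III" if stage3[i] else "II",
            age_years=float(age[i]),
            sex=str(sex[i]),
            t_stage=str(t_stage[i]),
            n_stage=str(n_stage[i]),
            site=str(site[i]),
            batch=f"B{batch[i]}",
        )
        for i in range(n)
    ]
    expr = ExpressionMatrix(gene_ids, sample_ids, observed, scale="log2")
    dataset = CohortDataset(expr, records)
    truth = SyntheticTruth(
        predictive_genes=[gene_ids[i] for i in pred_idx],
        prognostic_genes=[gene_ids[i] for i in prog_idx],
        benefit=benefit,
        biomarker=biomarker,
        hazard=hazard,
        threshold_value=threshold_value,
    )
    return dataset, truth


def analytic_censoring_fraction(hazards, c_min: float, c_max: float) -> float:
    """E[P(censored)] for exponential event times vs Uniform(c_min, c_max)
    administrative censoring: mean over patients of
    (exp(-h c_min) - exp(-h c_max)) / (h (c_max - c_min))."""
    h = np.asarray(hazards, dtype=float)
    return float(np.mean((np.exp(-h * c_min) - np.exp(-h * c_max))
                         / (h * (c_max - c_min))))


# ------------------------------------------------------------ end-to-end

@dataclass
class EndToEndSettings:
    """Pipeline settings for the recovery experiment."""

    n_train: int = 400
    deg_alpha: float = 0.05
    deg_fallback_top: int = 10    # candidates when nothing passes alpha
    label_threshold: float = 36.0
    ga: Optional[object] = None   # GaConfig; defaults applied in run
    stepp_n2: Optional[int] = None
    stepp_n1: Optional[int] = None


def end_to_end_recovery(config: SyntheticConfig, settings: EndToEndSettings,
                        seed: int) -> dict:
    """Run label -> screen -> GA-SVM -> STEPP -> validation on a split.

    Generates one cohort, batch-corrects it, trains on ``n_train`` patients
    and evaluates on the rest. Reports predictive-gene recall of the
    selected panel, the train-score quantile error of the recovered STEPP
    cutoff relative to the planted threshold quantile tau, and the Wald p
    of the treatment x predicted-group interaction on the held-out half.
    """
    from . import stepp as stepp_mod
    from .deg import wilcoxon_screen
    from .labeling import label_cohort
    from .preprocess import combat_adjust
    from .survstats import interaction_pvalue
    from .svmga import GaConfig, ga_select, predict_scores, train_final_model

    rng = np.random.default_rng(seed)
    dataset, truth = generate_cohort(config, seed)
    if config.n_batches > 1:
        adj = combat_adjust(dataset.expression,
                            [r.batch for r in dataset.clinical])
        dataset = CohortDataset(adj, dataset.clinical)
    perm = rng.permutation(dataset.n_samples)
    ids = np.array(dataset.sample_ids)
    train_ids = sorted(ids[perm[: settings.n_train]])
    test_ids = sorted(ids[perm[settings.n_train:]])
    if not test_ids:
        raise ValueError("no held-out samples: reduce n_train")
    train = dataset.subset(train_ids)
    test = dataset.subset(test_ids)

    labeled = label_cohort(train, settings.label_threshold)
    deg = wilcoxon_screen(labeled.dataset.expression, labeled.labels,
                          alpha=settings.deg_alpha)
    candidates = deg.candidate_genes
    if not candidates:
        logger.warning("end_to_end_recovery: no gene passed alpha=%g; "
                       "falling back to top %d by p",
                       settings.deg_alpha, settings.deg_fallback_top)
        candidates = deg.table["gene"].head(settings.deg_fallback_top).tolist()

    ga_cfg = settings.ga or GaConfig(seed=seed)
    ga_cfg = replace(ga_cfg, seed=seed)
    chrom, trace = ga_select(labeled.dataset, labeled.labels, candidates, ga_cfg)
    model = train_final_model(labeled.dataset, labeled.labels, chrom,
                              candidates, folds=ga_cfg.cv_folds, seed=seed)
    selected = set(model.selected_genes)
    recall = (len(selected & set(truth.predictive_genes))
              / max(len(truth.predictive_genes), 1))

    train_scores = predict_scores(model, train)
    test_scores = predict_scores(model, test)
    n2, n1 = settings.stepp_n2, settings.stepp_n1
    if n2 is None:
        n2, n1 = stepp_mod.default_window_sizes(train.n_samples)
    profile = stepp_mod.stepp_profile(train, train_scores, n2, n1)
    cutoff = stepp_mod.select_cutoff(profile)

    report = {
        "seed": seed,
        "n_candidates": len(candidates),
        "selected_genes": sorted(selected),
        "predictive_genes": truth.predictive_genes,
        "recall": recall,
        "ga_best_fitness": trace.best_fitness[-1],
        "cutoff": cutoff,
    }
    if cutoff is None:
        report["cutoff_quantile_error"] = np.nan
        report["interaction_p"] = np.nan
        return report
    report["cutoff_quantile_error"] = abs(
        float(np.mean(train_scores <= cutoff)) - config.tau)
    groups = stepp_mod.stratify_patients(test_scores, cutoff)
    group01 = (groups == "predicted-benefit").astype(float)
    act = np.array([r.act for r in test.clinical], dtype=float)
    times = np.array([r.rfs_months for r in test.clinical])
    events = np.array([r.relapse_event for r in test.clinical], dtype=bool)
    try:
        adjusters = pd.DataFrame({"stage3": [
            1.0 if r.tnm_stage == "III" else 0.0 for r in test.clinical]})
        report["interaction_p"] = interaction_pvalue(act, group01, adjusters,
                                                     times, events)
    except (ValueError, RuntimeError) as exc:
        logger.warning("end_to_end_recovery: interaction undefined (%s)", exc)
        report["interaction_p"] = np.nan
    return report


def write_cohort(dataset: CohortDataset, truth: SyntheticTruth, out_dir) -> None:
    """Write expression TSV, clinical CSV and truth CSV for CLI use."""
    from pathlib import Path

    from .io import write_clinical, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.expression, out / "expression.tsv")
    write_clinical(dataset.clinical, out / "clinical.csv")
    pd.DataFrame({
        "sample_id": dataset.sample_ids,
        "true_benefit": truth.benefit.astype(int),
        "biomarker": truth.biomarker,
        "hazard": truth.hazard,
    }).to_csv(out / "truth.csv", index=False)
    pd.DataFrame({
        "gene": truth.predictive_genes + truth.prognostic_genes,
        "role": (["predictive"] * len(truth.predictive_genes)
                 + ["prognostic"] * len(truth.prognostic_genes)),
    }).to_csv(out / "truth_genes.csv", index=False)


def direct_benefit_labels(truth: SyntheticTruth, flip_prob: float = 0.15,
                          seed: int = 0) -> list:
    """Benefit/futile labels driven directly by the planted gene signal.

    Used by wrapper-selection recovery experiments: the label is "benefit"
    iff the biomarker score exceeds its planted threshold, with independent
    flip noise. This isolates the gene-selection machinery from the
    survival-mediated labeling path (which the end-to-end experiment
    exercises instead).
    """
    from .labeling import BENEFIT, FUTILE

    rng = np.random.default_rng(seed)
    base = truth.biomarker > truth.threshold_value
    flips = rng.random(base.size) < flip_prob
    return [BENEFIT if b else FUTILE for b in (base ^ flips)]
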