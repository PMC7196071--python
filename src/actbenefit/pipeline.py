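"""End-to-end pipeline orchestration with a single config and one master seed.

``run_pipeline`` chains labeling, the rank-sum gene screen, GA-SVM model
fitting, STEPP cutoff selection, patient stratification and survival
validation over one cohort, writing every intermediate artifact plus a
manifest of content hashes. All stage randomness derives deterministically
from the master seed, so a rerun with the same config and inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import stepp as stepp_mod
from .deg import wilcoxon_screen
from .io import CohortDataset, align_cohort, read_clinical, read_expression, save_model
from .labeling import label_cohort
from .survstats import interaction_pvalue, km_rfs_comparison
from .svmga import GaConfig, ga_select, predict_scores, train_final_model

logger = logging.getLogger(__name__)

ARTIFACTS = ("labels.csv", "deg.csv", "model.json", "ga_trace.csv",
             "stepp.csv", "stratification.csv", "validation.csv",
             "manifest.json")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception, hint: str = ""):
        self.stage = stage
        msg = f"pipeline stage '{stage}' failed: {exc}"
        if hint:
            msg += f" ({hint})"
        super().__init__(msg)


@dataclass
class PipelineConfig:
    seed: int
    expression_path: Optional[str] = None
    clinical_path: Optional[str] = None
    batch_correct: bool = False
    label_threshold: float = 36.0
    exclusion_policy: str = "censored-early"
    deg_alpha: float = 0.001
    deg_fallback_top: int = 10
    ga: dict = field(default_factory=dict)
    stepp_n2: Optional[int] = None
    stepp_n1: Optional[int] = None
    cutoff_override: Optional[float] = None
    adjust_covariates: tuple = ("age", "sex", "stage")

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must set a seed (reproducibility is enforced)")
        self.seed = int(self.seed)
        unknown = set(self.adjust_covariates) - {"age", "sex", "stage"}
        if unknown:
            raise ValueError(f"unknown adjustment covariates: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in doc:
            raise ValueError(f"{path}: config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "adjust_covariates" in doc:
            doc["adjust_covariates"] = tuple(doc["adjust_covariates"])
        return cls(**doc)

    def ga_config(self, seed: int) -> GaConfig:
        return GaConfig(seed=seed, **self.ga)


def stage_seed(master: int, index: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    state = np.random.SeedSequence(master).generate_state(index + 1)
    return int(state[index] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _adjuster_frame(clinical, which) -> pd.DataFrame:
    cols = {}
    if "age" in which:
        ages = [r.age_years for r in clinical]
        if all(a is not None for a in ages):
            from .psmatch import age_category
            cat = pd.Series([age_category(a) for a in ages])
            for c, v in pd.get_dummies(cat, prefix="age", drop_first=True).items():
                cols[c] = v.astype(float).to_numpy()
        else:
            logger.warning("age adjustment skipped: missing values")
    if "sex" in which:
        sexes = [r.sex for r in clinical]
        if all(s is not None for s in sexes):
            cols["sex_male"] = np.array([1.0 if s == "male" else 0.0 for s in sexes])
        else:
            logger.warning("sex adjustment skipped: missing values")
    if "stage" in which:
        cols["stage3"] = np.array([1.0 if r.tnm_stage == "III" else 0.0
                                   for r in clinical])
    return pd.DataFrame(cols)


def run_pipeline(config: PipelineConfig, out_dir,
                 dataset: Optional[CohortDataset] = None) -> Path:
    """Run all stages; returns the artifact directory.

    ``dataset`` may be passed directly (e.g. a synthetic cohort); otherwise
    the configured expression/clinical paths are read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        if not (config.expression_path and config.clinical_path):
            raise PipelineError("load", ValueError(
                "config must give expression_path and clinical_path, "
                "or pass a dataset"))
        try:
            expr = read_expression(config.expression_path)
            clin = read_clinical(config.clinical_path)
            dataset = align_cohort(expr, clin)
        except Exception as exc:
            raise PipelineError("load", exc, "check input file formats") from exc

    if config.batch_correct:
        from .preprocess import combat_adjust
        try:
            batches = [r.batch for r in dataset.clinical]
            if any(b is None for b in batches):
                raise ValueError("batch correction requires a batch per sample")
            adj = combat_adjust(dataset.expression, batches)
            dataset = CohortDataset(adj, dataset.clinical)
        except Exception as exc:
            raise PipelineError("preprocess", exc) from exc

    try:
        labeled = label_cohort(dataset, config.label_threshold,
                               config.exclusion_policy)
    except Exception as exc:
        raise PipelineError("label", exc, "check rfs/relapse/act columns") from exc
    pd.DataFrame({"sample_id": labeled.dataset.sample_ids,
                  "label": labeled.labels}).to_csv(out / "labels.csv", index=False)

    try:
        deg = wilcoxon_screen(labeled.dataset.expression, labeled.labels,
                              alpha=config.deg_alpha)
    except Exception as exc:
        raise PipelineError("screen", exc) from exc
    deg.table.to_csv(out / "deg.csv", index=False)
    candidates = deg.candidate_genes
    if not candidates:
        logger.warning("no gene passed alpha=%g; using top %d by p",
                       config.deg_alpha, config.deg_fallback_top)
        candidates = deg.table["gene"].head(config.deg_fallback_top).tolist()

    ga_cfg = config.ga_config(stage_seed(config.seed, 1))
    try:
        chrom, trace = ga_select(labeled.dataset, labeled.labels, candidates, ga_cfg)
        model = train_final_model(labeled.dataset, labeled.labels, chrom,
                                  candidates, folds=ga_cfg.cv_folds,
                                  seed=stage_seed(config.seed, 2),
                                  training_summary={"seed": config.seed})
    except Exception as exc:
        raise PipelineError("train", exc) from exc
    trace.to_frame().to_csv(out / "ga_trace.csv", index=False)

    scores = predict_scores(model, dataset)
    n2, n1 = config.stepp_n2, config.stepp_n1
    if n2 is None:
        n2, n1 = stepp_mod.default_window_sizes(dataset.n_samples)
    try:
        profile = stepp_mod.stepp_profile(dataset, scores, n2, n1)
    except Exception as exc:
        raise PipelineError("stepp", exc) from exc
    profile.to_frame().to_csv(out / "stepp.csv", index=False)
    cutoff = config.cutoff_override
    if cutoff is None:
        cutoff = stepp_mod.select_cutoff(profile)
    if cutoff is None:
        raise PipelineError("stepp", ValueError(
            "no STEPP cutoff satisfies the HR<1 criterion"),
            "set cutoff_override to impose one")
    model.cutoff = float(cutoff)
    save_model(model, out / "model.json")

    groups = stepp_mod.stratify_patients(scores, cutoff)
    pd.DataFrame({"sample_id": dataset.sample_ids,
                  "score": np.round(scores, 10),
                  "group": groups}).to_csv(out / "stratification.csv", index=False)

    times = np.array([r.rfs_months for r in dataset.clinical])
    events = np.array([r.relapse_event for r in dataset.clinical], dtype=bool)
    act = np.array([r.act for r in dataset.clinical], dtype=bool)
    rows = []
    for gname in ("predicted-benefit", "predicted-futile"):
        mask = groups == gname
        if mask.sum() and 0 < act[mask].sum() < mask.sum():
            try:
                rows.append(km_rfs_comparison(times[mask], events[mask],
                                              act[mask], label=gname))
            except (ValueError, RuntimeError) as exc:
                logger.warning("validation in %s undefined: %s", gname, exc)
    group01 = (groups == "predicted-benefit").astype(float)
    inter = {"label": "interaction"}
    try:
        inter["p_unadjusted"] = interaction_pvalue(
            act.astype(float), group01, None, times, events)
        adj = _adjuster_frame(dataset.clinical, config.adjust_covariates)
        inter["p_adjusted"] = interaction_pvalue(
            act.astype(float), group01, adj, times, events)
    except (ValueError, RuntimeError) as exc:
        logger.warning("interaction test undefined: %s", exc)
    rows.append(inter)
    pd.DataFrame(rows).to_csv(out / "validation.csv", index=False)

    manifest = {
        "seed": config.seed,
        "cutoff": float(cutoff),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "artifacts": {name: _sha256(out / name) for name in ARTIFACTS
                      if name != "manifest.json" and (out / name).exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
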