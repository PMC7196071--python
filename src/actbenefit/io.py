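"""Data model and file I/O shared by all pipeline stages.

Expression matrices travel as tab-separated text with genes in rows
(microarray convention); clinical tables as CSV with one row per patient.
Trained models serialize to a versioned JSON document that is sufficient to
reproduce predictions without refitting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Clinical CSV columns that must be present.
MANDATORY_CLINICAL_COLUMNS = (
    "sample_id",
    "act",
    "rfs_months",
    "relapse_event",
    "tnm_stage",
)

#: Optional columns parsed into typed fields; anything else is kept as a
#: categorical extra.
OPTIONAL_CLINICAL_COLUMNS = (
    "age_years",
    "sex",
    "t_stage",
    "n_stage",
    "site",
    "grade",
    "race",
    "batch",
)


class ModelFormatError(ValueError):
    """Raised when a serialized model document cannot be interpreted."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers (probes before collapsing, genes after).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values.
    scale : {"raw", "log2"}
        Whether values are on the raw (intensity/FPKM) or log2 scale.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    scale: str = "log2"

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            self.gene_ids, list(sample_ids), self.values[:, idx], self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClinicalRecord:
    """One patient's treatment, outcome and covariates.

    ``act`` is True when the patient received 5-FU-based adjuvant
    chemotherapy; ``rfs_months`` / ``relapse_event`` encode right-censored
    relapse-free survival; ``tnm_stage`` is restricted to the II/III
    population the model is defined on.
    """

    sample_id: str
    act: bool
    rfs_months: float
    relapse_event: bool
    tnm_stage: str
    age_years: Optional[float] = None
    sex: Optional[str] = None
    t_stage: Optional[str] = None
    n_stage: Optional[str] = None
    site: Optional[str] = None
    grade: Optional[str] = None
    race: Optional[str] = None
    batch: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rfs_months < 0:
            raise ValueError(
                f"sample {self.sample_id}: rfs_months must be >= 0, "
                f"got {self.rfs_months}"
            )
        if self.tnm_stage not in ("II", "III"):
            raise ValueError(
                f"sample {self.sample_id}: tnm_stage must be 'II' or 'III' "
                f"(model population), got {self.tnm_stage!r}"
            )
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(
                f"sample {self.sample_id}: sex must be 'male'/'female', "
                f"got {self.sex!r}"
            )


@dataclass
class CohortDataset:
    """Aligned expression matrix + clinical records (same samples, same order)."""

    expression: ExpressionMatrix
    clinical: list

    def __post_init__(self):
        expr_ids = list(self.expression.sample_ids)
        clin_ids = [r.sample_id for r in self.clinical]
        if expr_ids != clin_ids:
            raise ValueError(
                "CohortDataset requires expression sample order to match "
                "clinical record order; use align_cohort() first"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.expression.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.clinical:
            d = {f.name: getattr(r, f.name) for f in dataclasses.fields(r) if f.name != "extras"}
            d.update(r.extras)
            rows.append(d)
        return pd.DataFrame(rows).set_index("sample_id", drop=False)

    def subset(self, sample_ids: Sequence[str]) -> "CohortDataset":
        """Subset to the given samples, in the given order."""
        by_id = {r.sample_id: r for r in self.clinical}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise KeyError(f"samples absent from cohort: {missing}")
        clin = [by_id[s] for s in sample_ids]
        return CohortDataset(self.expression.subset_samples(list(sample_ids)), clin)


def align_cohort(expression: ExpressionMatrix, clinical: Sequence[ClinicalRecord]) -> CohortDataset:
    """Intersect expression and clinical sample ids into an aligned dataset.

    Samples present on only one side are dropped with a logged warning.
    Alignment order is the clinical record order restricted to shared ids,
    so shuffling the expression columns does not change the result.
    """
    expr_ids = set(expression.sample_ids)
    clin_sorted = sorted(clinical, key=lambda r: r.sample_id)
    shared = [r for r in clin_sorted if r.sample_id in expr_ids]
    dropped_clin = [r.sample_id for r in clin_sorted if r.sample_id not in expr_ids]
    shared_ids = {r.sample_id for r in shared}
    dropped_expr = [s for s in expression.sample_ids if s not in shared_ids]
    if dropped_clin:
        logger.warning("align_cohort: %d clinical samples without expression dropped: %s",
                       len(dropped_clin), dropped_clin[:10])
    if dropped_expr:
        logger.warning("align_cohort: %d expression samples without clinical dropped: %s",
                       len(dropped_expr), dropped_expr[:10])
    if not shared:
        raise ValueError("no overlap between expression and clinical sample ids")
    order = [r.sample_id for r in shared]
    return CohortDataset(expression.subset_samples(order), shared)


def read_expression(path, genes_in_rows: bool = True, scale: str = "log2") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = gene id, header = samples).

    ``genes_in_rows=False`` flips the orientation (samples in rows).
    Duplicate gene ids are a hard error: collapsing replicate probes is an
    explicit preprocessing step, not an I/O side effect.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if not genes_in_rows:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
    if dupes:
        raise ValueError(
            f"{path}: duplicate gene ids {dupes[:5]} — collapse probes explicitly"
        )
    values = np.empty(df.shape, dtype=float)
    for j, s in enumerate(sample_ids):
        col = pd.to_numeric(df.iloc[:, j], errors="coerce")
        bad = np.nonzero(~np.isfinite(col.to_numpy(dtype=float)))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric value {df.iloc[i, j]!r} for gene "
                f"{gene_ids[i]!r}, sample {s!r}"
            )
        values[:, j] = col.to_numpy(dtype=float)
    return ExpressionMatrix(gene_ids, sample_ids, values, scale=scale)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def _parse_bool(value, column, sample):
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"sample {sample}: cannot parse {column}={value!r} as 0/1")


def read_clinical(path) -> list:
    """Read the clinical CSV into typed :class:`ClinicalRecord` objects.

    Mandatory columns: sample_id, act, rfs_months, relapse_event, tnm_stage.
    Optional typed columns are kept missing when empty (never imputed);
    unknown columns are preserved in ``record.extras``.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANDATORY_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory clinical columns: {missing}")
    extra_cols = [c for c in df.columns
                  if c not in MANDATORY_CLINICAL_COLUMNS and c not in OPTIONAL_CLINICAL_COLUMNS]
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        kwargs = dict(
            sample_id=sid,
            act=_parse_bool(row["act"], "act", sid),
            rfs_months=float(row["rfs_months"]),
            relapse_event=_parse_bool(row["relapse_event"], "relapse_event", sid),
            tnm_stage=str(row["tnm_stage"]).strip(),
        )
        for col in OPTIONAL_CLINICAL_COLUMNS:
            if col in df.columns and pd.notna(row[col]) and str(row[col]).strip() != "":
                val = str(row[col]).strip()
                kwargs[col] = float(val) if col == "age_years" else val
        extras = {c: str(row[c]) for c in extra_cols if pd.notna(row[c])}
        records.append(ClinicalRecord(extras=extras, **kwargs))
    return records


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    rows = []
    for r in records:
        d = {
            "sample_id": r.sample_id,
            "act": int(r.act),
            "rfs_months": r.rfs_months,
            "relapse_event": int(r.relapse_event),
            "tnm_stage": r.tnm_stage,
        }
        for col in OPTIONAL_CLINICAL_COLUMNS:
            v = getattr(r, col)
            if v is not None:
                d[col] = v
        d.update(r.extras)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class TrainedBenefitModel:
    """A fitted benefit classifier: gene panel + RBF-SVM + Platt calibration.

    The model stores everything needed to score new patients exactly:
    the selected genes, z-scoring statistics from training, the support
    vectors / dual coefficients / intercept of the RBF-SVM in that
    standardized feature space, the sigmoid calibration (A, B) mapping
    decision values to benefit probabilities, and the STEPP-derived score
    cutoff once one has been chosen.
    """

    selected_genes: list
    include_stage: bool
    cost_c: float
    gamma_g: float
    feature_means: list
    feature_sds: list
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    calibration: dict          # {"A": float, "B": float}
    training_summary: dict = field(default_factory=dict)
    cutoff: Optional[float] = None

    def __post_init__(self):
        if not self.selected_genes:
            raise ValueError("selected_genes must be non-empty")
        if not self.cost_c > 0:
            raise ValueError("cost_c must be > 0")
        if not self.gamma_g > 0:
            raise ValueError("gamma_g must be > 0")
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()

    @property
    def n_features(self) -> int:
        return len(self.selected_genes) + (1 if self.include_stage else 0)

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        """RBF decision function on standardized features (n x p)."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        d2 = ((features[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma_g * d2) @ self.dual_coef + self.intercept

    def calibrated_scores(self, features: np.ndarray) -> np.ndarray:
        f = self.decision_values(features)
        a, b = self.calibration["A"], self.calibration["B"]
        return 1.0 / (1.0 + np.exp(a * f + b))


def save_model(model: TrainedBenefitModel, path) -> None:
    doc = {
        "format": "actbenefit-model",
        "format_version": MODEL_FORMAT_VERSION,
        "selected_genes": model.selected_genes,
        "include_stage": model.include_stage,
        "cost_c": model.cost_c,
        "gamma_g": model.gamma_g,
        "feature_means": list(map(float, model.feature_means)),
        "feature_sds": list(map(float, model.feature_sds)),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": float(model.intercept),
        "calibration": {k: float(v) for k, v in model.calibration.items()},
        "training_summary": model.training_summary,
        "cutoff": model.cutoff,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> TrainedBenefitModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not a valid model document ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != "actbenefit-model":
        raise ModelFormatError(f"{path}: not an actbenefit model document")
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {version} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedBenefitModel(
        selected_genes=doc["selected_genes"],
        include_stage=doc["include_stage"],
        cost_c=doc["cost_c"],
        gamma_g=doc["gamma_g"],
        feature_means=doc["feature_means"],
        feature_sds=doc["feature_sds"],
        support_vectors=np.array(doc["support_vectors"], dtype=float),
        dual_coef=np.array(doc["dual_coef"], dtype=float),
        intercept=float(doc["intercept"]),
        calibration=doc["calibration"],
        training_summary=doc.get("training_summary", {}),
        cutoff=doc.get("cutoff"),
    )
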