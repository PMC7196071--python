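"""Expression preprocessing: quantile normalization, log2, probe collapsing,
low-expression filtering, and ComBat batch correction.

The order used for merged microarray cohorts is: quantile-normalize raw
intensities within cohort, log2-transform, collapse probes to genes, then
ComBat across cohorts. For RNA-seq (FPKM) the zero-expression filter runs
before the log transform.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the across-sample mean distribution.

    After normalization each column's sorted values equal the mean of the
    per-sample sorted value vectors; within-sample rank order is preserved.
    Ties within a sample receive the average of the tied target values.
    """
    if matrix.n_samples < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids,
                                matrix.values.copy(), matrix.scale)
    values = matrix.values
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        # average rank -> linear interpolation over target handles ties as
        # "average of tied target values"
        ranks = scipy.stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, len(target) + 1), target)
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, out, matrix.scale)


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """v -> log2(v + offset). Requires raw-scale, non-negative values."""
    if matrix.scale != "raw":
        raise ValueError("log2_transform expects a raw-scale matrix")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if np.any(matrix.values < 0):
        raise ValueError("negative expression values cannot be log-transformed")
    shifted = matrix.values + offset
    if np.any(shifted <= 0):
        raise ValueError("log2 of zero: use a positive offset for zero values")
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids,
                            np.log2(shifted), scale="log2")


def read_probe_map(path) -> dict:
    """2-column TSV (probe, gene) -> dict. Unmapped probes simply absent."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    if df["probe"].duplicated().any():
        dupes = df.loc[df["probe"].duplicated(), "probe"].tolist()
        raise ValueError(f"probe map has duplicate probe ids: {dupes[:5]}")
    return dict(zip(df["probe"], df["gene"]))


def collapse_probes(matrix: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Average replicate probes per gene; drop probes without a mapping."""
    mapped = [(p, probe_map[p]) for p in matrix.gene_ids if p in probe_map]
    if not mapped:
        raise ValueError("no probe in the matrix appears in the probe map")
    n_dropped = matrix.n_genes - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    genes = sorted({g for _, g in mapped})
    gene_pos = {g: i for i, g in enumerate(genes)}
    probe_idx = matrix.gene_index([p for p, _ in mapped])
    sums = np.zeros((len(genes), matrix.n_samples))
    counts = np.zeros(len(genes))
    for (probe, gene), row in zip(mapped, probe_idx):
        sums[gene_pos[gene]] += matrix.values[row]
        counts[gene_pos[gene]] += 1
    return ExpressionMatrix(genes, matrix.sample_ids,
                            sums / counts[:, None], matrix.scale)


def filter_low_expression(matrix: ExpressionMatrix, zero_fraction: float = 0.5):
    """Drop genes that are exactly zero in >= ``zero_fraction`` of samples.

    Intended for raw FPKM matrices from sequencing cohorts. Returns the
    filtered matrix and the number of genes removed.
    """
    if matrix.scale != "raw":
        raise ValueError("filter_low_expression expects raw (FPKM) values")
    zero_prop = (matrix.values == 0).mean(axis=1)
    keep = zero_prop < zero_fraction
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_low_expression: removed %d / %d genes", removed, matrix.n_genes)
    kept_genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(kept_genes, matrix.sample_ids,
                            matrix.values[keep], matrix.scale), removed


def combat_adjust(matrix: ExpressionMatrix, batch) -> ExpressionMatrix:
    """Parametric empirical-Bayes (ComBat) location/scale batch adjustment.

    ``batch`` is a per-sample categorical label sequence aligned to
    ``matrix.sample_ids``. No biological covariates are used. The actual
    adjustment is the standard published estimator as implemented in
    scanpy (numerically equivalent to Bioconductor's sva::ComBat).
    """
    batch = np.asarray([str(b) for b in batch])
    if len(batch) != matrix.n_samples:
        raise ValueError("batch labels must align with samples")
    levels, counts = np.unique(batch, return_counts=True)
    if len(levels) == 1:
        logger.warning("combat_adjust: single batch, returning input unchanged")
        return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids,
                                matrix.values.copy(), matrix.scale)
    small = levels[counts < 2]
    if small.size:
        raise ValueError(f"batches with fewer than 2 samples: {list(small)}")
    import anndata

    adata = anndata.AnnData(
        X=matrix.values.T.copy(),
        obs=pd.DataFrame({"batch": pd.Categorical(batch)},
                         index=matrix.sample_ids),
    )
    import scanpy

    scanpy.pp.combat(adata, key="batch")
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids,
                            np.asarray(adata.X).T, matrix.scale)
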