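"""Relative-expression-ordering (REO) gene-pair risk classifier.

A signature is a list of ordered gene pairs with the convention that
expression(gene_a) > expression(gene_b) within a patient votes "high
risk". A patient is high risk when at least ``vote_threshold`` of the
usable pairs vote high. Because only within-patient orderings matter, the
call is invariant to any monotone per-patient transformation of the data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"


def read_signature(path) -> list:
    """2-column TSV (gene_a, gene_b) -> list of pairs."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"],
                     dtype=str, comment="#")
    pairs = [(a.strip(), b.strip()) for a, b in zip(df["gene_a"], df["gene_b"])]
    return validate_signature(pairs)


def validate_signature(pairs) -> list:
    seen = set()
    out = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"signature pair ({a}, {b}) repeats the same gene")
        if (a, b) in seen:
            raise ValueError(f"duplicate signature pair ({a}, {b})")
        seen.add((a, b))
        out.append((a, b))
    if not out:
        raise ValueError("empty signature")
    return out


def classify_reo(matrix: ExpressionMatrix, signature, vote_threshold: float = 0.5):
    """Per-patient {high, low} risk call by majority vote over gene pairs.

    Pairs whose genes are absent from the matrix are dropped with a
    warning; equal expression within a pair counts as not-greater.
    Returns a pandas Series indexed by sample id.
    """
    signature = validate_signature(list(signature))
    present = set(matrix.gene_ids)
    usable = [(a, b) for a, b in signature if a in present and b in present]
    dropped = len(signature) - len(usable)
    if dropped:
        logger.warning("classify_reo: %d / %d pairs dropped (missing genes)",
                       dropped, len(signature))
    if not usable:
        raise ValueError("all signature pairs reference genes absent from the matrix")
    idx_a = matrix.gene_index([a for a, _ in usable])
    idx_b = matrix.gene_index([b for _, b in usable])
    votes = matrix.values[idx_a] > matrix.values[idx_b]   # pairs x samples
    frac = votes.mean(axis=0)
    calls = np.where(frac >= vote_threshold, HIGH, LOW)
    return pd.Series(calls, index=matrix.sample_ids, name="reo_risk")
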