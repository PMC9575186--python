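"""Preprocessing contracts shared by clustering and classification.

Per-gene z-scoring (sample SD, n-1 denominator), intersection to the gene
universe common to all cohorts, and additive batch correction. For
cross-cohort classification the canonical order is intersect -> merge ->
batch-correct -> z-score, which leaves z-scores batch-clean.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["zscore_genes", "intersect_genes", "remove_batch_effect", "merge_cohorts"]


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample SD 1 (n-1 denominator).

    Constant genes have no z-score and are dropped with a logged count.
    """
    if m.shape[1] < 2:
        raise ValidationError("z-scoring needs at least two samples")
    sd = m.values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info("zscore_genes: dropped %d constant genes", int(constant.sum()))
    values = m.values.loc[~constant]
    out = values.sub(values.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return ExpressionMatrix(out, m.cohort_id, m.platform)


def intersect_genes(ms: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the genes common to all, in the first
    matrix's row order."""
    if len(ms) < 2:
        raise ValidationError("intersect_genes needs at least two matrices")
    common = set(ms[0].genes)
    for m in ms[1:]:
        common &= set(m.genes)
    if not common:
        raise ValidationError("empty gene intersection across cohorts")
    order = [g for g in ms[0].genes if g in common]
    return [ExpressionMatrix(m.values.loc[order], m.cohort_id, m.platform) for m in ms]


def merge_cohorts(ms: Sequence[ExpressionMatrix], cohort_id: str = "merged") -> tuple[ExpressionMatrix, pd.Series]:
    """Column-concatenate gene-aligned cohorts; returns the merged matrix
    and the sample -> cohort batch map."""
    ms = intersect_genes(ms) if len(ms) > 1 else list(ms)
    merged = pd.concat([m.values for m in ms], axis=1)
    batch = pd.concat([pd.Series(m.cohort_id, index=m.samples) for m in ms])
    return ExpressionMatrix(merged, cohort_id, ms[0].platform), batch


def remove_batch_effect(m: ExpressionMatrix, batch: Mapping[str, str] | pd.Series) -> ExpressionMatrix:
    """Subtract per-gene additive batch effects estimated by least squares.

    The model is value = grand-effect + batch-effect with a sum-to-zero
    batch encoding, so corrected data keep the grand mean: for a one-way
    layout the fitted batch term is the batch mean minus the unweighted
    mean of batch means, and correction subtracts exactly that. Idempotent,
    and exact equalization of batch means for balanced designs.
    """
    batch = pd.Series(dict(batch)) if not isinstance(batch, pd.Series) else batch
    missing = [s for s in m.samples if s not in batch.index]
    if missing:
        raise ValidationError(f"samples without batch assignment: {missing[:5]}")
    batch = batch.loc[m.samples]
    counts = batch.value_counts()
    if len(counts) < 2:
        raise ValidationError("batch correction needs at least two batches")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"batches with a single sample: {small}")

    values = m.values
    batch_means = values.T.groupby(batch).mean().T        # genes x batches
    centered = batch_means.sub(batch_means.mean(axis=1), axis=0)
    correction = centered[batch.values].to_numpy()        # broadcast per sample
    out = pd.DataFrame(values.to_numpy() - correction, index=values.index,
                       columns=values.columns)
    return ExpressionMatrix(out, m.cohort_id, m.platform)
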