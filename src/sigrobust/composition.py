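"""Functional and compositional follow-up: ssGSEA scores and linear deconvolution.

Single-sample GSEA condenses a gene set into one per-sample activity
score via a weighted running sum over the sample's expression ranking:
in-set genes contribute their rank value raised to a weight w (default
0.25), normalized to total mass 1; out-of-set genes contribute uniform
mass. The raw score is the sum of the difference between the two
cumulative distributions over all rank positions, and raw scores are
normalized by the range (max - min) of the whole term x sample matrix.

Cell-type composition of bulk profiles is estimated by sum-to-one
non-negative least squares against a reference basis of cell-type
profiles. This is a transparent linear stand-in for support-vector
deconvolution services: the contract (bulk + basis -> fractions) is the
same, absolute values will differ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import f_oneway, ttest_ind

from .io import ExpressionMatrix, SubtypeLabelSet, ValidationError
from .simulate import CellTypeBasis

__all__ = [
    "ssgsea_score",
    "ssgsea_matrix",
    "enrichment_association",
    "nnls_deconvolve",
]


def ssgsea_score(sample: pd.Series, gene_set, weight: float = 0.25) -> float:
    """Raw ssGSEA running-sum statistic for one sample and one gene set.

    Genes are ranked by expression descending (ties broken stably by input
    gene order); the rank value of the gene at position i (1-based from
    the bottom, so the top gene has value n) raised to ``weight`` drives
    the in-set increments. Positive scores mean the set sits among the
    top-ranked genes.
    """
    genes = list(sample.index)
    in_set = set(gene_set) & set(genes)
    if not in_set:
        raise ValidationError("gene set shares no genes with the sample")
    if len(in_set) == len(genes):
        raise ValidationError("gene set covers every gene; enrichment undefined")
    values = sample.to_numpy(dtype=float)
    n = len(genes)
    # stable descending order: mergesort keeps input order among ties
    order = np.argsort(-values, kind="mergesort")
    rank_values = np.arange(n, 0, -1, dtype=float)  # n for the top gene
    member = np.fromiter((genes[i] in in_set for i in order), dtype=bool, count=n)
    w = rank_values ** weight * member
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~member) / (n - len(in_set))
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(m: ExpressionMatrix, gene_sets: dict[str, list[str]],
                  weight: float = 0.25, normalize: bool = True) -> pd.DataFrame:
    """Terms x samples ssGSEA score matrix.

    With ``normalize=True`` raw scores are divided by (max - min) of the
    entire raw matrix, putting all terms and samples on one scale.
    """
    if not gene_sets:
        raise ValidationError("no gene sets supplied")
    scores = pd.DataFrame(
        {s: {term: ssgsea_score(m.values[s], gs, weight=weight)
             for term, gs in gene_sets.items()}
         for s in m.samples}
    )
    scores = scores.loc[list(gene_sets)]
    if normalize:
        span = float(scores.values.max() - scores.values.min())
        if span > 0:
            scores = scores / span
    return scores


def enrichment_association(profile: pd.DataFrame, groups: SubtypeLabelSet) -> pd.DataFrame:
    """Associate enrichment-score terms with subtypes.

    Per term: two-sided Welch t-test for two groups, one-way ANOVA
    otherwise, Bonferroni-adjusted over terms. The associated class is the
    argmax of the per-class mean score (ties report every tied class,
    '|'-joined); direction is 'up' when that mean is positive, 'down'
    otherwise. Terms with adjusted p >= 0.05 carry ``significant=False``.
    """
    labels = groups.align_to(list(profile.columns))
    class_masks = {}
    for cls in groups.scheme.classes:
        mask = (labels == cls).to_numpy()
        if mask.any():
            if mask.sum() < 2:
                raise ValidationError(f"group {cls!r} has fewer than 2 samples")
            class_masks[cls] = mask
    if len(class_masks) < 2:
        raise ValidationError("need at least two non-empty groups")
    values = profile.to_numpy()
    rows = []
    for i, term in enumerate(profile.index):
        samples = [values[i][mask] for mask in class_masks.values()]
        if all(np.all(s == samples[0][0]) for s in samples):
            p = 1.0
        elif len(samples) == 2:
            p = float(ttest_ind(samples[0], samples[1], equal_var=False).pvalue)
        else:
            p = float(f_oneway(*samples).pvalue)
        means = {cls: float(values[i][mask].mean()) for cls, mask in class_masks.items()}
        top = max(means.values())
        tied = [cls for cls, mu in means.items() if mu == top]
        rows.append({
            "term": term,
            "p": p,
            "associated_class": "|".join(tied),
            "direction": "up" if top > 0 else "down",
            **{f"mean_{cls}": mu for cls, mu in means.items()},
        })
    out = pd.DataFrame(rows).set_index("term")
    out["p_adj"] = np.minimum(1.0, out["p"] * len(out))
    out["significant"] = out["p_adj"] < 0.05
    return out


def nnls_deconvolve(bulk: ExpressionMatrix, basis: CellTypeBasis) -> pd.DataFrame:
    """Estimate cell-type fractions per bulk sample by NNLS, renormalized
    to sum to one. Returns cell types x samples."""
    shared = [g for g in basis.genes if g in set(bulk.genes)]
    n_types = len(basis.cell_types)
    if len(shared) < n_types:
        raise ValidationError(
            f"only {len(shared)} shared genes for {n_types} cell types")
    B = basis.profiles.loc[shared].to_numpy()
    if np.linalg.matrix_rank(B) < n_types:
        raise ValidationError("cell-type basis is rank-deficient on the shared genes")
    Y = bulk.values.loc[shared].to_numpy()
    fractions = np.empty((n_types, Y.shape[1]))
    for j in range(Y.shape[1]):
        coef, _ = nnls(B, Y[:, j])
        total = coef.sum()
        fractions[:, j] = coef / total if total > 0 else 1.0 / n_types
    return pd.DataFrame(fractions, index=basis.cell_types, columns=bulk.samples)
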