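"""Signature-restricted hierarchical clustering and partition concordance.

Samples are the clustered units; features are the z-scored expression
values of the signature genes. Agglomerative clustering uses Pearson
correlation distance (1 - r) with average linkage, and the tree is cut to
a fixed number of clusters k. Concordance between a clustering and the
annotated subtypes is quantified with the Rand index and the
Hubert-Arabie adjusted Rand index. A per-gene nonparametric screen
(Wilcoxon rank-sum for two groups, Kruskal-Wallis otherwise, Bonferroni
over the genes tested) measures how strongly individual signature genes
separate the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import comb
from scipy.stats import kruskal, mannwhitneyu

from .io import ExpressionMatrix, GeneSignature, SubtypeLabelSet, SubtypeScheme, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "correlation_distance",
    "hcluster",
    "rand_index",
    "adjusted_rand_index",
    "gene_association",
    "pairwise_subtype_association",
]


@dataclass
class ClusteringResult:
    assignments: SubtypeLabelSet
    k: int
    linkage_record: np.ndarray
    signature_overlap: int


def correlation_distance(x, y) -> float:
    """Pearson correlation distance 1 - r, in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("correlation distance needs two equal-length vectors, n >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r)


def hcluster(m: ExpressionMatrix, signature: GeneSignature, k: int,
             linkage: str = "average") -> ClusteringResult:
    """Cluster samples on correlation distance over signature genes.

    ``m`` should be z-scored. The dendrogram is cut to exactly ``k`` flat
    clusters named Cl1..Clk by first appearance. Deterministic for fixed
    input; invariant to sample order up to cluster renaming.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if m.shape[1] < k:
        raise ValidationError("need at least k samples")
    overlap = signature.overlap(m)
    if not overlap:
        raise ValidationError(
            f"signature {signature.name!r} has no genes in common with the matrix")
    logger.info("hcluster: %d/%d signature genes present", len(overlap), signature.size)
    X = m.values.loc[overlap].to_numpy().T  # samples x genes
    dist = pdist(X, metric="correlation")
    Z = hierarchy.linkage(dist, method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # name clusters by order of first appearance so output is sample-order stable
    seen: dict[int, str] = {}
    names = []
    for c in flat:
        if c not in seen:
            seen[c] = f"Cl{len(seen) + 1}"
        names.append(seen[c])
    scheme = SubtypeScheme(f"{signature.name}_clusters", tuple(dict.fromkeys(names)))
    labels = SubtypeLabelSet(scheme=scheme,
                             labels=pd.Series(names, index=m.samples), origin="cluster")
    return ClusteringResult(assignments=labels, k=len(seen), linkage_record=Z,
                            signature_overlap=len(overlap))


# ---------------------------------------------------------------------------
# Partition agreement
# ---------------------------------------------------------------------------


def _contingency(a, b) -> np.ndarray:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("partitions must cover the same samples")
    if a.size == 0:
        raise ValidationError("empty partitions")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((int(ai.max()) + 1, int(bi.max()) + 1), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)
    return ct


def rand_index(a, b) -> float:
    """Fraction of sample pairs on which two partitions agree."""
    ct = _contingency(a, b)
    n = ct.sum()
    if n < 2:
        raise ValidationError("Rand index needs at least two samples")
    sum_sq = (ct.astype(float) ** 2).sum()
    sum_rows = (ct.sum(axis=1).astype(float) ** 2).sum()
    sum_cols = (ct.sum(axis=0).astype(float) ** 2).sum()
    same_same = (sum_sq - n) / 2.0                       # pairs together in both
    diff_diff = comb(n, 2) - (sum_rows - n) / 2.0 - (sum_cols - n) / 2.0 + (sum_sq - n) / 2.0
    return float((same_same + diff_diff) / comb(n, 2))


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie chance-corrected Rand index.

    0 in expectation for independent partitions under the permutation
    model, 1 iff the partitions are identical up to renaming.
    """
    ct = _contingency(a, b)
    n = ct.sum()
    if n < 2:
        raise ValidationError("ARI needs at least two samples")
    sum_cells = comb(ct, 2).sum()
    sum_rows = comb(ct.sum(axis=1), 2).sum()
    sum_cols = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:  # both partitions trivial (all-singletons or one block)
        return 1.0 if np.array_equal(sum_rows, sum_cols) and sum_cells == sum_rows else 0.0
    return float((sum_cells - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# Per-gene association screening
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 25  # exact rank-sum p below this combined n, if tie-free


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_N_MAX and tie_free) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _group_arrays(m: ExpressionMatrix, groups: SubtypeLabelSet,
                  genes: list[str]) -> tuple[np.ndarray, list[np.ndarray]]:
    labels = groups.align_to(m.samples)
    values = m.values.loc[genes].to_numpy()
    masks = []
    for cls in groups.scheme.classes:
        mask = (labels == cls).to_numpy()
        if mask.any():
            if mask.sum() < 2:
                raise ValidationError(f"group {cls!r} has fewer than 2 samples")
            masks.append(mask)
    if len(masks) < 2:
        raise ValidationError("need at least two non-empty groups")
    return values, masks


def gene_association(m: ExpressionMatrix, groups: SubtypeLabelSet,
                     genes: GeneSignature | list[str]) -> pd.DataFrame:
    """Per-gene group-difference screen with Bonferroni adjustment.

    Two groups: two-sided Wilcoxon rank-sum (exact when the pooled sample
    is small and tie-free, normal approximation with tie correction
    otherwise). More than two: Kruskal-Wallis. The Bonferroni family is the
    set of genes actually tested (signature genes present in the matrix).
    Returns a DataFrame indexed by gene with ``p``, ``p_adj`` and
    ``neg_log10_p_adj`` columns.
    """
    gene_list = genes.overlap(m) if isinstance(genes, GeneSignature) else \
        [g for g in genes if g in set(m.genes)]
    if not gene_list:
        raise ValidationError("no tested genes present in the matrix")
    values, masks = _group_arrays(m, groups, gene_list)
    pvals = np.empty(len(gene_list))
    for i in range(len(gene_list)):
        row = values[i]
        samples = [row[mask] for mask in masks]
        if all(np.all(s == samples[0][0]) for s in samples):
            pvals[i] = 1.0  # completely tied gene carries no signal
            continue
        if len(samples) == 2:
            pvals[i] = _wilcoxon_p(samples[0], samples[1])
        else:
            pvals[i] = float(kruskal(*samples).pvalue)
    m_tests = len(gene_list)
    p_adj = np.minimum(1.0, pvals * m_tests)
    return pd.DataFrame({
        "p": pvals,
        "p_adj": p_adj,
        "neg_log10_p_adj": -np.log10(np.maximum(p_adj, np.finfo(float).tiny)),
    }, index=pd.Index(gene_list, name="gene"))


def pairwise_subtype_association(m: ExpressionMatrix, groups: SubtypeLabelSet,
                                 genes: GeneSignature | list[str]) -> pd.DataFrame:
    """One-vs-rest Wilcoxon per (gene, class), Bonferroni over all tests.

    For k = 2 this reduces to :func:`gene_association` up to the
    multiplicity constant. Returns a DataFrame indexed by (gene, class).
    """
    gene_list = genes.overlap(m) if isinstance(genes, GeneSignature) else \
        [g for g in genes if g in set(m.genes)]
    if not gene_list:
        raise ValidationError("no tested genes present in the matrix")
    labels = groups.align_to(m.samples)
    values = m.values.loc[gene_list].to_numpy()
    rows = []
    for cls in groups.scheme.classes:
        mask = (labels == cls).to_numpy()
        if not mask.any():
            continue
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValidationError(f"one-vs-rest split for {cls!r} leaves a group of size < 2")
        for i, gene in enumerate(gene_list):
            row = values[i]
            if np.all(row == row[0]):
                p = 1.0
            else:
                p = _wilcoxon_p(row[mask], row[~mask])
            rows.append((gene, cls, p))
    out = pd.DataFrame(rows, columns=["gene", "class", "p"]).set_index(["gene", "class"])
    out["p_adj"] = np.minimum(1.0, out["p"] * len(out))
    out["neg_log10_p_adj"] = -np.log10(np.maximum(out["p_adj"], np.finfo(float).tiny))
    return out
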