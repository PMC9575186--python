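"""Null models for signature robustness: random signatures, shuffled labels, SSMD.

A signature that truly encodes subtype biology should beat two nulls:

* size-matched random gene sets drawn from the shared gene universe
  (real signature genes are not excluded — the conservative null), and
* the real signature with permuted subtype labels.

For classification, each null replicate records the mean 5-fold CV
accuracy; for clustering, the concordance (ARI) between real-signature
clusters and random-signature clusters is compared against the pairwise
ARI among random-signature clusterings. The separation between the two
replicate distributions is summarized by the strictly standardized mean
difference, beta = (mu1 - mu2) / sqrt(sigma1^2 + sigma2^2), reported as
|beta| in the final matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .classify import cv_accuracy
from .cluster import adjusted_rand_index, hcluster
from .io import ExpressionMatrix, GeneSignature, SubtypeLabelSet, SubtypeScheme, ValidationError

__all__ = [
    "NullDistribution",
    "GroupSummary",
    "sample_random_signature",
    "shuffle_labels",
    "classification_null",
    "clustering_null",
    "ssmd",
    "ssmd_from_values",
]


@dataclass
class NullDistribution:
    """Replicate statistics from one experimental setting."""

    setting: str   # real | random_signature | shuffled_labels
    statistic: str  # cv_accuracy | ari
    values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.setting not in ("real", "random_signature", "shuffled_labels", "pairwise_random"):
            raise ValidationError(f"unknown setting {self.setting!r}")

    @property
    def n_reps(self) -> int:
        return len(self.values)

    def summary(self) -> dict:
        return {
            "setting": self.setting,
            "statistic": self.statistic,
            "n_reps": self.n_reps,
            "median": float(np.median(self.values)),
            "mean": float(np.mean(self.values)),
            "max": float(np.max(self.values)),
        }


@dataclass(frozen=True)
class GroupSummary:
    """Mean and sample variance (n-1) of one replicate-value list."""

    mu: float
    var: float

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValidationError("variance must be non-negative")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(mu=float(arr.mean()), var=float(arr.var(ddof=1)))


def ssmd(g1: GroupSummary, g2: GroupSummary) -> float:
    """Strictly standardized mean difference for two independent groups
    with unequal variances: (mu1 - mu2) / sqrt(var1 + var2)."""
    denom = g1.var + g2.var
    if denom <= 0:
        raise ValidationError("SSMD undefined: both group variances are zero")
    return float((g1.mu - g2.mu) / np.sqrt(denom))


def ssmd_from_values(values1, values2) -> float:
    return ssmd(GroupSummary.from_values(values1), GroupSummary.from_values(values2))


def sample_random_signature(universe, size: int, seed: int,
                            scheme: SubtypeScheme | None = None) -> GeneSignature:
    """Uniform without-replacement draw of ``size`` genes from the universe.

    The matched size is the real signature's size after overlap filtering
    with the dataset at hand, not its nominal published size.
    """
    universe = list(universe)
    if size > len(universe):
        raise ValidationError(f"cannot draw {size} genes from a universe of {len(universe)}")
    rng = np.random.default_rng(seed)
    genes = [universe[i] for i in rng.choice(len(universe), size=size, replace=False)]
    return GeneSignature(name=f"random_{seed}", genes=genes,
                         scheme=scheme or SubtypeScheme("random", ("a", "b")))


def shuffle_labels(labels: SubtypeLabelSet, seed: int) -> SubtypeLabelSet:
    """Uniform permutation of the label vector over samples; class
    frequencies are preserved exactly."""
    if len(labels.labels) < 2:
        raise ValidationError("need at least two samples to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labels.labels))
    return SubtypeLabelSet(scheme=labels.scheme,
                           labels=pd.Series(labels.labels.values[perm],
                                            index=labels.labels.index),
                           origin=labels.origin)


def classification_null(m: ExpressionMatrix, labels: SubtypeLabelSet,
                        signature: GeneSignature, n_reps: int, seed: int,
                        folds: int = 5) -> dict[str, NullDistribution]:
    """CV-accuracy distributions under the real, random-signature and
    shuffled-label settings.

    Each replicate re-runs the full mean-5-fold-CV evaluation: (a) the
    real signature with a fresh CV fold seed, (b) a fresh size-matched
    random signature, (c) the real signature with freshly permuted labels.
    Returns the three :class:`NullDistribution` objects keyed by setting.
    """
    overlap = signature.overlap(m)
    if not overlap:
        raise ValidationError("signature has no genes in the matrix")
    universe = m.genes
    real_feats = m.values.loc[overlap].T
    real, random_sig, shuffled = [], [], []
    for rep in range(n_reps):
        rep_seed = seed + rep
        real.append(cv_accuracy(real_feats, labels, folds=folds, seed=rep_seed))
        rsig = sample_random_signature(universe, len(overlap), seed=rep_seed * 2 + 1)
        random_sig.append(cv_accuracy(m.values.loc[rsig.genes].T, labels,
                                      folds=folds, seed=rep_seed))
        shuf = shuffle_labels(labels, seed=rep_seed * 2 + 2)
        shuffled.append(cv_accuracy(real_feats, shuf, folds=folds, seed=rep_seed))
    return {
        "real": NullDistribution("real", "cv_accuracy", real, seed),
        "random_signature": NullDistribution("random_signature", "cv_accuracy", random_sig, seed),
        "shuffled_labels": NullDistribution("shuffled_labels", "cv_accuracy", shuffled, seed),
    }


def clustering_null(m: ExpressionMatrix, signature: GeneSignature, k: int,
                    n_reps: int, seed: int, linkage: str = "average",
                    max_pairs: int = 10_000) -> dict[str, NullDistribution]:
    """ARI of real-vs-random and random-vs-random signature clusterings.

    ``real_vs_random`` holds ARI(real clusters, random-signature clusters)
    for each of ``n_reps`` random signatures; ``pairwise_random`` holds the
    ARI over all unordered pairs of the random clusterings, subsampled to
    at most ``max_pairs`` seeded draws when the pair count explodes.
    """
    overlap = signature.overlap(m)
    if not overlap:
        raise ValidationError("signature has no genes in the matrix")
    if n_reps < 2:
        raise ValidationError("clustering_null needs n_reps >= 2")
    real = hcluster(m, signature, k, linkage=linkage).assignments.labels.to_numpy()
    universe = m.genes
    random_parts = []
    for rep in range(n_reps):
        rsig = sample_random_signature(universe, len(overlap), seed=seed + rep)
        random_parts.append(hcluster(m, rsig, k, linkage=linkage).assignments.labels.to_numpy())
    vs_real = np.array([adjusted_rand_index(real, part) for part in random_parts])
    pairs = list(combinations(range(n_reps), 2))
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    pairwise = np.array([adjusted_rand_index(random_parts[i], random_parts[j])
                         for i, j in pairs])
    return {
        "real_vs_random": NullDistribution("random_signature", "ari", vs_real, seed),
        "pairwise_random": NullDistribution("pairwise_random", "ari", pairwise, seed),
    }
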