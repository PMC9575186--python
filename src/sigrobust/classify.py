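"""Cross-cohort subtype classification with a signature x cohort model grid.

One random-forest classifier is trained for every (signature, labeled
training cohort) pair — four published signatures on their four discovery
cohorts give the canonical sixteen-model grid. Forest hyperparameters are
frozen to the reference defaults (100 trees, Gini impurity, sqrt(p)
candidate features per split, bootstrap resampling) so that "default
values" cannot drift between library versions. Performance is the mean
accuracy of a seeded, stratified 5-fold cross-validation; fitted models
predict subtype labels on external cohorts sharing the preprocessed gene
universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix, GeneSignature, SubtypeLabelSet, ValidationError

__all__ = [
    "ModelSpec",
    "RF_DEFAULTS",
    "train_classifier",
    "cv_accuracy",
    "build_model_grid",
    "predict_external",
    "cross_scheme_confusion",
]

# frozen reference defaults, recorded in run manifests
RF_DEFAULTS = dict(n_estimators=100, criterion="gini", max_features="sqrt", bootstrap=True)


@dataclass
class ModelSpec:
    """One cell of the model grid: a signature applied to a training cohort."""

    signature_name: str
    training_cohort: str
    scheme_classes: tuple[str, ...]
    feature_genes: list[str]
    classifier: RandomForestClassifier | None = None
    cv_accuracy: float = float("nan")
    seed: int = 0


def _feature_frame(m: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    missing = [g for g in genes if g not in set(m.genes)]
    if missing:
        raise ValidationError(f"cohort {m.cohort_id!r} lacks feature genes: {missing[:5]}")
    return m.values.loc[genes].T  # samples x genes


def train_classifier(features: pd.DataFrame, labels: SubtypeLabelSet,
                     seed: int = 0) -> RandomForestClassifier:
    """Fit a random forest with the frozen defaults on samples x genes."""
    y = labels.align_to(list(features.index))
    if y.nunique() < 2:
        raise ValidationError("training labels contain a single class")
    clf = RandomForestClassifier(random_state=seed, **RF_DEFAULTS)
    clf.fit(features.to_numpy(), y.to_numpy())
    return clf


def cv_accuracy(features: pd.DataFrame, labels: SubtypeLabelSet,
                folds: int = 5, seed: int = 0) -> float:
    """Mean held-out accuracy over seeded stratified k-fold CV."""
    y = labels.align_to(list(features.index)).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("cross-validation needs at least two classes")
    if counts.min() < folds:
        raise ValidationError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} samples, fewer than {folds} folds")
    X = features.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(random_state=seed + fold, **RF_DEFAULTS)
        clf.fit(X[tr], y[tr])
        accs.append(float((clf.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def build_model_grid(signatures: list[GeneSignature],
                     training_cohorts: list[tuple[ExpressionMatrix, SubtypeLabelSet]],
                     folds: int = 5, seed: int = 0) -> tuple[list[ModelSpec], list[dict]]:
    """Train one model per (signature, cohort) pair.

    Cohorts must be preprocessed (shared gene universe, batch-corrected,
    z-scored) and labeled. A cell whose signature has zero overlap with a
    cohort's genes is reported as a failure; the rest of the grid
    proceeds. The master seed expands to per-model seeds via a counter.
    Returns (models, failures).
    """
    models: list[ModelSpec] = []
    failures: list[dict] = []
    counter = 0
    for sig in signatures:
        for m, labels in training_cohorts:
            counter += 1
            model_seed = seed + counter
            feature_genes = sig.overlap(m)
            try:
                if not feature_genes:
                    raise ValidationError(
                        f"signature {sig.name!r} shares no genes with cohort {m.cohort_id!r}")
                feats = _feature_frame(m, feature_genes)
                acc = cv_accuracy(feats, labels, folds=folds, seed=model_seed)
                clf = train_classifier(feats, labels, seed=model_seed)
            except ValidationError as exc:
                failures.append({"signature": sig.name, "cohort": m.cohort_id, "error": str(exc)})
                continue
            models.append(ModelSpec(
                signature_name=sig.name, training_cohort=m.cohort_id,
                scheme_classes=labels.scheme.classes, feature_genes=feature_genes,
                classifier=clf, cv_accuracy=acc, seed=model_seed))
    return models, failures


def predict_external(model: ModelSpec, cohort: ExpressionMatrix) -> SubtypeLabelSet:
    """Apply a fitted grid model to another cohort; one label per sample."""
    if model.classifier is None:
        raise ValidationError("model has no fitted classifier")
    feats = _feature_frame(cohort, model.feature_genes)
    pred = model.classifier.predict(feats.to_numpy())
    from .io import SubtypeScheme
    scheme = SubtypeScheme(f"{model.signature_name}@{model.training_cohort}",
                           model.scheme_classes)
    return SubtypeLabelSet(scheme=scheme,
                           labels=pd.Series(pred, index=list(cohort.samples)),
                           origin="predicted")


def cross_scheme_confusion(a: SubtypeLabelSet, b: SubtypeLabelSet) -> pd.DataFrame:
    """Contingency table of co-assignments between two labelings of the
    same samples (possibly under different schemes)."""
    if set(a.samples) != set(b.samples):
        raise ValidationError("label sets cover different samples")
    bb = b.labels.loc[a.labels.index]
    table = pd.crosstab(a.labels, bb)
    table = table.reindex(index=list(a.scheme.classes), columns=list(b.scheme.classes),
                          fill_value=0)
    table.index.name = a.scheme.name
    table.columns.name = b.scheme.name
    return table
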