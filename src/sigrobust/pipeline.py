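"""Configuration-driven orchestration of the full robustness evaluation.

A YAML config describes one run: a simulation block (the synthetic study
takes the place of downloaded cohorts), the signature to evaluate, the
stages to execute and the seeds/replicate counts. Every stage writes its
outputs plus a manifest into the run directory; re-running the same
config reproduces every output bit for bit.

Stage order and dependencies::

    simulate -> preprocess -> cluster
                           -> classify -> survival
                           -> robustness
    simulate -> composition

A stage failure is recorded in the summary and its dependents are
skipped; :func:`run_pipeline` then reports ``ok=False``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import RF_DEFAULTS, build_model_grid, predict_external
from .cluster import adjusted_rand_index, gene_association, hcluster, rand_index
from .composition import enrichment_association, nnls_deconvolve, ssgsea_matrix
from .io import write_expression, write_labels, write_survival
from .preprocess import merge_cohorts, remove_batch_effect, zscore_genes
from .robustness import classification_null, clustering_null, ssmd_from_values
from .simulate import SimulationConfig, make_default_basis, simulate_cohorts, simulate_mixtures
from .survival import pairwise_logrank

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "run_pipeline"]

_STAGES = ("cluster", "classify", "robustness", "composition", "survival")
_SIM_KEYS = set(SimulationConfig.__dataclass_fields__)


class ConfigError(ValueError):
    """Invalid run configuration; the message carries the offending key path."""


def _validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("/: config must be a mapping")
    known = {"seed", "reps", "simulate", "stages", "linkage", "folds"}
    unknown = set(config) - known
    if unknown:
        raise ConfigError(f"/{sorted(unknown)[0]}: unknown config key")
    out = {
        "seed": int(config.get("seed", 0)),
        "reps": int(config.get("reps", 1000)),
        "linkage": config.get("linkage", "average"),
        "folds": int(config.get("folds", 5)),
        "stages": list(config.get("stages", _STAGES)),
    }
    for stage in out["stages"]:
        if stage not in _STAGES:
            raise ConfigError(f"/stages: unknown stage {stage!r}")
    sim = dict(config.get("simulate", {}))
    bad = set(sim) - _SIM_KEYS
    if bad:
        raise ConfigError(f"/simulate/{sorted(bad)[0]}: unknown simulation key")
    for key in ("class_proportions", "contamination_range", "class_hazard_ratios"):
        if key in sim and sim[key] is not None:
            sim[key] = tuple(sim[key])
    sim.setdefault("seed", out["seed"])
    try:
        sim_config = SimulationConfig(**sim)
        sim_config.validate()
    except Exception as exc:
        raise ConfigError(f"/simulate: {exc}") from exc
    out["simulate"] = sim_config
    return out


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the summary dict.

    ``config`` may be a mapping or a path to a YAML file. Outputs land in
    ``out_dir``: per-cohort data TSVs under ``data/``, one directory per
    stage, plus ``manifest.yaml`` and ``summary.json``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "sigrobust_version": __version__,
        "seed": cfg["seed"],
        "reps": cfg["reps"],
        "folds": cfg["folds"],
        "linkage": cfg["linkage"],
        "stages": cfg["stages"],
        "rf_defaults": dict(RF_DEFAULTS),
        "simulate": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in cfg["simulate"].__dict__.items()},
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    summary: dict = {"ok": True, "stages": {}, "failures": []}

    study = simulate_cohorts(cfg["simulate"])
    data_dir = out_dir / "data"
    data_dir.mkdir(exist_ok=True)
    for cohort in study.cohorts:
        cid = cohort.expression.cohort_id
        write_expression(cohort.expression, data_dir / f"{cid}_expression.tsv")
        write_labels(cohort.labels, data_dir / f"{cid}_labels.tsv")
        write_survival(cohort.survival, data_dir / f"{cid}_survival.tsv")
    from .io import write_signature
    write_signature(study.signature, data_dir / "planted_signature.tsv")
    summary["stages"]["simulate"] = {"cohorts": len(study.cohorts),
                                     "genes": len(study.gene_universe)}

    zs = {c.expression.cohort_id: zscore_genes(c.expression) for c in study.cohorts}
    k = study.config.k
    sig = study.signature

    def _run(stage, fn):
        nonlocal summary
        try:
            summary["stages"][stage] = fn()
        except Exception as exc:  # recorded, dependents skipped
            logger.exception("stage %s failed", stage)
            summary["failures"].append({"stage": stage, "error": str(exc)})
            summary["ok"] = False

    if "cluster" in cfg["stages"]:
        def _cluster():
            stage_dir = out_dir / "cluster"
            stage_dir.mkdir(exist_ok=True)
            metrics = {}
            for cohort in study.cohorts:
                cid = cohort.expression.cohort_id
                res = hcluster(zs[cid], sig, k, linkage=cfg["linkage"])
                write_labels(res.assignments, stage_dir / f"{cid}_assignments.tsv")
                truth = cohort.labels.align_to(res.assignments.samples)
                assoc = gene_association(zs[cid], res.assignments, sig)
                assoc.to_csv(stage_dir / f"{cid}_gene_association.tsv", sep="\t")
                metrics[cid] = {
                    "ri": rand_index(truth, res.assignments.labels),
                    "ari": adjusted_rand_index(truth, res.assignments.labels),
                    "signature_overlap": res.signature_overlap,
                    "significant_genes": int((assoc["p_adj"] < 0.05).sum()),
                }
            (stage_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
            return metrics
        _run("cluster", _cluster)

    models = []
    if "classify" in cfg["stages"]:
        def _classify():
            nonlocal models
            stage_dir = out_dir / "classify"
            stage_dir.mkdir(exist_ok=True)
            merged, batch = merge_cohorts([c.expression for c in study.cohorts])
            if batch.nunique() > 1:
                merged = remove_batch_effect(merged, batch)
            merged = zscore_genes(merged)
            from .io import ExpressionMatrix
            cohorts = [(ExpressionMatrix(merged.values[c.expression.samples],
                                         c.expression.cohort_id, "synthetic"), c.labels)
                       for c in study.cohorts]
            models_, failures = build_model_grid([sig], cohorts,
                                                 folds=cfg["folds"], seed=cfg["seed"])
            models = models_
            grid = {f"{m.signature_name}@{m.training_cohort}": m.cv_accuracy for m in models}
            for model in models:
                for cm, _ in cohorts:
                    pred = predict_external(model, cm)
                    write_labels(pred, stage_dir /
                                 f"{model.training_cohort}_predicts_{cm.cohort_id}.tsv")
            out = {"grid_size": len(models), "cv_accuracy": grid,
                   "grid_failures": failures}
            (stage_dir / "models.json").write_text(json.dumps(out, indent=2))
            return out
        _run("classify", _classify)

    if "robustness" in cfg["stages"]:
        def _robustness():
            stage_dir = out_dir / "robustness"
            stage_dir.mkdir(exist_ok=True)
            cohort = study.cohorts[0]
            m = zs[cohort.expression.cohort_id]
            cls_null = classification_null(m, cohort.labels, sig,
                                           n_reps=cfg["reps"], seed=cfg["seed"],
                                           folds=cfg["folds"])
            pd.DataFrame({name: d.values for name, d in cls_null.items()}).to_csv(
                stage_dir / "classification_null.tsv", sep="\t", index=False)
            clu_null = clustering_null(m, sig, k, n_reps=max(2, cfg["reps"]),
                                       seed=cfg["seed"], linkage=cfg["linkage"])
            for name, d in clu_null.items():
                pd.DataFrame({name: d.values}).to_csv(
                    stage_dir / f"ari_{name}.tsv", sep="\t", index=False)
            ssmd_val = ssmd_from_values(clu_null["real_vs_random"].values,
                                        clu_null["pairwise_random"].values)
            out = {name: d.summary() for name, d in cls_null.items()}
            out["clustering_ssmd_abs"] = abs(ssmd_val)
            (stage_dir / "summary.json").write_text(json.dumps(out, indent=2))
            return out
        _run("robustness", _robustness)

    if "composition" in cfg["stages"]:
        def _composition():
            stage_dir = out_dir / "composition"
            stage_dir.mkdir(exist_ok=True)
            cohort = study.cohorts[0]
            m = zs[cohort.expression.cohort_id]
            # per-class signature blocks double as functional terms
            classes = sig.scheme.classes
            gene_sets = {f"set_{c}": [g for g in sig.genes
                                      if sig.direction and sig.direction.get(g) == c]
                         for c in classes}
            gene_sets = {t: g for t, g in gene_sets.items() if g}
            scores = ssgsea_matrix(m, gene_sets)
            scores.to_csv(stage_dir / "ssgsea_scores.tsv", sep="\t")
            assoc = enrichment_association(scores, cohort.labels)
            assoc.to_csv(stage_dir / "term_association.tsv", sep="\t")
            basis = make_default_basis(seed=cfg["seed"])
            bulk, true_frac = simulate_mixtures(basis, 100, [1.0] * len(basis.cell_types),
                                                noise_sd=0.05, seed=cfg["seed"])
            est = nnls_deconvolve(bulk, basis)
            est.to_csv(stage_dir / "fractions.tsv", sep="\t")
            rmse = float(np.sqrt(((est.values - true_frac.values) ** 2).mean()))
            out = {"significant_terms": int(assoc["significant"].sum()),
                   "deconvolution_rmse": rmse}
            (stage_dir / "summary.json").write_text(json.dumps(out, indent=2))
            return out
        _run("composition", _composition)

    if "survival" in cfg["stages"]:
        def _survival():
            stage_dir = out_dir / "survival"
            stage_dir.mkdir(exist_ok=True)
            metrics = {}
            for cohort in study.cohorts:
                cid = cohort.expression.cohort_id
                mat = pairwise_logrank(cohort.labels, cohort.survival)
                mat.to_csv(stage_dir / f"{cid}_pairwise_logrank.tsv", sep="\t")
                finite = mat.values[np.isfinite(mat.values)]
                metrics[cid] = {"max_neg_log10_p": float(finite.max()) if finite.size else None}
            (stage_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
            return metrics
        _run("survival", _survival)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
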