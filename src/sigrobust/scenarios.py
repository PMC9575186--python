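"""Canned synthetic study conditions for the robustness evaluation.

Two worlds bracket the question the pipeline answers:

* **signal**: subtype labels drive a planted signature (per-gene shift of
  3 noise SDs), the background carries no subtype information, and a
  purity gradient (contamination by a fixed normal-tissue profile)
  contaminates every gene but is independent of the labels. Here the
  signature should clearly beat size-matched random gene sets in
  classification, and signature-derived clusters should differ sharply
  from random-gene clusters (large |SSMD|), because random gene sets can
  only see the purity gradient.

* **confounded**: no subtype effect at all (delta = 0); the "subtypes"
  are quantile bins of the per-sample contamination fraction. Any gene
  set, real or random, sees the same global purity signal, so real and
  random signatures classify equally well — the failure mode in which a
  published signature's accuracy proves nothing about subtype biology.

The background universe is large enough (20000 genes vs a 50-gene
signature) that the great majority of size-matched random draws contain
no planted gene at all; a single planted gene at delta = 3 already
classifies well, so overlap leakage would otherwise mask the contrast.
"""

from __future__ import annotations

import numpy as np

from .preprocess import zscore_genes
from .robustness import classification_null, clustering_null, ssmd_from_values
from .simulate import SimulationConfig, simulate_cohorts

__all__ = [
    "signal_scenario_config",
    "confounded_scenario_config",
    "run_robustness_scenario",
]


def signal_scenario_config(seed: int, samples: int = 120) -> SimulationConfig:
    return SimulationConfig(
        n_cohorts=1,
        samples_per_cohort=samples,
        k=2,
        n_signature_genes_per_class=25,
        n_background_genes=20000,
        effect_size=3.0,
        noise_sd=1.0,
        batch_shift_sd=0.0,
        contamination_range=(0.0, 0.8),
        labels_from_contamination=False,
        class_hazard_ratios=(1.0, 3.0),
        seed=seed,
    )


def confounded_scenario_config(seed: int, samples: int = 120) -> SimulationConfig:
    cfg = signal_scenario_config(seed, samples=samples)
    return SimulationConfig(**{**cfg.__dict__, "effect_size": 0.0,
                               "labels_from_contamination": True})


def run_robustness_scenario(config: SimulationConfig, n_reps: int = 100,
                            seed: int = 0) -> dict:
    """Simulate one cohort and run the classification and clustering nulls.

    Returns a flat summary: per-setting accuracy distributions and their
    medians, the real-minus-random median accuracy gap, the majority-class
    rate, and the clustering SSMD between real-vs-random and
    random-vs-random ARI lists.
    """
    study = simulate_cohorts(config)
    cohort = study.cohorts[0]
    m = zscore_genes(cohort.expression)
    labels = cohort.labels
    cls_counts = labels.labels.value_counts()
    majority_rate = float(cls_counts.max() / cls_counts.sum())

    cls_null = classification_null(m, labels, study.signature, n_reps=n_reps, seed=seed)
    clu_null = clustering_null(m, study.signature, k=config.k, n_reps=n_reps, seed=seed)
    ari_real_vs_random = clu_null["real_vs_random"].values
    ari_pairwise_random = clu_null["pairwise_random"].values

    medians = {name: float(np.median(d.values)) for name, d in cls_null.items()}
    return {
        "config": config,
        "majority_rate": majority_rate,
        "accuracy": {name: d.values for name, d in cls_null.items()},
        "accuracy_median": medians,
        "real_minus_random_gap": medians["real"] - medians["random_signature"],
        "shuffled_median": medians["shuffled_labels"],
        "ari_real_vs_random": ari_real_vs_random,
        "ari_pairwise_random": ari_pairwise_random,
        "clustering_ssmd": ssmd_from_values(ari_real_vs_random, ari_pairwise_random),
    }
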