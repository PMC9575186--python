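#!/usr/bin/env python
"""Generate the synthetic multi-cohort study used by the downstream analyses.

Four cohorts of 150 samples, two latent subtypes, a 50-gene planted
signature (effect 1 SD per gene), cohort-level batch shifts, tumor purity
between 40% and 100%, and subtype-dependent exponential survival
(hazard ratio 2 for S2). Writes expression/label/survival TSVs plus the
planted signature under results/data/.
"""

from pathlib import Path

import yaml

from sigrobust.io import write_expression, write_labels, write_signature, write_survival
from sigrobust.simulate import SimulationConfig, simulate_cohorts

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

CONFIG = SimulationConfig(
    n_cohorts=4,
    samples_per_cohort=150,
    k=2,
    n_signature_genes_per_class=25,
    n_background_genes=2000,
    effect_size=1.0,
    batch_shift_sd=0.5,
    contamination_range=(0.0, 0.6),
    class_hazard_ratios=(1.0, 2.0),
    censor_rate=0.3,
    seed=20,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate_cohorts(CONFIG)
    for cohort in study.cohorts:
        cid = cohort.expression.cohort_id
        write_expression(cohort.expression, OUT / f"{cid}_expression.tsv")
        write_labels(cohort.labels, OUT / f"{cid}_labels.tsv")
        write_survival(cohort.survival, OUT / f"{cid}_survival.tsv")
        cohort.contamination.rename("phi").to_csv(OUT / f"{cid}_contamination.tsv", sep="\t")
    write_signature(study.signature, OUT / "planted_signature.tsv")
    manifest = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in CONFIG.__dict__.items()}
    (OUT / "ground_truth.yaml").write_text(yaml.safe_dump(manifest))
    n_genes = len(study.gene_universe)
    print(f"wrote {len(study.cohorts)} cohorts ({n_genes} genes x "
          f"{CONFIG.samples_per_cohort} samples each) to {OUT}")


if __name__ == "__main__":
    main()
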