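#!/usr/bin/env python
"""Functional and compositional follow-up on the simulated study.

Part 1 — ssGSEA: per-sample enrichment of the planted signature's
per-class gene blocks on cohort 1, tested for association with the true
subtypes (Welch t-test, Bonferroni). The class-S1 block should score
high in S1 samples and be reported 'up' in S1, and symmetrically for S2.

Part 2 — deconvolution: noisy Dirichlet mixtures of a four-cell-type
pancreas-like basis are deconvolved by sum-to-one NNLS, and bulk
profiles with a planted acinar-contamination gradient are checked for
rank correlation between true contamination and estimated acinar
fraction. Outputs under results/composition/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from sigrobust.composition import enrichment_association, nnls_deconvolve, ssgsea_matrix
from sigrobust.io import ExpressionMatrix, read_expression, read_labels, read_signature
from sigrobust.preprocess import zscore_genes
from sigrobust.simulate import make_default_basis, simulate_mixtures

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "composition"
SEED = 20


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sig = read_signature(ROOT / "data" / "planted_signature.tsv")
    m = zscore_genes(read_expression(ROOT / "data" / "cohort1_expression.tsv",
                                     cohort_id="cohort1"))
    labels = read_labels(ROOT / "data" / "cohort1_labels.tsv", scheme=sig.scheme)
    gene_sets = {f"block_{c}": [g for g in sig.genes if sig.direction[g] == c]
                 for c in sig.scheme.classes}
    scores = ssgsea_matrix(m, gene_sets)
    scores.to_csv(OUT / "ssgsea_scores.tsv", sep="\t")
    assoc = enrichment_association(scores, labels)
    assoc.to_csv(OUT / "term_association.tsv", sep="\t")
    for term, row in assoc.iterrows():
        print(f"{term}: associated with {row['associated_class']} ({row['direction']}), "
              f"adjusted p = {row['p_adj']:.2e}")

    basis = make_default_basis(n_genes=200, seed=SEED)
    bulk, truth = simulate_mixtures(basis, 200, [1, 1, 1, 1], noise_sd=0.05, seed=SEED)
    est = nnls_deconvolve(bulk, basis)
    est.to_csv(OUT / "mixture_fractions.tsv", sep="\t")
    rmse = float(np.sqrt(((est.values - truth.values) ** 2).mean()))

    rng = np.random.default_rng(SEED)
    phi = rng.uniform(0.0, 0.8, size=150)
    vals = (np.outer(basis.profiles["ductal"], 1 - phi)
            + np.outer(basis.profiles["acinar"], phi)
            + rng.normal(0, 0.1, size=(200, 150)))
    contaminated = ExpressionMatrix(pd.DataFrame(
        vals, index=basis.genes, columns=[f"s{j}" for j in range(150)]))
    frac = nnls_deconvolve(contaminated, basis)
    rho = float(spearmanr(phi, frac.loc["acinar"]).statistic)
    print(f"deconvolution RMSE on Dirichlet mixtures: {rmse:.4f}")
    print(f"Spearman rho(contamination phi, estimated acinar fraction): {rho:.3f}")
    print("high-contamination samples are read as acinar-rich — the mechanism "
          "by which normal-tissue admixture can masquerade as a subtype")
    (OUT / "summary.json").write_text(json.dumps(
        {"deconvolution_rmse": rmse, "contamination_acinar_spearman": rho}, indent=2))


if __name__ == "__main__":
    main()
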