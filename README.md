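# sigrobust

**Robustness evaluation of transcriptomic subtype signatures.**

Tumor subtyping schemes are usually published as a gene signature: a
list of genes whose expression is supposed to stratify patients into
molecular classes. In pancreatic ductal adenocarcinoma (PDAC) alone,
four widely used schemes propose two, three, four or five subtypes
(Moffitt 50 tumor + 48 stroma genes, Collisson 62, Bailey 613,
Puleo 403). Whether those signatures measure tumor biology — or merely
cohort-level batch effects and the fraction of normal tissue in each
bulk sample — is exactly what this package tests.

`sigrobust` is aimed at computational biologists who want to
stress-test a signature before trusting it. It implements:

- **Clustering concordance** — agglomerative clustering of samples on
  correlation distance over signature genes, scored against annotated
  subtypes with the Rand index (RI) and adjusted Rand index (ARI).
- **Cross-cohort classification** — a (signature × training cohort)
  grid of random-forest models (frozen defaults: 100 trees, Gini, √p
  features) evaluated by stratified 5-fold cross-validation; four
  signatures on four discovery cohorts give the canonical 16-model grid.
- **Null models** — size-matched random gene signatures and permuted
  subtype labels, repeated (default 1000×), with the separation between
  real and random replicate distributions summarized by the strictly
  standardized mean difference, β = (μ₁ − μ₂)/√(σ₁² + σ₂²).
- **Per-gene screens** — Wilcoxon rank-sum / Kruskal–Wallis tests with
  Bonferroni correction, reported as −log10(adjusted p).
- **Composition follow-up** — single-sample GSEA (weighted running sum
  over the expression ranking) with a highest-mean-score subtype
  association rule, and sum-to-one NNLS deconvolution of bulk profiles
  against a cell-type basis.
- **Survival separation** — Kaplan–Meier curves and pairwise log-rank
  tests between predicted classes, reported as a −log10(p) matrix.
- **A synthetic multi-cohort generator** with planted subtype signal,
  per-cohort batch shifts, per-sample normal-tissue contamination
  (tumor purity) and subtype-dependent exponential survival — so every
  stage can be validated against known ground truth.

The scientific point the package operationalizes: a signature can
classify well for the wrong reason. If "subtypes" are driven by tumor
purity, *any* random gene set classifies as well as the published one —
so accuracy alone certifies nothing. The null batteries make that
failure mode measurable.

## Worked example

The numbered scripts under `analysis/` run the whole evaluation on a
simulated four-cohort study (150 samples each, two subtypes, 50 planted
signature genes at 1 SD per-gene effect, batch shifts, purity 40–100%):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_cluster_concordance.py
python analysis/03_classification_grid.py
python analysis/04_robustness_nulls.py
python analysis/05_composition.py
python analysis/06_survival.py
```

`02` prints, per cohort, how well signature-restricted clusters recover
the true subtypes:

```
cohort1: RI=1.000 ARI=1.000 signature genes separating clusters: 49/50
cohort2: RI=0.987 ARI=0.973 signature genes separating clusters: 50/50
```

`03` trains the 16-model grid (planted signature plus three size-matched
random signatures × four cohorts):

```
model grid: 16 models (4 signatures x 4 cohorts), 0 failures
planted-signature CV accuracy: 0.987-1.000; random-signature CV accuracy: 0.513-0.707
```

`04` contrasts two worlds at 100 null replicates each — one where the
labels really are driven by the signature, one where they are bins of
the contamination fraction:

```
[signal] real=1.000 random=0.567 shuffled=0.550 gap=+0.433 clustering |SSMD|=2.72
[confounded] real=0.842 random=0.875 shuffled=0.508 gap=-0.033 clustering |SSMD|=0.73
```

Read: with genuine signal, the real signature beats random gene sets by
~0.43 accuracy and its clusters separate clearly from random-gene
clusters (|SSMD| ≈ 2.7 here; typically 3–5 across simulation seeds); in
the purity-confounded world the random signatures do just as well
(gap −0.03) even though absolute accuracy is a healthy 0.84–0.88 — high
accuracy, no subtype biology. `05` closes
the loop mechanistically: NNLS deconvolution recovers mixture fractions
to RMSE ≈ 0.001 and the estimated acinar fraction rank-correlates with
the planted contamination at ρ ≈ 1.0, which is how normal-tissue
admixture comes to masquerade as an "exocrine-like" subtype.

There is also a CLI (`sigrobust simulate|preprocess|cluster|classify|robustness|run`)
driving the same library, with YAML-configured end-to-end runs
(`sigrobust run --config cfg.yaml --out rundir`) that are bit-for-bit
reproducible under a fixed seed.

## Layout

```
src/sigrobust/     io, simulate, preprocess, cluster, classify,
                   robustness, composition, survival, scenarios,
                   pipeline, cli
analysis/          numbered narrative drivers (write results/)
tests/             pytest suite incl. brute-force oracles
docs/methods.md    models, defaults, design choices, limitations
```

The packaged signature registry (`sigrobust.io.registry_get`) carries
the five published schemes with their exact sizes and class names; the
gene lists themselves are synthetic placeholders (see
`docs/methods.md`) — load genuine lists with `read_signature` for real
analyses.
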