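# Methods

`sigrobust` evaluates whether a published gene signature for tumor
subtyping actually carries subtype information, or merely rides on
technical and compositional structure (cohort batch effects, tumor
purity). The package was designed around pancreatic ductal
adenocarcinoma (PDAC), where two- to five-class transcriptomic
subtyping schemes coexist (Moffitt tumor 50 / stroma 48 genes,
Collisson 62, Bailey 613, Puleo 403), but every component is generic.
Because the real cohorts behind those schemes are external downloads,
the package ships a synthetic multi-cohort generator with known ground
truth; all shipped analyses and tests run on it.

## Evaluation pipeline

**Preprocessing.** Genes are z-scored per row (sample SD, n−1
denominator; constant genes dropped with a logged count). For
cross-cohort classification the order is: intersect gene universes →
merge cohorts → remove additive batch effects → z-score. The batch
model is per-gene least squares `value = grand effect + batch effect`
with a sum-to-zero batch encoding, so correction subtracts
`batch mean − mean of batch means` and keeps the grand mean; it is
idempotent and exactly equalizes batch means in balanced designs. The
z-score-after-correction order is a design choice (either order is
defensible); it guarantees the features handed to classifiers are
batch-clean and unit-variance.

**Clustering concordance.** Samples are clustered agglomeratively on
Pearson correlation distance (1 − r) over the signature genes only,
with average linkage, and the tree is cut to the scheme's k. Average
linkage is the conventional partner of correlation distance; a flag
switches to complete or Ward for sensitivity runs. Concordance between
clusters and annotated subtypes is the Rand index and the
Hubert–Arabie adjusted Rand index computed from the contingency table;
both are verified in the tests against exhaustive pair counting on all
set partitions of up to six samples. A per-gene screen (two-sided
Wilcoxon rank-sum for two groups — exact when the pooled sample is ≤25
and tie-free, normal approximation with tie correction otherwise —
Kruskal–Wallis for more) reports Bonferroni-adjusted p-values, with the
family equal to the genes actually tested after overlap filtering.

**Classification.** One random-forest classifier per
(signature × labeled training cohort) cell — four signatures on four
discovery cohorts give the canonical sixteen-model grid. Forest
hyperparameters are frozen (100 trees, Gini, √p candidate features per
split, bootstrap) rather than left to a library default that drifts
across versions, and are recorded in run manifests. Performance is the
mean accuracy of stratified, seeded 5-fold cross-validation;
stratification stabilizes small-class folds. A master seed expands to
per-model seeds via a counter.

**Null models and SSMD.** Three classification settings are repeated
(default 1000 replicates; shipped analyses and tests use 100): the
real signature with fresh CV folds, a fresh size-matched random gene
set per replicate, and the real signature with freshly permuted labels.
The random pool is the shared gene universe *including* the signature's
own genes (the conservative null), and the matched size is the
signature's size after overlap filtering, not its nominal size. For
clustering, the ARI between real-signature clusters and each
random-signature clustering (list A) is compared against the pairwise
ARI among the random clusterings (list B; subsampled to ≤10 000 seeded
pairs when the pair count explodes). The separation summary is the
strictly standardized mean difference

    beta = (mu1 − mu2) / sqrt(sigma1^2 + sigma2^2)

with n−1 variances, reported as |beta|. A signature whose clusters
merely reflect the dominant global signal gives list A ≈ list B and
small |beta|.

**ssGSEA.** The per-sample score of a gene set ranks genes by
expression descending (ties broken stably by input order) and
accumulates, position by position, the difference between the
normalized in-set mass — rank value raised to a weight w, default
0.25 — and the uniform out-of-set mass; the raw score is the sum of
that difference over all positions, and raw scores are normalized by
the (max − min) range of the whole term × sample matrix. Weight, rank
weighting and range normalization are explicit knobs because ssGSEA
dialects differ between tools. At w = 0 the score is rank-only and
invariant under strictly monotone transformations of the expression
vector. Term–subtype association uses a two-sided Welch t-test (two
groups) or one-way ANOVA, Bonferroni over terms; the associated class
is the argmax of per-class mean score (ties reported, not broken) and
the direction is that mean's sign.

**Deconvolution.** Cell-type fractions are estimated per bulk sample
by non-negative least squares against a reference basis, renormalized
to sum to one. This is a transparent linear stand-in for support-vector
deconvolution services with the same contract (bulk + basis →
fractions); absolute values will differ from those tools, but the
property that matters here — contaminated samples receive high
normal-cell fractions — is preserved and tested.

**Survival.** Kaplan–Meier curves and two-group log-rank tests are
delegated to lifelines (the standard aggregated-risk-set treatment of
ties); the package adds the pairwise class-pair matrix reported as
−log10(p), with zero-event pairs flagged missing rather than coerced to
a number, and no multiplicity correction by default (a flag adds
Bonferroni). The test suite checks the log-rank statistic against an
independent observed-vs-expected oracle on 100 random fixtures.

## Synthetic data generator

For sample j of class c with contamination φ_j in cohort b, gene g:

    x[g, j] = (1 − φ_j) · (δ · σ · 1[g ∈ sig(c)] + ε) + φ_j · ν_g + β[b, g]

with noise ε ~ N(0, σ²), per-cohort batch shift β ~ N(0, batch_sd²),
φ ~ Uniform(contamination range), and a "normal tissue" profile
ν ~ N(0, 1) drawn once per study — contamination is a purity-correlated
*global* signal shared by all cohorts, mimicking acinar admixture.
Survival is exponential with hazard `base · HR(class)` and independent
exponential censoring whose hazard is calibrated so that
P(censored) equals the requested rate. Identical configs give
bitwise-identical output.

Key defaults and why: 4 cohorts × 150 samples (typical compendium
scale); δ = 1 noise SD per marker gene (a modest per-gene effect whose
aggregate over ~50 genes is strong, as in real signatures);
batch_shift_sd = 0.5 (batch comparable to half the biological noise);
contamination up to 0.6 (tumor cellularity ≥40%, a common curation
floor); base hazard 0.04/month (median OS ≈ 17 months, PDAC-like);
censor rate 0.3. With `labels_from_contamination=True` the "subtypes"
become quantile bins of φ — composition masquerading as biology.

The generator deliberately omits count noise (negative binomial),
platform-specific artifacts and gene–gene correlation beyond the
planted blocks and the contamination profile: every pipeline stage
z-scores or ranks its input, so a Gaussian z-score-like scale loses
nothing those stages could see. Consequently, passing tests demonstrate
correctness of the machinery and the qualitative signal/confounder
dichotomy — not that real PDAC cohorts contain (or lack) subtype
signal.

## The two benchmark worlds

`sigrobust.scenarios` fixes two study conditions used by the analyses,
the acceptance checks and `scripts/acceptance.py`:

* **signal** — one cohort of 120 samples, k = 2, a 50-gene planted
  signature at δ = 3, no batch shift, contamination Uniform(0, 0.8)
  independent of the labels, and a 20 000-gene background. The
  background is large because a single planted gene at δ = 3 already
  classifies at ~0.85–0.9; with 20 050 genes the great majority of
  size-matched random draws contain no planted gene, so the
  real-vs-random contrast measures the signature, not overlap leakage.
* **confounded** — identical geometry with δ = 0 and labels equal to
  contamination bins.

Expected behavior, asserted in `tests/test_acceptance.py`: in the
signal world the median real-signature CV accuracy beats the median
random-signature accuracy by ≥0.2 and the clustering |SSMD| exceeds 3
(random gene sets agree with each other on the purity gradient but not
with the signature's subtype clusters); in the confounded world the
real-vs-random gap collapses to ≤0.05 — a published signature's
accuracy there proves nothing about subtype biology. Shuffled-label
accuracy tracks the majority-class rate in both worlds.

## Numerical and degenerate-input choices

* Missing expression values: any row containing one is dropped at
  ingestion with a logged count; downstream stages are total.
* Duplicate gene symbols: element-wise median across rows (the
  probe-to-gene convention); symbols matched case-sensitively after
  trimming, no alias resolution.
* Completely tied genes/terms in the screens get p = 1 rather than an
  undefined test statistic.
* ARI of two trivial identical partitions (all-singletons or one
  block) is defined as 1.
* Correlation distance on a constant vector, SSMD with two zero
  variances, log-rank with zero pooled events: explicit errors, never
  NaN.
* Replicate counts: the null batteries default to 1000 replicates;
  shipped analyses, tests and the acceptance script use 100 (and the
  statistical bands above are comfortably wide at that scale).
* Registry gene lists are synthetic placeholders with the published
  sizes and class schemes (the published supplements are not
  redistributable here); a SHA-256 manifest guards the fixtures
  against drift. Analyses of real cohorts should load the genuine
  lists via `read_signature`.

## Known limitations

* The NNLS deconvolver is not CIBERSORTx; fraction values are not
  comparable across methods.
* The ssGSEA dialect (rank weighting, w = 0.25, range normalization)
  is one of several in circulation; scores are comparable only within
  a run.
* No consensus clustering, no empirical-Bayes batch correction
  (ComBat), no Cox modeling or continuous-gradient (PAMG-style)
  prognostic scoring.
* Pipeline runs recompute every stage; there is no content-addressed
  stage cache. Determinism is guaranteed by seeding, and re-running a
  config reproduces outputs bit for bit.
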