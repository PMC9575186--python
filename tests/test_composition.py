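"""ssGSEA running sum, term-subtype association, and NNLS deconvolution."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from oracles import ssgsea_running_sum
from sigrobust.composition import (
    enrichment_association,
    nnls_deconvolve,
    ssgsea_matrix,
    ssgsea_score,
)
from sigrobust.io import ExpressionMatrix, SubtypeLabelSet, SubtypeScheme, ValidationError
from sigrobust.simulate import make_default_basis, simulate_mixtures


def series(values, genes=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=genes)


class TestSsgseaScore:
    def test_sign_property_top_and_bottom_sets(self):
        s = series(np.arange(20, 0, -1))
        assert ssgsea_score(s, [f"G{i}" for i in range(4)]) > 0
        assert ssgsea_score(s, [f"G{i}" for i in range(16, 20)]) < 0

    def test_worked_running_sum_w0(self):
        # values (5,4,3,2,1), set = top 2, w=0:
        # P_in steps 1/2, 1; P_out steps 0, 0, 1/3, 2/3, 1
        # score = .5 + 1 + 2/3 + 1/3 + 0 = 2.5
        s = series([5, 4, 3, 2, 1])
        assert ssgsea_score(s, ["G0", "G1"], weight=0.0) == pytest.approx(2.5)

    def test_exhaustive_oracle_all_subsets_of_8_genes(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=8)
        genes = [f"G{i}" for i in range(8)]
        s = series(values, genes)
        for w in (0.0, 0.25, 1.0):
            for r in range(1, 8):
                for subset in combinations(genes, r):
                    expected = ssgsea_running_sum(values, genes, set(subset), w)
                    assert ssgsea_score(s, subset, weight=w) == pytest.approx(expected, abs=1e-10)

    def test_rank_only_regime_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=30)
        s = series(values)
        gene_set = [f"G{i}" for i in range(0, 30, 3)]
        base = ssgsea_score(s, gene_set, weight=0.0)
        transformed = series(np.exp(values) * 3 + 7)
        assert ssgsea_score(transformed, gene_set, weight=0.0) == pytest.approx(base)

    def test_duplicate_sample_identical_scores(self):
        rng = np.random.default_rng(2)
        m = ExpressionMatrix(pd.DataFrame(
            np.repeat(rng.normal(size=(15, 1)), 2, axis=1),
            index=[f"G{i}" for i in range(15)], columns=["s1", "s2"]))
        scores = ssgsea_matrix(m, {"t": [f"G{i}" for i in range(5)]}, normalize=False)
        assert scores["s1"].equals(scores["s2"])

    def test_degenerate_sets_rejected(self):
        s = series([3, 2, 1])
        with pytest.raises(ValidationError):
            ssgsea_score(s, ["ZZZ"])
        with pytest.raises(ValidationError):
            ssgsea_score(s, ["G0", "G1", "G2"])

    def test_agrees_with_gseapy_dialect_in_rank(self):
        """Cross-check: per-sample score ordering matches gseapy's ssGSEA."""
        import gseapy
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(120)]
        samples = [f"s{j}" for j in range(12)]
        df = pd.DataFrame(rng.normal(size=(120, 12)) + rng.normal(size=(120, 1)),
                          index=genes, columns=samples)
        gene_sets = {"term": genes[:15]}
        ours = ssgsea_matrix(ExpressionMatrix(df), gene_sets, weight=0.25,
                             normalize=False).loc["term"]
        res = gseapy.ssgsea(data=df, gene_sets=gene_sets, outdir=None,
                            sample_norm_method="rank", weight=0.25,
                            min_size=2, seed=0, threads=1)
        theirs = res.res2d.set_index("Name")["ES"].astype(float).loc[samples]
        rho = spearmanr(ours.values, theirs.values).statistic
        assert rho > 0.95


class TestEnrichmentAssociation:
    def profile(self, shift_class=None, n_terms=5, n=40, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{j}" for j in range(n)]
        labels = SubtypeLabelSet(SubtypeScheme("s", ("a", "b", "c")),
                                 pd.Series((["a", "b", "c"] * n)[:n], index=samples))
        scores = pd.DataFrame(rng.normal(size=(n_terms, n)),
                              index=[f"T{i}" for i in range(n_terms)], columns=samples)
        if shift_class:
            mask = (labels.labels == shift_class).values
            scores.iloc[0, mask] += 2.0
        return scores, labels

    def test_constant_term_not_associated(self):
        scores, labels = self.profile()
        scores.iloc[1] = 0.5
        res = enrichment_association(scores, labels)
        assert res.loc["T1", "p_adj"] == 1.0
        assert not res.loc["T1", "significant"]

    def test_shifted_term_found_up_in_its_class(self):
        scores, labels = self.profile(shift_class="b", seed=1)
        res = enrichment_association(scores, labels)
        assert res.loc["T0", "significant"]
        assert res.loc["T0", "associated_class"] == "b"
        assert res.loc["T0", "direction"] == "up"

    def test_type_one_error_under_global_null(self):
        scores, labels = self.profile(n_terms=1000, seed=2)
        res = enrichment_association(scores, labels)
        assert res["significant"].mean() <= 0.05

    def test_two_group_uses_t_test(self):
        rng = np.random.default_rng(4)
        samples = [f"s{j}" for j in range(20)]
        labels = SubtypeLabelSet(SubtypeScheme("s", ("a", "b")),
                                 pd.Series(["a", "b"] * 10, index=samples))
        scores = pd.DataFrame(rng.normal(size=(3, 20)), index=["T0", "T1", "T2"],
                              columns=samples)
        from scipy.stats import ttest_ind
        res = enrichment_association(scores, labels)
        a = scores.loc["T0"][(labels.labels == "a").values]
        b = scores.loc["T0"][(labels.labels == "b").values]
        assert res.loc["T0", "p"] == pytest.approx(
            ttest_ind(a, b, equal_var=False).pvalue)


class TestDeconvolution:
    def test_pure_column_recovered(self):
        basis = make_default_basis(n_genes=80, seed=0)
        bulk = ExpressionMatrix(basis.profiles.iloc[:, [2]].rename(columns={"macrophage": "s1"}))
        frac = nnls_deconvolve(bulk, basis)
        assert frac.loc["macrophage", "s1"] == pytest.approx(1.0, abs=1e-8)

    def test_even_mix_recovered(self):
        basis = make_default_basis(n_genes=80, seed=1)
        mix = 0.5 * basis.profiles.iloc[:, 0] + 0.5 * basis.profiles.iloc[:, 1]
        bulk = ExpressionMatrix(mix.to_frame("s1"))
        frac = nnls_deconvolve(bulk, basis)
        assert frac.loc[basis.cell_types[0], "s1"] == pytest.approx(0.5, abs=1e-8)
        assert frac.loc[basis.cell_types[1], "s1"] == pytest.approx(0.5, abs=1e-8)

    def test_fractions_sum_to_one_and_nonnegative(self):
        basis = make_default_basis(n_genes=60, seed=2)
        bulk, _ = simulate_mixtures(basis, 50, [1, 1, 1, 1], noise_sd=0.2, seed=2)
        frac = nnls_deconvolve(bulk, basis)
        assert (frac.values >= 0).all()
        np.testing.assert_allclose(frac.sum(axis=0), 1.0, atol=1e-9)

    def test_parameter_recovery_rmse(self):
        basis = make_default_basis(n_genes=200, seed=3)
        bulk, truth = simulate_mixtures(basis, 200, [1, 1, 1, 1], noise_sd=0.05, seed=3)
        est = nnls_deconvolve(bulk, basis)
        rmse = np.sqrt(((est.values - truth.values) ** 2).mean())
        assert rmse < 0.05

    def test_contamination_tracks_estimated_acinar_fraction(self):
        """Samples with more normal-tissue contamination should get a higher
        estimated acinar fraction: the mechanism behind composition-driven
        'subtypes'."""
        rng = np.random.default_rng(5)
        basis = make_default_basis(n_genes=150, seed=5)
        n = 120
        phi = rng.uniform(0.0, 0.8, size=n)
        tumor = basis.profiles["ductal"].to_numpy()
        acinar = basis.profiles["acinar"].to_numpy()
        bulk_vals = np.outer(tumor, 1 - phi) + np.outer(acinar, phi)
        bulk_vals += rng.normal(0, 0.1, size=bulk_vals.shape)
        bulk = ExpressionMatrix(pd.DataFrame(bulk_vals, index=basis.genes,
                                             columns=[f"s{j}" for j in range(n)]))
        frac = nnls_deconvolve(bulk, basis)
        rho = spearmanr(phi, frac.loc["acinar"].values).statistic
        assert rho > 0.8

    def test_rank_deficient_basis_rejected(self):
        from sigrobust.simulate import CellTypeBasis
        col = np.arange(1.0, 11.0)
        basis = CellTypeBasis(pd.DataFrame({"a": col, "b": 2 * col}))
        bulk = ExpressionMatrix(pd.DataFrame({"s1": col}, index=basis.genes))
        with pytest.raises(ValidationError):
            nnls_deconvolve(bulk, basis)
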