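"""Correlation-distance clustering, RI/ARI, and the per-gene screens."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import pair_counting_indices, set_partitions
from sigrobust.cluster import (
    adjusted_rand_index,
    correlation_distance,
    gene_association,
    hcluster,
    pairwise_subtype_association,
    rand_index,
)
from sigrobust.io import ExpressionMatrix, SubtypeLabelSet, SubtypeScheme, ValidationError
from sigrobust.preprocess import zscore_genes
from sigrobust.simulate import SimulationConfig, simulate_cohorts


def blob_matrix(delta=5.0, n=30, genes=12, seed=0):
    """Two Gaussian blobs separated by delta on every gene; z-scored."""
    rng = np.random.default_rng(seed)
    half = n // 2
    data = rng.normal(size=(genes, n))
    # alternate the shift's sign across genes: correlation distance is blind
    # to a constant per-sample offset, the profile shape must change
    data[0::2, half:] += delta
    data[1::2, half:] -= delta
    m = ExpressionMatrix(pd.DataFrame(
        data, index=[f"G{i}" for i in range(genes)],
        columns=[f"s{j}" for j in range(n)]))
    truth = np.array([0] * half + [1] * (n - half))
    from sigrobust.io import GeneSignature
    sig = GeneSignature("blob", list(m.genes), SubtypeScheme("blob", ("a", "b")))
    return zscore_genes(m), sig, truth


class TestCorrelationDistance:
    def test_identity_zero(self):
        assert correlation_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_anticorrelation_two(self):
        assert correlation_distance([1, 2, 3], [-1, -2, -3]) == pytest.approx(2.0)

    def test_worked_value(self):
        assert correlation_distance([1, 2, 3], [1, 2, 4]) == pytest.approx(1 - 0.981980506, abs=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            correlation_distance([1, 1, 1], [1, 2, 3])


class TestHcluster:
    def test_separated_blobs_recovered_exactly(self):
        m, sig, truth = blob_matrix()
        res = hcluster(m, sig, k=2)
        assert adjusted_rand_index(truth, res.assignments.labels) == pytest.approx(1.0)

    def test_k_equals_n_gives_singletons(self):
        m, sig, _ = blob_matrix(n=8)
        res = hcluster(m, sig, k=8)
        assert res.assignments.labels.nunique() == 8

    def test_duplicated_samples_cocluster(self):
        m, sig, _ = blob_matrix(n=10)
        dup = m.values.copy()
        dup.columns = [f"d{j}" for j in range(dup.shape[1])]
        both = ExpressionMatrix(pd.concat([m.values, dup], axis=1))
        res = hcluster(both, sig, k=2)
        lab = res.assignments.labels
        for j in range(10):
            assert lab[f"s{j}"] == lab[f"d{j}"]

    def test_sample_order_invariance_up_to_renaming(self):
        m, sig, _ = blob_matrix(delta=1.0, n=24, seed=3)
        rng = np.random.default_rng(5)
        perm = rng.permutation(m.samples)
        shuffled = ExpressionMatrix(m.values[perm])
        a = hcluster(m, sig, k=3).assignments.labels
        b = hcluster(shuffled, sig, k=3).assignments.labels.loc[a.index]
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_empty_overlap_rejected(self):
        m, _, _ = blob_matrix()
        from sigrobust.io import GeneSignature
        foreign = GeneSignature("x", ["ZZZ"], SubtypeScheme("x", ("a", "b")))
        with pytest.raises(ValidationError):
            hcluster(m, foreign, k=2)


class TestPartitionIndices:
    def test_worked_case(self):
        assert rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(1 / 3)
        assert adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_identical_partitions(self):
        a = [0, 1, 1, 2, 0]
        assert rand_index(a, a) == 1.0
        assert adjusted_rand_index(a, a) == 1.0

    def test_label_renaming_invariance(self):
        a = [0, 0, 1, 2, 2, 1]
        b = ["x", "x", "z", "y", "y", "z"]
        assert rand_index(a, b) == rand_index(a, a)
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_exhaustive_pair_counting_oracle_up_to_n6(self):
        """Agreement with brute-force pair enumeration on every pair of
        set partitions of up to 6 samples (and with scikit-learn's ARI)."""
        for n in (3, 4, 5, 6):
            parts = list(set_partitions(n))
            for i, a in enumerate(parts):
                for b in parts[i:]:
                    ri_o, ari_o = pair_counting_indices(a, b)
                    assert rand_index(a, b) == pytest.approx(ri_o, abs=1e-12)
                    ari = adjusted_rand_index(a, b)
                    assert ari == pytest.approx(ari_o, abs=1e-12)
                    assert ari == pytest.approx(adjusted_rand_score(a, b), abs=1e-9)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            rand_index([0, 1], [0, 1, 2])

    def test_random_partition_ari_centered_at_zero(self):
        rng = np.random.default_rng(42)
        vals = [adjusted_rand_index(rng.integers(0, 3, 200), rng.integers(0, 3, 200))
                for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.02


class TestGeneAssociation:
    def two_group_matrix(self):
        data = [[1, 2, 3, 10, 11, 12],   # clean separation
                [7, 7, 7, 7, 7, 7]]      # all ties
        m = ExpressionMatrix(pd.DataFrame(data, index=["G1", "G2"],
                                          columns=[f"s{j}" for j in range(6)]))
        labels = SubtypeLabelSet(SubtypeScheme("s", ("a", "b")),
                                 pd.Series(["a"] * 3 + ["b"] * 3, index=m.samples))
        return m, labels

    def test_exact_rank_sum_p(self):
        m, labels = self.two_group_matrix()
        res = gene_association(m, labels, ["G1"])
        assert res.loc["G1", "p"] == pytest.approx(0.1)  # 2/20 arrangements
        assert res.loc["G1", "p_adj"] == pytest.approx(0.1)

    def test_tied_gene_p_one(self):
        m, labels = self.two_group_matrix()
        res = gene_association(m, labels, ["G1", "G2"])
        assert res.loc["G2", "p_adj"] == 1.0
        assert res.loc["G1", "p_adj"] == pytest.approx(0.2)  # Bonferroni m=2

    def test_planted_genes_flagged_after_bonferroni(self):
        cfg = SimulationConfig(n_cohorts=1, samples_per_cohort=100, k=3,
                               n_signature_genes_per_class=20, n_background_genes=100,
                               effect_size=3.0, batch_shift_sd=0.0,
                               contamination_range=(0.0, 0.0), seed=4)
        study = simulate_cohorts(cfg)
        c = study.cohorts[0]
        res = gene_association(zscore_genes(c.expression), c.labels, study.signature)
        assert (res["p_adj"] < 0.05).mean() >= 0.95

    def test_type_one_error_controlled_under_global_null(self):
        rng = np.random.default_rng(8)
        m = ExpressionMatrix(pd.DataFrame(rng.normal(size=(1000, 60)),
                                          index=[f"G{i}" for i in range(1000)],
                                          columns=[f"s{j}" for j in range(60)]))
        labels = SubtypeLabelSet(SubtypeScheme("s", ("a", "b", "c")),
                                 pd.Series(["a", "b", "c"] * 20, index=m.samples))
        res = gene_association(m, labels, list(m.genes))
        assert (res["p_adj"] < 0.05).mean() <= 0.05

    def test_small_group_rejected(self):
        m, _ = self.two_group_matrix()
        labels = SubtypeLabelSet(SubtypeScheme("s", ("a", "b")),
                                 pd.Series(["a"] + ["b"] * 5, index=m.samples))
        with pytest.raises(ValidationError):
            gene_association(m, labels, ["G1"])


class TestPairwiseSubtypeAssociation:
    def test_k2_reduces_to_gene_association_up_to_multiplicity(self):
        rng = np.random.default_rng(2)
        m = ExpressionMatrix(pd.DataFrame(rng.normal(size=(5, 40)),
                                          index=[f"G{i}" for i in range(5)],
                                          columns=[f"s{j}" for j in range(40)]))
        labels = SubtypeLabelSet(SubtypeScheme("s", ("a", "b")),
                                 pd.Series(["a", "b"] * 20, index=m.samples))
        ga = gene_association(m, labels, list(m.genes))
        pw = pairwise_subtype_association(m, labels, list(m.genes))
        for g in m.genes:
            assert pw.loc[(g, "a"), "p"] == pytest.approx(ga.loc[g, "p"])
            assert pw.loc[(g, "b"), "p"] == pytest.approx(ga.loc[g, "p"])

    def test_shifted_class_has_smallest_median_p(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(30, 90))
        labels = pd.Series(["a"] * 30 + ["b"] * 30 + ["c"] * 30,
                           index=[f"s{j}" for j in range(90)])
        data[:, :30] += 3.0  # class a shifted on every gene
        m = ExpressionMatrix(pd.DataFrame(data, index=[f"G{i}" for i in range(30)],
                                          columns=labels.index))
        pw = pairwise_subtype_association(
            m, SubtypeLabelSet(SubtypeScheme("s", ("a", "b", "c")), labels), list(m.genes))
        med = pw["p_adj"].groupby(level="class").median()
        assert med.idxmin() == "a"

    def test_type_one_error_controlled_under_global_null(self):
        rng = np.random.default_rng(6)
        m = ExpressionMatrix(pd.DataFrame(rng.normal(size=(1000, 60)),
                                          index=[f"G{i}" for i in range(1000)],
                                          columns=[f"s{j}" for j in range(60)]))
        labels = SubtypeLabelSet(SubtypeScheme("s", ("a", "b", "c")),
                                 pd.Series(["a", "b", "c"] * 20, index=m.samples))
        pw = pairwise_subtype_association(m, labels, list(m.genes))
        assert (pw["p_adj"] < 0.05).mean() <= 0.05
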