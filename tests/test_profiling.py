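import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from kinact import (
    ActivityMatrix,
    bh_fdr,
    cluster_matrix,
    differential_table,
    label_peptide_clusters,
    label_sample_clusters,
    welch_t_test,
)
from kinact.quantify import FLAG_OK
from oracles import bh_stepup


def _matrix(values: np.ndarray, peptides=None, samples=None) -> ActivityMatrix:
    peptides = peptides or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=peptides, columns=samples)
    return ActivityMatrix(df, pd.DataFrame(FLAG_OK, index=peptides, columns=samples))


def _planted_matrix(rng, n_per_cluster=6, n_samples=8, means=(2.0, 6.0, 10.0), sd=0.1):
    blocks, labels = [], []
    for lab, mu in zip("abc", means):
        blocks.append(rng.normal(mu, sd, size=(n_per_cluster, n_samples)))
        labels += [lab] * n_per_cluster
    return _matrix(np.vstack(blocks)), labels


class TestClusterMatrix:
    def test_identical_rows_share_cluster(self):
        values = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0], [7.0, 1.0]])
        out = cluster_matrix(_matrix(values), "peptides", k=3)
        assert out.labels["p0"] == out.labels["p1"]

    def test_planted_peptide_clusters_recovered_exactly(self):
        rng = np.random.default_rng(0)
        matrix, truth = _planted_matrix(rng)
        out = cluster_matrix(matrix, "peptides", k=3)
        pred = [out.labels[p] for p in matrix.peptides]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_partition_invariant_to_row_permutation(self):
        rng = np.random.default_rng(1)
        matrix, _ = _planted_matrix(rng)
        out1 = cluster_matrix(matrix, "peptides", k=3)
        perm = rng.permutation(len(matrix.peptides))
        shuffled = _matrix(
            matrix.values.to_numpy()[perm],
            peptides=[matrix.peptides[i] for i in perm],
            samples=matrix.samples,
        )
        out2 = cluster_matrix(shuffled, "peptides", k=3)
        # same partition: co-membership is identical for every pair
        for a in matrix.peptides:
            for b in matrix.peptides:
                assert (out1.labels[a] == out1.labels[b]) == (out2.labels[a] == out2.labels[b])

    def test_semantic_labels_follow_mean_activity(self):
        rng = np.random.default_rng(2)
        matrix, _ = _planted_matrix(rng)  # means 2 < 6 < 10
        out = label_peptide_clusters(matrix, cluster_matrix(matrix, "peptides", k=3))
        mean_of = {
            lab: matrix.values.loc[out.members(lab)].to_numpy().mean() for lab in "ABC"
        }
        assert mean_of["B"] > mean_of["A"] > mean_of["C"]

    def test_sample_labels_low_is_1(self):
        values = np.hstack(
            [np.full((5, 4), 1.0), np.full((5, 4), 5.0)]
        ) + np.random.default_rng(3).normal(0, 0.05, size=(5, 8))
        matrix = _matrix(values)
        out = label_sample_clusters(matrix, cluster_matrix(matrix, "samples", k=2))
        assert {out.labels[s] for s in matrix.samples[:4]} == {"1"}
        assert {out.labels[s] for s in matrix.samples[4:]} == {"2"}

    def test_k_larger_than_items_rejected(self):
        with pytest.raises(ValueError):
            cluster_matrix(_matrix(np.eye(3)), "peptides", k=4)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test((1, 2, 3), (1, 2, 3))
        assert t == 0.0 and p == 1.0

    def test_hand_computed_satterthwaite(self):
        t, df, p = welch_t_test((5.1, 4.9, 5.3), (6.2, 6.0, 6.4))
        assert t == pytest.approx(-6.7362, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0025, abs=2e-4)

    def test_degenerate_zero_variance(self):
        assert welch_t_test((1, 1, 1), (1, 1))[2] == 1.0
        assert welch_t_test((1, 1, 1), (2, 2))[2] == 0.0

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        a, b = rng.normal(size=9), rng.normal(0.5, 2.0, size=7)
        t, df, p = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),  # step-up by hand
            ([0.03], [0.03]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_stepup(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.001, max_value=1.0), min_size=2, max_size=20),
        st.data(),
    )
    def test_monotone_in_each_p(self, p, data):
        """Lowering one p-value never raises any q-value."""
        i = data.draw(st.integers(min_value=0, max_value=len(p) - 1))
        q_before = bh_fdr(p)
        lowered = list(p)
        lowered[i] = lowered[i] / 2
        q_after = bh_fdr(lowered)
        assert (q_after <= q_before + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDifferentialTable:
    def _groups(self, samples):
        half = len(samples) // 2
        return {s: ("1" if i < half else "2") for i, s in enumerate(samples)}

    def test_equal_means_zero_noise_fold_change_one(self):
        values = np.tile(np.array([3.0, 5.0])[:, None], (1, 8))
        values += np.random.default_rng(0).normal(0, 1e-12, values.shape)
        matrix = _matrix(values)
        out = differential_table(matrix, self._groups(matrix.samples))
        np.testing.assert_allclose(out["fold_change"], 1.0, rtol=1e-6)

    def test_planted_log2_shift_of_one_gives_fold_change_two(self):
        values = np.hstack([np.full((3, 4), 3.0), np.full((3, 4), 4.0)])
        values += np.random.default_rng(1).normal(0, 1e-9, values.shape)
        matrix = _matrix(values)
        out = differential_table(matrix, self._groups(matrix.samples))
        np.testing.assert_allclose(out["fold_change"], 2.0, rtol=1e-6)

    def test_permuted_labels_give_uniform_p(self):
        """Under the null the p-value distribution is U(0,1) (KS at 1%)."""
        from scipy import stats

        rng = np.random.default_rng(2)
        matrix = _matrix(rng.normal(5.0, 1.0, size=(5000, 18)))
        out = differential_table(matrix, self._groups(matrix.samples))
        assert stats.kstest(out["p_value"], "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        matrix = _matrix(np.ones((3, 3)))
        with pytest.raises(ValueError):
            differential_table(matrix, {"s0": "1", "s1": "2", "s2": "2"})
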