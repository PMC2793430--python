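import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coevotree.msa_io import Alignment, encode_rows
from coevotree.pair_stats import (
    DirichletParams, PairCounts, ScoreMatrix, apc_correct, asc_correct,
    column_entropy, log_R, log_joint_prob, log_marginal_prob,
    mutual_information, pair_counts, score_matrix, z_transform,
    NoUsableSequences,
)

from _oracles import apc_on_shifted, dirichlet_multinomial_log


def aln(rows):
    return Alignment([f"s{i}" for i in range(len(rows))], encode_rows(rows))


class TestDirichletParams:
    def test_consistency_enforced(self):
        p = DirichletParams(0.5)
        assert p.lambda_pair == pytest.approx(0.025)
        with pytest.raises(ValueError):
            DirichletParams(0.5, lambda_pair=0.1)
        with pytest.raises(ValueError):
            DirichletParams(-1.0)


class TestPairCounts:
    def test_plain_pair(self):
        pc = pair_counts(aln(["AC", "AC", "AC"]), 0, 1)
        assert pc.n_ab[0, 1] == 3 and pc.n == 3

    def test_gapped_rows_dropped_entirely(self):
        pc = pair_counts(aln(["AC", "A-", "-C"]), 0, 1)
        assert pc.n == 1 and pc.n_ab[0, 1] == 1
        # marginals recomputed on the filtered subset
        assert pc.n_a.sum() == 1 and pc.n_b.sum() == 1

    def test_same_column_rejected(self):
        with pytest.raises(ValueError):
            pair_counts(aln(["AC"]), 0, 0)

    def test_all_gapped_signals(self):
        with pytest.raises(NoUsableSequences):
            pair_counts(aln(["A-", "-C"]), 0, 1)


class TestMarginalLikelihoods:
    def test_single_observation_is_uniform(self):
        c = np.zeros(20)
        c[3] = 1
        # symmetry forces 1/20 whatever lambda is
        for lam in (0.1, 0.5, 2.0):
            assert log_marginal_prob(c, DirichletParams(lam)) == pytest.approx(
                np.log(1 / 20), abs=1e-12)

    def test_two_same_letter_gamma_ratio(self):
        c = np.zeros(20)
        c[0] = 2
        # Gamma(10)/Gamma(12) * Gamma(2.5)/Gamma(0.5) = (0.5*1.5)/(10*11)
        expect = np.log(0.5 * 1.5 / (10 * 11))
        assert log_marginal_prob(c, DirichletParams(0.5)) == pytest.approx(expect)

    def test_empty_counts_log_one(self):
        assert log_marginal_prob(np.zeros(20), DirichletParams(0.5)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_gamma_ratio_script(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 7, size=20)
        p = DirichletParams(0.5)
        assert log_marginal_prob(c, p) == pytest.approx(
            dirichlet_multinomial_log(c, 0.5), rel=1e-12)
        n_ab = rng.integers(0, 3, size=(20, 20))
        pc = PairCounts(n_ab=n_ab, n_a=n_ab.sum(1), n_b=n_ab.sum(0),
                        n=int(n_ab.sum()))
        assert log_joint_prob(pc, p) == pytest.approx(
            dirichlet_multinomial_log(n_ab, 0.025), rel=1e-12)


class TestLogR:
    def test_single_sequence_zero(self):
        assert log_R(aln(["AC"]), 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_independent_columns_penalised(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 20, size=(1000, 2)).astype(np.uint8)
        a = Alignment([f"s{i}" for i in range(1000)], mat)
        assert log_R(a, 0, 1) < 0

    def test_correlated_columns_positive_and_near_n_mi(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=1000)
        mat = np.stack([x, x], axis=1).astype(np.uint8)
        a = Alignment([f"s{i}" for i in range(1000)], mat)
        lr = log_R(a, 0, 1)
        mi = mutual_information(pair_counts(a, 0, 1))
        assert lr > 0
        assert abs(lr / 1000 - mi) < 0.06  # converges slowly; see below

    def test_stirling_convergence_with_n(self):
        """|log R/N - MI| shrinks as N grows (binary perfectly-correlated pair).

        The fixed-N discrepancy contains a ~(20*lambda)*ln N offset from the
        Dirichlet normalisation, so only the trend — not a tight fixed-N
        bound — is asserted for this low-MI pair.
        """
        errs = []
        for n in (10**3, 10**4, 10**5):
            x = np.tile([0, 1], n // 2)
            a = Alignment([f"s{i}" for i in range(n)],
                          np.stack([x, x], axis=1).astype(np.uint8))
            lr = log_R(a, 0, 1)
            mi = mutual_information(pair_counts(a, 0, 1))
            errs.append(abs(lr / n - mi))
        assert errs[0] > errs[1] > errs[2]

    def test_alphabet_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 20, size=(50, 2)).astype(np.uint8)
        a = Alignment([f"s{i}" for i in range(50)], mat)
        perm = rng.permutation(20).astype(np.uint8)
        b = Alignment(a.seq_ids, perm[mat])
        assert log_R(a, 0, 1) == pytest.approx(log_R(b, 0, 1), rel=1e-12)


class TestMiAndEntropy:
    def test_product_counts_zero_mi(self):
        n_ab = np.zeros((20, 20))
        n_ab[0, :2] = [4, 4]
        n_ab[1, :2] = [2, 2]
        pc = PairCounts(n_ab=n_ab, n_a=n_ab.sum(1), n_b=n_ab.sum(0), n=12)
        assert mutual_information(pc) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_counts_ln2(self):
        n_ab = np.zeros((20, 20))
        n_ab[0, 0] = n_ab[1, 1] = 5
        pc = PairCounts(n_ab=n_ab, n_a=n_ab.sum(1), n_b=n_ab.sum(0), n=10)
        assert mutual_information(pc) == pytest.approx(np.log(2))

    def test_hand_computed_2x2(self):
        n_ab = np.zeros((20, 20))
        n_ab[:2, :2] = [[2, 1], [1, 2]]
        pc = PairCounts(n_ab=n_ab, n_a=n_ab.sum(1), n_b=n_ab.sum(0), n=6)
        # plug-in formula evaluated by hand
        p = np.array([[2, 1], [1, 2]]) / 6
        expect = sum(p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
                     for i in range(2) for j in range(2))
        assert mutual_information(pc) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("counts,expect", [
        ([5] + [0] * 19, 0.0),
        ([1] * 20, np.log(20)),
        ([3, 1] + [0] * 18, -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))),
    ])
    def test_column_entropy(self, counts, expect):
        assert column_entropy(np.array(counts)) == pytest.approx(expect)


class TestZTransform:
    def test_three_entry_values(self):
        v = np.full((3, 3), np.nan)
        v[0, 1] = v[1, 0] = 1.0
        v[0, 2] = v[2, 0] = 2.0
        v[1, 2] = v[2, 1] = 3.0
        z = z_transform(ScoreMatrix(v, "logR"))
        assert z.values[0, 1] == pytest.approx(-np.sqrt(1.5))
        assert z.values[0, 2] == pytest.approx(0.0)

    def test_constant_matrix_warns_zero(self):
        v = np.full((3, 3), 2.0)
        np.fill_diagonal(v, np.nan)
        with pytest.warns(UserWarning):
            z = z_transform(ScoreMatrix(v, "logR"))
        assert np.all(z.defined_offdiag() == 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        z1 = z_transform(ScoreMatrix(v, "logR"))
        z2 = z_transform(z1)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-12)

    def test_output_standardised(self):
        rng = np.random.default_rng(4)
        v = rng.normal(2, 5, size=(8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        z = z_transform(ScoreMatrix(v, "logR")).defined_offdiag()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, rel=1e-12)


class TestCorrections:
    @pytest.mark.parametrize("seed", range(5))
    def test_apc_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        got = apc_correct(ScoreMatrix(v, "logR")).values
        want = apc_on_shifted(v)
        mask = ~np.isnan(v)
        np.testing.assert_allclose(got[mask], want[mask], atol=1e-12)

    def test_apc_constant_and_l2_are_zero(self):
        const = np.full((4, 4), 3.0)
        np.fill_diagonal(const, np.nan)
        assert np.all(apc_correct(ScoreMatrix(const, "logR")).defined_offdiag() == 0)
        two = np.full((2, 2), np.nan)
        two[0, 1] = two[1, 0] = 1.7
        assert apc_correct(ScoreMatrix(two, "logR")).values[0, 1] == pytest.approx(0.0)

    def test_apc_shift_invariance(self):
        """Adding a constant to all entries is absorbed by the min-shift."""
        rng = np.random.default_rng(9)
        v = rng.normal(size=(6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        a = apc_correct(ScoreMatrix(v, "logR")).values
        b = apc_correct(ScoreMatrix(v + 17.3, "logR")).values
        mask = ~np.isnan(v)
        np.testing.assert_allclose(a[mask], b[mask], atol=1e-9)

    def test_asc_constant_zero_and_formula(self):
        const = np.full((4, 4), 2.0)
        np.fill_diagonal(const, np.nan)
        assert np.allclose(asc_correct(ScoreMatrix(const, "mi")).defined_offdiag(), 0)
        rng = np.random.default_rng(11)
        v = rng.normal(size=(5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        out = asc_correct(ScoreMatrix(v, "mi")).values
        row = np.nanmean(v, axis=1)
        iu = np.triu_indices(5, 1)
        overall = np.nanmean(v[iu])
        assert out[1, 3] == pytest.approx(v[1, 3] - (row[1] + row[3] - overall))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_score_matrix_symmetric(seed):
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 20, size=(8, 4)).astype(np.uint8)
    a = Alignment([f"s{i}" for i in range(8)], mat)
    m = score_matrix(a, kind="logR").values
    np.testing.assert_allclose(m, m.T, equal_nan=True)
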