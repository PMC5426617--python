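import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from cooccurnet import (
    AbundanceMatrix,
    NoiseSpec,
    add_tiebreak_noise,
    min_distinct_gap,
    pairwise_correlations,
    permute_elements,
    spearman_rho,
)


def _matrix(counts):
    counts = np.asarray(counts, float)
    n, l = counts.shape
    return AbundanceMatrix(counts, [f"o{i}" for i in range(n)], [f"L{j}" for j in range(l)])


class TestGapAndNoise:
    def test_gap_adjacent_integers(self):
        m = _matrix([[0, 1, 5], [1, 5, 0]])
        assert min_distinct_gap(m) == 1.0

    def test_gap_fractional_values(self):
        m = _matrix([[0, 0.25], [1.0, 0.25]])
        assert min_distinct_gap(m) == 0.25

    def test_amplitude_is_gap_over_1000(self):
        m = _matrix([[0, 1, 5], [1, 5, 0]])
        spec = NoiseSpec.for_matrix(m, seed=0)
        assert spec.amplitude == pytest.approx(0.001)

    def test_constant_matrix_has_no_gap(self):
        with pytest.raises(ValueError, match="constant"):
            min_distinct_gap(_matrix([[2, 2], [2, 2]]))

    def test_amplitude_above_half_gap_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(gap=1.0, amplitude=0.5, seed=0)

    @given(
        arrays(np.int64, (4, 7), elements=st.integers(0, 5)),
        st.integers(0, 2**31 - 1),
    )
    def test_order_preservation_property(self, counts, seed):
        counts = counts.astype(float)
        if np.unique(counts).size < 2:
            return
        m = _matrix(counts)
        noisy = add_tiebreak_noise(m, NoiseSpec.for_matrix(m, seed=seed))
        flat, noisy_flat = m.counts.ravel(), noisy.counts.ravel()
        order = np.argsort(flat, kind="stable")
        strict = np.diff(flat[order]) > 0
        assert np.all(np.diff(noisy_flat[order])[strict] > 0)

    def test_distinct_entries_keep_their_ranks(self):
        rng = np.random.default_rng(0)
        counts = rng.permutation(30).reshape(3, 10).astype(float)
        m = _matrix(counts)
        noisy = add_tiebreak_noise(m, NoiseSpec.for_matrix(m, seed=4))
        for raw, pert in zip(m.counts, noisy.counts):
            np.testing.assert_array_equal(np.argsort(raw), np.argsort(pert))

    def test_tied_zeros_break_symmetrically(self):
        # row (0,0,5,5): each zero outranks the other in ~50% of draws,
        # and both zeros always rank below both fives
        m = _matrix([[0, 0, 5, 5], [1, 2, 3, 4]])
        wins = 0
        n_draws = 400
        for seed in range(n_draws):
            noisy = add_tiebreak_noise(m, NoiseSpec.for_matrix(m, seed=seed)).counts[0]
            assert max(noisy[0], noisy[1]) < min(noisy[2], noisy[3])
            wins += noisy[0] > noisy[1]
        assert 0.4 < wins / n_draws < 0.6


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_hand_evaluated_example(self):
        # ranks (1,2,3,4,5) vs (2,1,4,3,5): sum d^2 = 4, rho = 1 - 24/120
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_all_length5_permutation_pairs_match_rank_pearson(self):
        perms = np.array(list(itertools.permutations(range(1, 6))), dtype=float)
        pearson = np.corrcoef(perms)  # rank-then-Pearson oracle
        # closed form evaluated pairwise (vectorized over the 120x120 grid)
        d2 = ((perms[:, None, :] - perms[None, :, :]) ** 2).sum(axis=2)
        closed = 1 - 6 * d2 / (5 * 24)
        np.testing.assert_allclose(closed, pearson, atol=1e-12)
        # spot-check the function against a sample of the grid
        rng = np.random.default_rng(0)
        for i, j in rng.integers(0, 120, size=(50, 2)):
            assert spearman_rho(perms[i], perms[j]) == pytest.approx(
                pearson[i, j], abs=1e-12
            )

    def test_ties_rejected(self):
        with pytest.raises(ValueError, match="ties"):
            spearman_rho([1, 1, 2, 3], [1, 2, 3, 4])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2, 3, 4])


class TestPairwise:
    def test_monotone_transform_gives_rho_one(self):
        base = np.array([3.0, 1.0, 4.0, 2.0, 8.0])
        m = _matrix(np.vstack([base, base + 10, base * 2]))
        c = pairwise_correlations(m)
        np.testing.assert_allclose(c.rho, 1.0)

    def test_matches_per_pair_brute_force(self):
        rng = np.random.default_rng(5)
        counts = rng.random((4, 9))
        m = _matrix(counts)
        c = pairwise_correlations(m)
        for i in range(4):
            for j in range(i + 1, 4):
                assert c.rho[i, j] == pytest.approx(
                    spearman_rho(counts[i], counts[j]), abs=1e-12
                )

    def test_structure_invariants(self, sparse_matrix):
        noisy = add_tiebreak_noise(
            sparse_matrix, NoiseSpec.for_matrix(sparse_matrix, seed=3)
        )
        c = pairwise_correlations(noisy)
        np.testing.assert_allclose(c.rho, c.rho.T)
        np.testing.assert_allclose(np.diag(c.rho), 1.0)
        assert np.all(np.abs(c.rho) <= 1.0)

    def test_tie_free_input_invariant_to_noise(self):
        rng = np.random.default_rng(11)
        counts = rng.random((5, 12))  # ties have probability zero
        m = _matrix(counts)
        c_raw = pairwise_correlations(m)
        noisy = add_tiebreak_noise(m, NoiseSpec.for_matrix(m, seed=9))
        c_noisy = pairwise_correlations(noisy)
        np.testing.assert_allclose(c_raw.rho, c_noisy.rho, atol=1e-12)

    def test_raises_on_ties_by_default(self, sparse_matrix):
        with pytest.raises(ValueError, match="tie"):
            pairwise_correlations(sparse_matrix)

    def test_average_policy_matches_scipy(self, sparse_matrix):
        c = pairwise_correlations(sparse_matrix, on_ties="average")
        ref = stats.spearmanr(sparse_matrix.counts, axis=1).statistic
        mask = ~np.isnan(ref)
        np.testing.assert_allclose(c.rho[mask], ref[mask], atol=1e-12)


class TestPermutation:
    def test_value_multiset_conserved(self, sparse_matrix):
        perm = permute_elements(sparse_matrix, seed=2)
        assert perm.counts.shape == sparse_matrix.counts.shape
        np.testing.assert_array_equal(
            np.sort(perm.counts.ravel()), np.sort(sparse_matrix.counts.ravel())
        )

    def test_histogram_is_seed_invariant(self, sparse_matrix):
        h1 = np.sort(permute_elements(sparse_matrix, seed=1).counts.ravel())
        h2 = np.sort(permute_elements(sparse_matrix, seed=99).counts.ravel())
        np.testing.assert_array_equal(h1, h2)

    def test_mean_offdiag_correlation_near_zero(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.poisson(2.0, size=(12, 80)).astype(float))
        rhos = []
        for seed in range(10):
            perm = permute_elements(m, seed=seed)
            noisy = add_tiebreak_noise(perm, NoiseSpec.for_matrix(perm, seed=seed))
            rhos.append(pairwise_correlations(noisy).abs_offdiag().mean())
        # null mean |rho| for L=80 is ~ sqrt(2/pi)/sqrt(L-1) ~ 0.09
        assert np.mean(rhos) < 0.15
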