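"""Delay-embedding, mutual-information and FNN selection tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecgcast import (
    EmbeddingParams,
    InvalidInputError,
    embed,
    fnn_fraction,
    lorenz63,
    mutual_information,
    select_delay,
    select_embedding_dim,
)


def mi_bruteforce(s, q, n_bins):
    """Literal double-sum over an explicitly built joint histogram."""
    s, q = np.asarray(s, float), np.asarray(q, float)
    joint = np.zeros((n_bins, n_bins))
    for si, qi in zip(s, q):
        i = min(int((si - s.min()) / (s.max() - s.min()) * n_bins), n_bins - 1)
        j = min(int((qi - q.min()) / (q.max() - q.min()) * n_bins), n_bins - 1)
        joint[i, j] += 1
    P = joint / joint.sum()
    ps, pq = P.sum(axis=1), P.sum(axis=0)
    total = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if P[i, j] > 0:
                total += P[i, j] * np.log2(P[i, j] / (ps[i] * pq[j]))
    return total


class TestEmbed:
    def test_worked_example(self):
        """Series 1..10 with m=3, tau=2: six delay vectors, five targets."""
        emb = embed(np.arange(1.0, 11.0), EmbeddingParams(m=3, tau=2))
        assert emb.M == 6
        np.testing.assert_array_equal(emb.X[0], [1, 3, 5])
        np.testing.assert_array_equal(emb.X[5], [6, 8, 10])
        assert emb.Y[0] == 6
        assert emb.Y.size == 5
        assert emb.M_usable == 5

    def test_degenerate_m1_tau1(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        emb = embed(x, EmbeddingParams(m=1, tau=1))
        np.testing.assert_array_equal(emb.X.ravel(), x)
        np.testing.assert_array_equal(emb.Y, x[1:])

    def test_too_short_raises(self):
        with pytest.raises(InvalidInputError):
            embed(np.arange(5.0), EmbeddingParams(m=3, tau=3))

    @given(
        n=st.integers(12, 60),
        m=st.integers(1, 4),
        tau=st.integers(1, 3),
    )
    def test_row_count_and_inverse_consistency(self, n, m, tau):
        """M = N - (m-1)tau rows; column 0 plus the series tail
        reconstructs the input exactly."""
        if n - (m - 1) * tau < 2:
            return
        x = np.sin(0.7 * np.arange(n)) + 0.1 * np.arange(n)
        emb = embed(x, EmbeddingParams(m=m, tau=tau))
        assert emb.X.shape == (n - (m - 1) * tau, m)
        tail = x[n - (m - 1) * tau:]
        np.testing.assert_array_equal(np.concatenate([emb.X[:, 0], tail]), x)

    def test_invalid_params(self):
        with pytest.raises(InvalidInputError):
            EmbeddingParams(m=0, tau=1)
        with pytest.raises(InvalidInputError):
            EmbeddingParams(m=2, tau=0)


class TestMutualInformation:
    def test_matches_bruteforce_on_small_series(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        expected = mi_bruteforce(x[:-2], x[2:], 3)
        assert mutual_information(x, 2, 3) == pytest.approx(expected, abs=1e-12)

    def test_self_pairing_equals_marginal_entropy(self):
        """A series repeating with period L pairs each value with itself
        at lag L, so I equals the marginal entropy H(S)."""
        base = np.array([0.1, 0.9, 0.3, 0.7, 0.5, 0.2])
        x = np.tile(base, 20)
        lag = base.size
        s = x[:-lag]
        counts, _ = np.histogram(s, bins=4)
        p = counts[counts > 0] / counts.sum()
        h_s = -(p * np.log2(p)).sum()
        assert mutual_information(x, lag, 4) == pytest.approx(h_s, abs=1e-12)

    def test_iid_uniform_mi_near_zero(self):
        x = np.random.default_rng(1).uniform(size=10000)
        assert mutual_information(x, 1, 16) < 0.05

    def test_symmetry(self):
        """I(S,Q) = I(Q,S): reversing the series swaps the axis roles."""
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.normal(size=200))
        for lag in (1, 3, 9):
            forward = mutual_information(x, lag, 8)
            backward = mutual_information(x[::-1], lag, 8)
            assert forward == pytest.approx(backward, abs=1e-12)

    def test_nonneg_and_bounded_by_marginals(self):
        rng = np.random.default_rng(3)
        x = np.sin(np.arange(300) * 0.2) + rng.normal(0, 0.2, 300)
        for lag in (1, 5, 20):
            mi = mutual_information(x, lag, 8)
            s, q = x[:-lag], x[lag:]
            hs = mi_bruteforce(s, s, 8)  # I(S,S) = H(S) under this binning
            hq = mi_bruteforce(q, q, 8)
            assert 0.0 <= mi <= min(hs, hq) + 1e-12

    def test_constant_series_flagged_zero(self):
        with pytest.warns(RuntimeWarning):
            assert mutual_information(np.ones(50), 1, 8) == 0.0

    def test_too_few_pairs_raises(self):
        with pytest.raises(InvalidInputError):
            mutual_information(np.arange(12.0), 5, 4)


class TestSelectDelay:
    def test_sine_first_minimum_near_quarter_period(self):
        """Quarter-period MI minimum of a period-40 sinusoid; a small
        observation noise keeps the sampled values from collapsing onto
        a 40-point grid, which flattens the histogram profile."""
        n = np.arange(4000)
        x = np.sin(2 * np.pi * n / 40)
        x = x + np.random.default_rng(0).normal(0, 0.02, n.size)
        profile = select_delay(x, 20, 16)
        assert profile.selected is not None
        assert 8 <= profile.selected <= 12

    def test_monotone_ramp_has_no_minimum(self):
        profile = select_delay(np.arange(200.0), 30, 16)
        assert profile.selected is None

    def test_profile_deterministic(self):
        x = np.sin(np.arange(500) * 0.13)
        p1 = select_delay(x, 25, 12)
        p2 = select_delay(x, 25, 12)
        np.testing.assert_array_equal(p1.mi_bits, p2.mi_bits)
        assert p1.selected == p2.selected

    def test_max_lag_too_large_raises(self):
        with pytest.raises(InvalidInputError):
            select_delay(np.arange(40.0), 25, 8)


class TestFnn:
    def test_sine_two_dimensional(self):
        """A sinusoid's limit cycle embeds in two dimensions: nearly all
        one-dimensional neighbors are false, none survive at m=2.  An
        irrational frequency avoids exact repeats of the delay
        vectors."""
        x = np.sin(2 * np.pi * (np.sqrt(2.0) / 50.0) * np.arange(2000))
        assert fnn_fraction(x, 1, 9, 15.0, 9) > 0.8
        assert fnn_fraction(x, 2, 9, 15.0, 9) < 0.02
        assert select_embedding_dim(x, 9, 6).selected == 2

    def test_iid_noise_mostly_false_at_m1(self):
        x = np.random.default_rng(3).normal(size=1000)
        assert fnn_fraction(x, 1, 1, 15.0, 1) > 0.9

    def test_fraction_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for x in (rng.normal(size=300), np.sin(np.arange(300) * 0.31)):
            for m in (1, 2, 4):
                assert 0.0 <= fnn_fraction(x, m, 2, 15.0, 2) <= 1.0

    def test_monotone_on_deterministic_series(self):
        x = np.sin(2 * np.pi * (np.sqrt(2.0) / 50.0) * np.arange(1500))
        fracs = [fnn_fraction(x, m, 9, 15.0, 9) for m in range(1, 5)]
        assert all(b <= a + 1e-9 for a, b in zip(fracs, fracs[1:]))

    def test_lorenz_three_dimensional(self):
        """The Lorenz-63 attractor unfolds at embedding dimension 3."""
        x = lorenz63(5000)
        tau = select_delay(x, 50, 16).selected
        assert tau is not None
        profile = select_embedding_dim(x, tau, 6, r_threshold=15.0)
        assert profile.selected == 3

    def test_selection_deterministic(self):
        x = np.sin(2 * np.pi * (np.sqrt(2.0) / 50.0) * np.arange(800))
        p1 = select_embedding_dim(x, 9, 5)
        p2 = select_embedding_dim(x, 9, 5)
        np.testing.assert_array_equal(p1.fractions, p2.fractions)
        assert p1.selected == p2.selected
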