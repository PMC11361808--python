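import numpy as np
import pytest

from twas_knockoff.correlation import GeneCorrelation
from twas_knockoff.filter import (
    GhostKnockoffFilter,
    estimated_fdp,
    evaluate_selection,
    importance_scores,
    kappa_tau,
    knockoff_threshold,
    select,
)

from conftest import random_correlation


def brute_force_threshold(kappa, tau, alpha, M):
    """Independent enumeration of the data-dependent threshold."""
    best = np.inf
    for t in sorted(set(tau[tau > 0])):
        n_knock = sum(1 for k, tv in zip(kappa, tau) if k >= 1 and tv >= t)
        n_orig = sum(1 for k, tv in zip(kappa, tau) if k == 0 and tv >= t)
        fdp = (1 / M + n_knock / M) / max(1, n_orig)
        if fdp <= alpha and t < best:
            best = t
    return best


class TestImportanceScores:
    def test_elementwise_squares(self, rng):
        z = rng.standard_normal(10)
        zk = rng.standard_normal((10, 4))
        T, TK = importance_scores(z, zk)
        np.testing.assert_allclose(T, z**2)
        np.testing.assert_allclose(TK, zk**2)
        assert importance_scores(np.array(-3.0), np.array([0.0]))[0] == 9.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="conform"):
            importance_scores(np.zeros(3), np.zeros((4, 2)))


class TestKappaTau:
    def test_original_wins(self):
        kappa, tau, delta = kappa_tau(9.0, np.array([1.0, 2, 3, 4, 5]))
        assert kappa == 0
        assert tau == pytest.approx(6.0)  # 9 - median(1..5)
        assert delta == pytest.approx(6.0)

    def test_knockoff_wins_zeroes_delta(self):
        kappa, tau, delta = kappa_tau(1.0, np.array([4.0, 0, 0, 0, 0]))
        assert kappa == 1
        # pooled max 4 minus median of the remaining scores (1,0,0,0,0)
        assert tau == pytest.approx(4.0)
        assert delta == 0.0

    def test_single_knockoff_case(self):
        kappa, tau, delta = kappa_tau(5.0, np.array([2.0]))
        assert (kappa, tau, delta) == (0, 3.0, 3.0)

    def test_tie_counts_as_knockoff_win(self):
        kappa, tau, delta = kappa_tau(4.0, np.array([4.0, 1.0]))
        assert kappa >= 1
        assert delta == 0.0

    def test_even_m_median_averages_middle_pair(self):
        kappa, tau, delta = kappa_tau(10.0, np.array([1.0, 2.0]))
        assert tau == pytest.approx(10.0 - 1.5)

    def test_vectorized_matches_scalar(self, rng):
        T = rng.exponential(size=20)
        TK = rng.exponential(size=(20, 5))
        kappa, tau, delta = kappa_tau(T, TK)
        for g in range(20):
            k, t, d = kappa_tau(T[g], TK[g])
            assert kappa[g] == k
            assert tau[g] == pytest.approx(t)
            assert delta[g] == pytest.approx(d)

    def test_delta_nonzero_only_when_original_wins(self, rng):
        T = rng.exponential(size=100)
        TK = rng.exponential(size=(100, 3))
        kappa, tau, delta = kappa_tau(T, TK)
        assert np.all((delta != 0) <= (kappa == 0))
        np.testing.assert_allclose(delta[kappa == 0], tau[kappa == 0])


class TestThreshold:
    def test_worked_single_knockoff_example(self):
        kappa = np.array([0, 0, 0, 1])
        tau = np.array([3.0, 2.0, 1.0, 0.5])
        t_hat, fdp = knockoff_threshold(kappa, tau, alpha=0.5, M=1)
        assert t_hat == 1.0
        assert fdp == pytest.approx(1 / 3)
        res = select(kappa, tau, np.where(kappa == 0, tau, 0.0), t_hat)
        assert res.selected == ["0", "1", "2"]

    def test_all_originals_win(self):
        kappa = np.zeros(10, dtype=int)
        tau = np.linspace(1, 10, 10)
        t_hat, fdp = knockoff_threshold(kappa, tau, alpha=0.05, M=5)
        assert t_hat == tau.min()  # (1/5)/10 = 0.02 <= 0.05 at the smallest tau
        assert fdp == pytest.approx(0.02)

    def test_no_qualifying_threshold_gives_empty_selection(self):
        kappa = np.array([1, 2])
        tau = np.array([5.0, 3.0])
        t_hat, _ = knockoff_threshold(kappa, tau, alpha=0.1, M=5)
        assert t_hat == np.inf
        res = select(kappa, tau, np.zeros(2), t_hat)
        assert res.selected == []

    def test_single_strong_gene_selected_at_loose_alpha(self):
        t_hat, _ = knockoff_threshold(np.array([0]), np.array([5.0]), 0.9, 5)
        assert t_hat == 5.0

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            knockoff_threshold(np.array([0]), np.array([1.0]), alpha=1.5, M=1)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.integers(3, 40)
        M = int(rng.integers(1, 6))
        alpha = float(rng.uniform(0.02, 0.5))
        T = rng.exponential(size=D) * rng.choice([1, 5], size=D)
        TK = rng.exponential(size=(D, M))
        kappa, tau, delta = kappa_tau(T, TK)
        t_hat, _ = knockoff_threshold(kappa, tau, alpha, M)
        assert t_hat == brute_force_threshold(kappa, tau, alpha, M)
        res = select(kappa, tau, delta, t_hat)
        expected = {
            str(g)
            for g in range(D)
            if kappa[g] == 0 and np.isfinite(t_hat) and tau[g] >= t_hat
        }
        assert set(res.selected) == expected

    def test_threshold_monotone_in_alpha(self, rng):
        D, M = 200, 3
        kappa = rng.integers(0, M + 1, size=D)
        tau = rng.exponential(size=D)
        prev_t = np.inf
        prev_sel: set = set()
        for alpha in (0.01, 0.05, 0.1, 0.3, 0.6):
            t_hat, _ = knockoff_threshold(kappa, tau, alpha, M)
            assert t_hat <= prev_t
            delta = np.where(kappa == 0, tau, 0.0)
            sel = set(select(kappa, tau, delta, t_hat).selected)
            assert prev_sel <= sel
            prev_t, prev_sel = t_hat, sel

    def test_selection_threshold_consistency(self, rng):
        kappa = rng.integers(0, 4, size=50)
        tau = rng.exponential(size=50)
        delta = np.where(kappa == 0, tau, 0.0)
        t_hat, _ = knockoff_threshold(kappa, tau, 0.2, 3)
        via_delta = set(select(kappa, tau, delta, t_hat).selected)
        direct = {
            str(g) for g in range(50) if kappa[g] == 0 and tau[g] >= t_hat
        }
        assert via_delta == direct


class TestEvaluate:
    def test_plugin_values(self):
        mfdr, tpp = evaluate_selection({"a", "b"}, {"a"}, alpha=0.05)
        assert mfdr == pytest.approx(1 / 22)
        assert tpp == 1.0

    def test_empty_selection(self):
        mfdr, tpp = evaluate_selection(set(), {"a"}, alpha=0.05)
        assert mfdr == 0.0
        assert tpp == 0.0

    def test_selection_subset_of_truth(self):
        mfdr, _ = evaluate_selection({"a"}, {"a", "b"}, alpha=0.1)
        assert mfdr == 0.0

    def test_empty_truth_gives_missing_tpp(self):
        _, tpp = evaluate_selection({"a"}, set(), alpha=0.1)
        assert tpp is None


class TestGhostKnockoffFilterEstimator:
    def test_fit_sets_fitted_attributes(self, rng):
        D = 30
        S = random_correlation(rng, D)
        z = rng.standard_normal(D)
        filt = GhostKnockoffFilter(alpha=0.2, M=3, random_state=0).fit(z, S)
        assert filt.support_.shape == (D,)
        assert filt.z_knockoff_.shape == (D, 3)
        assert filt.kappa_.shape == (D,)
        assert len(filt.selected_genes_) == filt.support_.sum()
        np.testing.assert_array_equal(
            filt.get_support(indices=True), np.flatnonzero(filt.support_)
        )

    def test_deterministic_given_seed(self, rng):
        S = random_correlation(rng, 20)
        z = rng.standard_normal(20)
        a = GhostKnockoffFilter(random_state=42).fit(z, S)
        b = GhostKnockoffFilter(random_state=42).fit(z, S)
        np.testing.assert_array_equal(a.z_knockoff_, b.z_knockoff_)
        np.testing.assert_array_equal(a.support_, b.support_)

    def test_accepts_gene_correlation_and_propagates_ids(self, rng):
        S = random_correlation(rng, 5)
        gc = GeneCorrelation(gene_ids=list("abcde"), matrix=S)
        filt = GhostKnockoffFilter(alpha=0.5, M=2, random_state=1).fit(
            np.array([4.0, 0.1, -0.2, 3.5, 0.0]), gc
        )
        assert filt.gene_ids_ == list("abcde")
        assert set(filt.selected_genes_) <= set("abcde")

    def test_parameter_validation(self, rng):
        S = random_correlation(rng, 4)
        z = np.zeros(4)
        with pytest.raises(ValueError, match="alpha"):
            GhostKnockoffFilter(alpha=1.5).fit(z, S)
        with pytest.raises(ValueError, match="M"):
            GhostKnockoffFilter(M=0).fit(z, S)
        with pytest.raises(ValueError, match="s_method"):
            GhostKnockoffFilter(s_method="magic").fit(z, S)
        with pytest.raises(ValueError, match="genes"):
            GhostKnockoffFilter().fit(np.zeros(3), S)

    def test_sklearn_get_set_params_roundtrip(self):
        filt = GhostKnockoffFilter(alpha=0.1, M=7)
        params = filt.get_params()
        assert params["alpha"] == 0.1 and params["M"] == 7
        filt.set_params(alpha=0.2)
        assert filt.alpha == 0.2

    def test_estimated_fdp_definition(self):
        kappa = np.array([0, 0, 1, 2])
        tau = np.array([3.0, 2.0, 2.5, 0.1])
        # at t=2: 2 original wins, 1 knockoff win above threshold
        assert estimated_fdp(kappa, tau, 2.0, M=5) == pytest.approx(
            (1 / 5 + 1 / 5) / 2
        )
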