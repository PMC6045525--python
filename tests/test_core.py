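"""Likelihood, posterior and EM machinery against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import painlca as pl
from painlca.core import _em_single_start, _encode_patterns

from conftest import (
    all_patterns,
    brute_force_loglik,
    brute_force_pattern_prob,
    brute_force_posterior,
    fixture_from_params,
)


class TestPatternLogProbability:
    def test_uniform_independent_items(self):
        params = pl.LCAParameters(gamma=[1.0], rho=[[0.5] * 4])
        assert pl.pattern_log_probability(params, [1, 0, 1, 0]) == pytest.approx(
            np.log(1 / 16)
        )

    def test_fully_missing_pattern_has_probability_one(self, two_class_params):
        lp = pl.pattern_log_probability(
            two_class_params, [np.nan, np.nan]
        )
        assert lp == pytest.approx(0.0, abs=1e-12)

    def test_two_class_hand_example(self, two_class_params):
        # 0.4*0.9*0.1 + 0.6*0.2*0.8 = 0.132
        lp = pl.pattern_log_probability(two_class_params, [1, 1])
        assert lp == pytest.approx(np.log(0.132), abs=1e-12)

    def test_length_mismatch_raises(self, two_class_params):
        with pytest.raises(ValueError, match="length"):
            pl.pattern_log_probability(two_class_params, [1, 0, 1])

    def test_matches_brute_force_with_missing_items(self, table2_params):
        p = table2_params
        for pattern in ([1, np.nan, 0, 1], [np.nan, 1, np.nan, 0], [0, 0, 0, 0]):
            expected = brute_force_pattern_prob(p.gamma, p.rho, pattern)
            assert pl.pattern_log_probability(p, pattern) == pytest.approx(
                np.log(expected), abs=1e-10
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_complete_pattern_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        C, J = int(rng.integers(1, 4)), int(rng.integers(1, 5))
        g = rng.dirichlet(np.ones(C))
        rho = rng.random((C, J))
        params = pl.LCAParameters(gamma=g, rho=rho)
        total = sum(
            np.exp(pl.pattern_log_probability(params, pat)) for pat in all_patterns(J)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestLogLikelihood:
    def test_empty_data_is_zero_with_warning(self, two_class_params):
        data = pl.ResponseMatrix(np.empty((0, 2)), item_names=("a", "b"))
        with pytest.warns(UserWarning):
            assert pl.log_likelihood(two_class_params, data) == 0.0

    def test_additive_over_records(self, two_class_params):
        data = pl.ResponseMatrix(np.array([[1, 1], [1, 1]], float),
                                 item_names=("a", "b"))
        assert pl.log_likelihood(two_class_params, data) == pytest.approx(
            2 * np.log(0.132), abs=1e-12
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        C, J, n = int(rng.integers(1, 4)), int(rng.integers(1, 5)), int(rng.integers(1, 50))
        params = pl.LCAParameters(
            gamma=rng.dirichlet(np.ones(C)), rho=rng.uniform(0.05, 0.95, (C, J))
        )
        items = rng.integers(0, 2, (n, J)).astype(float)
        items[rng.random((n, J)) < 0.2] = np.nan
        data = pl.ResponseMatrix(items, item_names=tuple(f"i{j}" for j in range(J)))
        assert pl.log_likelihood(params, data) == pytest.approx(
            brute_force_loglik(params.gamma, params.rho, items), abs=1e-10
        )


class TestPosterior:
    def test_identical_rho_rows_give_gamma(self):
        params = pl.LCAParameters(gamma=[0.3, 0.7], rho=[[0.4, 0.6], [0.4, 0.6]])
        data = pl.ResponseMatrix(np.array([[1, 0], [0, 1]], float),
                                 item_names=("a", "b"))
        post = pl.posterior_probabilities(params, data)
        assert np.allclose(post.probs, [[0.3, 0.7], [0.3, 0.7]], atol=1e-12)

    def test_two_class_hand_bayes(self, two_class_params):
        data = pl.ResponseMatrix(np.array([[1, 1]], float), item_names=("a", "b"))
        post = pl.posterior_probabilities(two_class_params, data)
        assert post.probs[0] == pytest.approx([0.036 / 0.132, 0.096 / 0.132], abs=1e-12)
        assert post.assigned[0] == 2

    def test_degenerate_prior_forces_class_one(self):
        params = pl.LCAParameters(gamma=[1.0, 0.0], rho=[[0.5, 0.5], [0.9, 0.9]])
        data = pl.ResponseMatrix(np.array([[1, 0], [1, 1]], float),
                                 item_names=("a", "b"))
        post = pl.posterior_probabilities(params, data)
        assert np.allclose(post.probs[:, 0], 1.0)
        assert (post.assigned == 1).all()

    def test_rows_normalised_and_match_brute_force(self, table2_params):
        rng = np.random.default_rng(5)
        items = rng.integers(0, 2, (40, 4)).astype(float)
        items[rng.random((40, 4)) < 0.25] = np.nan
        data = pl.ResponseMatrix(items)
        post = pl.posterior_probabilities(table2_params, data)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-10)
        for i in range(0, 40, 7):
            expected = brute_force_posterior(
                table2_params.gamma, table2_params.rho, items[i]
            )
            assert post.probs[i] == pytest.approx(expected, abs=1e-10)


class TestEM:
    def test_single_class_closed_form(self):
        rng = np.random.default_rng(3)
        items = rng.integers(0, 2, (200, 3)).astype(float)
        items[rng.random((200, 3)) < 0.1] = np.nan
        data = pl.ResponseMatrix(items, item_names=("a", "b", "c"))
        fit = pl.fit_em(data, 1, pl.EMConfig(seed=1, n_starts=2))
        assert fit.params.gamma == pytest.approx([1.0])
        assert fit.params.rho[0] == pytest.approx(
            np.nanmean(items, axis=0), abs=1e-7
        )

    def test_loglik_monotone_within_a_start(self, well_separated_params):
        fx = fixture_from_params(well_separated_params, "synthetic_sep")
        data = pl.simulate(fx, pl.GeneratorConfig(n_total=300, seed=9))
        patterns, counts = _encode_patterns(
            data.subset(data.any_observed_rows()).items
        )
        cfg = pl.EMConfig(seed=0, n_starts=1, max_iter=1, mad_tol=1e-12)
        rng = np.random.default_rng(12)
        J = well_separated_params.n_items
        gamma = rng.dirichlet(np.ones(3))
        rho = rng.uniform(0.1, 0.9, (3, J))
        params = pl.LCAParameters(gamma=gamma, rho=np.clip(rho, 1e-6, 1 - 1e-6))
        prev = None
        for _ in range(60):  # one EM sweep at a time; loglik must never drop
            gamma, rho, ll, *_ = _em_single_start(
                patterns, counts, 3, cfg, rng, init=(gamma, rho)
            )
            if prev is not None:
                assert ll >= prev - 1e-9
            prev = ll

    def test_recovers_well_separated_classes(self, well_separated_params):
        fx = fixture_from_params(well_separated_params, "synthetic_sep")
        data = pl.simulate(fx, pl.GeneratorConfig(n_total=2000, seed=21))
        fit = pl.fit_em(data, 3, pl.EMConfig(seed=4, n_starts=8, mad_tol=1e-7))
        aligned = pl.align_classes(fit.params, well_separated_params)
        assert np.abs(aligned.gamma - well_separated_params.gamma).max() < 0.04
        assert np.abs(aligned.rho - well_separated_params.rho).max() < 0.08

    def test_too_many_classes_warns(self):
        data = pl.ResponseMatrix(
            np.array([[0, 0], [1, 1], [0, 0]], float), item_names=("a", "b")
        )
        with pytest.warns(UserWarning, match="identifiab"):
            pl.fit_em(data, 3, pl.EMConfig(seed=1, n_starts=1, max_iter=50,
                                           mad_tol=1e-4))


class TestMarginalsAndAlignment:
    def test_single_class_marginals_equal_rho(self):
        params = pl.LCAParameters(gamma=[1.0], rho=[[0.2, 0.8, 0.5]])
        assert pl.model_implied_marginals(params) == pytest.approx([0.2, 0.8, 0.5])

    def test_table2_marginals_reproduce_published_prevalences(self, table2_params):
        marg = pl.model_implied_marginals(table2_params)
        # neck 27.9%, shoulder 20.7% (item order: neck, shoulder, upper, low)
        assert marg[0] == pytest.approx(0.2792, abs=1e-12)
        assert marg[1] == pytest.approx(0.20726, abs=1e-12)

    def test_align_identity_and_inverse_swap(self, table2_params):
        p = table2_params
        assert np.allclose(pl.align_classes(p, p).rho, p.rho)
        swapped = pl.LCAParameters(
            gamma=p.gamma[[2, 0, 1]], rho=p.rho[[2, 0, 1]], item_names=p.item_names
        )
        back = pl.align_classes(swapped, p)
        assert np.allclose(back.rho, p.rho)
        assert np.allclose(back.gamma, p.gamma)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_align_recovers_random_shuffle_exhaustively(self, seed):
        rng = np.random.default_rng(seed)
        params = pl.LCAParameters(
            gamma=rng.dirichlet(np.ones(3)), rho=rng.random((3, 4))
        )
        perm = rng.permutation(3)
        shuffled = pl.LCAParameters(gamma=params.gamma[perm], rho=params.rho[perm])
        recovered = pl.align_classes(shuffled, params)
        assert np.allclose(recovered.rho, params.rho)

    def test_sort_classes_orders_by_mean_rho(self):
        params = pl.LCAParameters(
            gamma=[0.2, 0.5, 0.3],
            rho=[[0.9, 0.8], [0.1, 0.2], [0.5, 0.5]],
        )
        s = pl.sort_classes_by_severity(params)
        assert np.allclose(s.rho.mean(axis=1), sorted(params.rho.mean(axis=1)))
        assert np.allclose(s.gamma, [0.5, 0.3, 0.2])
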