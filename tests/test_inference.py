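import math

import numpy as np
import pytest

from netmatch.inference import (
    ChoiceLikelihood,
    ChoiceRecord,
    LogNormPrior,
    MCMCConfig,
    ModelComparison,
    TruncNormPrior,
    aicc,
    compare_models,
    fit_choices_separately,
    fit_hierarchical,
    fit_participant,
    fit_shared,
    gelman_rubin,
    log_posterior,
    marginal_loglik,
    mh_chain,
    participant_loglik,
)
from netmatch.netgrow import Graph
from netmatch.synthetic_data import CohortConfig, generate_cohort

from conftest import k4


def grid_posterior(record, graph, prior, which="both", n_grid=401):
    """Independent dense-grid posterior: direct degree powers, no log tricks."""
    grid = np.linspace(prior.lo, prior.hi, n_grid)
    deg = graph.degrees().astype(float)
    post = np.empty(n_grid)
    for i, L in enumerate(grid):
        w = deg**L
        p1 = w[record.first_choice] / w.sum()
        w2 = w.copy()
        w2[record.first_choice] = 0
        p2 = w2[record.second_choice] / w2.sum()
        if which == "first":
            lik = p1
        elif which == "second":
            lik = p2
        else:
            lik = p1 * p2
        z = (L - prior.mu) / prior.sd
        post[i] = lik * math.exp(-0.5 * z * z)
    post /= post.sum()
    return grid, post


class TestParticipantLoglik:
    def test_path_center_then_endpoint(self, path3_graph):
        rec = ChoiceRecord("p", 1, 0)
        assert participant_loglik(rec, path3_graph, 1.0) == pytest.approx(
            math.log(0.25)
        )

    def test_value_blind_is_uniform(self, stimulus):
        rec = ChoiceRecord("p", 3, 17)
        n = stimulus.node_count
        assert participant_loglik(rec, stimulus, 0.0) == pytest.approx(
            math.log(1 / n) + math.log(1 / (n - 1))
        )

    @pytest.mark.parametrize("L", [-7.3, -1.0, 0.5, 2.0, 9.9])
    def test_matches_arbitrary_precision_oracle(self, stimulus, L):
        import sympy

        rec = ChoiceRecord("p", 0, 24)
        deg = [sympy.Integer(int(d)) for d in stimulus.degrees()]
        Ls = sympy.Float(L, 50)
        w = [sympy.Pow(d, Ls) for d in deg]
        total = sum(w)
        p1 = w[rec.first_choice] / total
        p2 = w[rec.second_choice] / (total - w[rec.first_choice])
        expected = float(sympy.log(p1 * p2).evalf(50))
        assert participant_loglik(rec, stimulus, L) == pytest.approx(
            expected, abs=1e-12
        )

    def test_invalid_node_raises(self, stimulus):
        with pytest.raises(ValueError):
            participant_loglik(ChoiceRecord("p", 0, 99), stimulus, 1.0)

    def test_vectorised_likelihood_agrees_with_reference(self, stimulus):
        records = [ChoiceRecord("a", 2, 9), ChoiceRecord("b", 20, 0)]
        lik = ChoiceLikelihood(stimulus, records)
        for L in (-3.0, 0.0, 1.7):
            expected = [participant_loglik(r, stimulus, L) for r in records]
            np.testing.assert_allclose(lik.loglik_scalar(L), expected, atol=1e-10)
            np.testing.assert_allclose(
                lik.loglik_vector(np.array([L, L])), expected, atol=1e-10
            )


class TestLogPosterior:
    def test_outside_truncation_is_minus_inf(self, stimulus):
        rec = ChoiceRecord("p", 0, 1)
        assert log_posterior(rec, stimulus, 10.5, TruncNormPrior()) == -np.inf
        assert log_posterior(rec, stimulus, -11.0, TruncNormPrior()) == -np.inf

    def test_additivity(self, stimulus):
        rec = ChoiceRecord("p", 5, 12)
        prior = TruncNormPrior()
        for L in (-2.0, 0.0, 3.5):
            assert log_posterior(rec, stimulus, L, prior) == pytest.approx(
                participant_loglik(rec, stimulus, L) + prior.logpdf(L)
            )

    def test_prior_only_maximised_at_prior_mode(self):
        prior = TruncNormPrior()
        grid = np.linspace(-10, 10, 401)
        vals = [prior.logpdf(g) for g in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.0, abs=0.06)


class TestMHChain:
    def test_standard_normal_target(self, rng):
        cfg = MCMCConfig(seed=0)
        samples, _ = mh_chain(
            lambda x: -0.5 * x * x, 0.0, cfg, rng, n_keep=100_000
        )
        assert samples.mean() == pytest.approx(0.0, abs=0.02)
        assert samples.std() == pytest.approx(1.0, abs=0.02)

    def test_infinite_start_raises(self, rng):
        with pytest.raises(ValueError):
            mh_chain(lambda x: -np.inf, 0.0, MCMCConfig(), rng)

    def test_matches_grid_posterior(self, stimulus, rng):
        rec = ChoiceRecord("p", 1, 7)
        prior = TruncNormPrior()
        lik = ChoiceLikelihood(stimulus, [rec])

        def logpost(L):
            if not (-10 <= L <= 10):
                return -np.inf
            return float(lik.loglik_scalar(L)[0]) + prior.logpdf(L)

        cfg = MCMCConfig(seed=0)
        pooled = np.concatenate(
            [
                mh_chain(logpost, s, cfg, rng, n_keep=200_000)[0]
                for s in cfg.starts
            ]
        )
        grid, post = grid_posterior(rec, stimulus, prior)
        edges = np.concatenate([[grid[0] - 0.025], grid + 0.025])
        hist, _ = np.histogram(pooled, bins=edges)
        tv = 0.5 * np.abs(hist / hist.sum() - post).sum()
        assert tv < 0.02

    def test_degenerate_target_flagged_by_rhat(self, rng):
        # accept only the exact start value: chains never move
        def logdens(x):
            return 0.0 if x == 0.0 else -np.inf

        cfg = MCMCConfig(seed=0)
        chains = [mh_chain(logdens, 0.0, cfg, rng, n_keep=100)[0] for _ in range(3)]
        assert gelman_rubin(chains) == np.inf


class TestGelmanRubin:
    def test_same_distribution_converged(self, rng):
        chains = [rng.normal(size=10_000) for _ in range(4)]
        assert gelman_rubin(chains) < 1.01

    def test_separated_chains_flagged(self, rng):
        chains = [
            rng.normal(-5, 0.1, size=1000),
            rng.normal(5, 0.1, size=1000),
        ]
        assert gelman_rubin(chains) > 10

    def test_hand_computed_example(self):
        # chains [1,2,3,4] and [3,4,5,6]; split halves: [1,2],[3,4],[3,4],[5,6]
        # W = mean(var) = 0.5; B = n * var(means) = 2 * var([1.5,3.5,3.5,5.5])
        # var(means, ddof=1) = 8/3 -> B = 16/3
        # var_plus = (1/2)*0.5 + (16/3)/2 = 0.25 + 8/3 = 35/12
        # rhat = sqrt((35/12)/0.5) = sqrt(35/6)
        rhat = gelman_rubin([np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])])
        assert rhat == pytest.approx(math.sqrt(35 / 6))

    def test_fewer_than_two_chains_raises(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.arange(10)])


class TestFitParticipant:
    def test_map_matches_grid_argmax(self, stimulus, fast_config, rng):
        prior = TruncNormPrior()
        for first, second in [(0, 3), (20, 24)]:
            rec = ChoiceRecord("p", first, second)
            fit = fit_participant(rec, stimulus, prior, fast_config, rng)
            grid, post = grid_posterior(rec, stimulus, prior)
            assert fit.converged
            assert fit.L_map == pytest.approx(grid[int(np.argmax(post))], abs=0.05)

    def test_symmetric_records_agree(self, stimulus, fast_config):
        # two records whose choices swap nodes of equal degree
        deg = stimulus.degrees()
        same = [i for i in range(25) if deg[i] == 3]
        a, b = same[0], same[1]
        f1 = fit_participant(
            ChoiceRecord("p", a, b), stimulus, config=fast_config
        )
        f2 = fit_participant(
            ChoiceRecord("q", b, a), stimulus, config=fast_config
        )
        assert f1.L_map == pytest.approx(f2.L_map, abs=0.15)

    def test_rhat_reported_below_threshold(self, stimulus, fast_config):
        fit = fit_participant(ChoiceRecord("p", 0, 1), stimulus, config=fast_config)
        assert 1.0 <= fit.rhat < fast_config.rhat_threshold


class TestFitChoicesSeparately:
    def test_equal_degree_choices_agree(self, stimulus, fast_config):
        deg = stimulus.degrees()
        same = [i for i in range(25) if deg[i] == 3]
        rec = ChoiceRecord("p", same[0], same[1])
        f1, f2 = fit_choices_separately(rec, stimulus, config=fast_config)
        assert f1.L_map == pytest.approx(f2.L_map, abs=0.3)

    def test_first_fit_matches_first_only_grid(self, stimulus, fast_config, rng):
        rec = ChoiceRecord("p", 0, 5)
        prior = TruncNormPrior()
        f1, _ = fit_choices_separately(rec, stimulus, prior, fast_config, rng)
        grid, post = grid_posterior(rec, stimulus, prior, which="first")
        assert f1.L_map == pytest.approx(grid[int(np.argmax(post))], abs=0.1)


class TestFitShared:
    def test_recovers_common_L(self, fast_config):
        cohort = generate_cohort(
            CohortConfig(n_participants=200, L_mean=1.0, L_sd=0.0, cohort_seed=8)
        )
        fit = fit_shared(cohort.records, cohort.stimulus, config=fast_config)
        q_lo, q_hi = np.percentile(fit.samples, [2.5, 97.5])
        assert q_lo < 1.0 < q_hi
        assert fit.L_map == pytest.approx(1.0, abs=0.3)

    def test_single_record_reduces_to_participant_fit(self, stimulus, fast_config):
        rec = ChoiceRecord("p", 4, 9)
        shared = fit_shared([rec], stimulus, config=fast_config)
        single = fit_participant(rec, stimulus, config=fast_config)
        assert shared.L_map == pytest.approx(single.L_map, abs=0.1)

    def test_empty_records_raise(self, stimulus, fast_config):
        with pytest.raises(ValueError):
            fit_shared([], stimulus, config=fast_config)


class TestFitHierarchical:
    def test_near_degenerate_sigma(self, fast_config):
        cohort = generate_cohort(
            CohortConfig(n_participants=100, L_mean=1.0, L_sd=0.01, cohort_seed=2)
        )
        pop = fit_hierarchical(cohort.records, cohort.stimulus, config=fast_config)
        shared = fit_shared(cohort.records, cohort.stimulus, config=fast_config)
        assert pop.sigma_map < 0.5
        assert pop.mu_map == pytest.approx(shared.L_map, abs=0.3)

    def test_order_invariance(self, fast_config):
        cohort = generate_cohort(
            CohortConfig(n_participants=80, L_mean=0.0, L_sd=2.0, cohort_seed=3)
        )
        pop1 = fit_hierarchical(cohort.records, cohort.stimulus, config=fast_config)
        pop2 = fit_hierarchical(
            cohort.records[::-1], cohort.stimulus, config=fast_config
        )
        assert pop1.mu_samples.mean() == pytest.approx(pop2.mu_samples.mean(), abs=0.3)
        assert pop1.sigma_samples.mean() == pytest.approx(
            pop2.sigma_samples.mean(), abs=0.4
        )

    def test_needs_two_records(self, stimulus, fast_config):
        with pytest.raises(ValueError):
            fit_hierarchical([ChoiceRecord("p", 0, 1)], stimulus, config=fast_config)

    def test_ci_ordered_and_contains_map(self, fast_config):
        cohort = generate_cohort(
            CohortConfig(n_participants=100, L_mean=0.5, L_sd=3.0, cohort_seed=5)
        )
        pop = fit_hierarchical(cohort.records, cohort.stimulus, config=fast_config)
        assert pop.mu_ci[0] < pop.mu_ci[1]
        assert pop.sigma_ci[0] < pop.sigma_ci[1]
        assert pop.sigma_map > 0


class TestMarginalLoglik:
    def test_sigma_zero_limit(self, stimulus):
        rec = ChoiceRecord("p", 2, 11)
        for mu in (-1.0, 0.68, 4.0):
            assert marginal_loglik(rec, stimulus, mu, 0.0) == pytest.approx(
                participant_loglik(rec, stimulus, mu)
            )
            assert marginal_loglik(rec, stimulus, mu, 1e-4) == pytest.approx(
                participant_loglik(rec, stimulus, mu), abs=1e-3
            )

    def test_agrees_with_monte_carlo(self, stimulus, rng):
        rec = ChoiceRecord("p", 0, 7)
        lik = ChoiceLikelihood(stimulus, [rec])
        mu, sigma = 0.5, 2.0
        n_mc = 1_000_000
        draws = rng.normal(mu, sigma, size=n_mc)
        vals = np.exp(lik.loglik_vector(np.clip(draws, -30, 30)))
        mc = vals.mean()
        se = vals.std() / math.sqrt(n_mc)
        for method in ("quad", "gauss"):
            est = math.exp(marginal_loglik(rec, stimulus, mu, sigma, method=method))
            assert abs(est - mc) < 3 * se

    def test_uniform_likelihood_graph(self):
        # complete graph: all degrees equal, so both choices are uniform and
        # the marginal is constant in (mu, sigma)
        g = Graph.from_edges(
            5, [(i, j) for i in range(5) for j in range(i + 1, 5)]
        )
        rec = ChoiceRecord("p", 0, 3)
        expected = math.log(1 / 5) + math.log(1 / 4)
        for mu, sigma in [(0.0, 1.0), (-3.0, 4.0), (5.0, 0.5)]:
            assert marginal_loglik(rec, g, mu, sigma) == pytest.approx(
                expected, abs=1e-6
            )

    def test_quad_and_gauss_agree(self, stimulus):
        rec = ChoiceRecord("p", 20, 3)
        for mu, sigma in [(0.68, 3.1), (-2.0, 1.0)]:
            assert marginal_loglik(rec, stimulus, mu, sigma, "quad") == pytest.approx(
                marginal_loglik(rec, stimulus, mu, sigma, "gauss"), abs=1e-4
            )


class TestAicc:
    def test_arithmetic(self):
        assert aicc(-100.0, 1, 1200) == pytest.approx(200 + 2 + 4 / 1198)
        assert aicc(0.0, 2, 5) == pytest.approx(10.0)

    def test_limit_to_aic(self):
        assert aicc(-50.0, 3, 10**9) == pytest.approx(100 + 6, abs=1e-6)

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            aicc(0.0, 2, 3)
        with pytest.raises(ValueError):
            aicc(0.0, 0, 100)


class TestCompareModels:
    def test_delta_field_is_exact_difference(self):
        comp = ModelComparison(aicc_shared=10.0, aicc_hier=7.5, n_obs=100)
        assert comp.delta == 10.0 - 7.5

    def test_no_individual_differences_prefers_shared(self):
        cohort = generate_cohort(
            CohortConfig(n_participants=100, L_mean=1.0, L_sd=0.0, cohort_seed=4)
        )
        comp = compare_models(cohort.records, cohort.stimulus)
        # identical maximised likelihoods leave only the parameter penalties
        assert comp.delta <= 0
        assert comp.delta == pytest.approx(
            aicc(0, 1, comp.n_obs) - aicc(0, 2, comp.n_obs), abs=0.5
        )

    def test_individual_differences_prefer_hierarchical(self):
        cohort = generate_cohort(
            CohortConfig(n_participants=150, L_mean=0.68, L_sd=3.1, cohort_seed=6)
        )
        comp = compare_models(cohort.records, cohort.stimulus)
        assert comp.delta > 20

    def test_empty_records_raise(self, stimulus):
        with pytest.raises(ValueError):
            compare_models([], stimulus)


class TestRecordValidation:
    def test_identical_choices_rejected(self):
        with pytest.raises(ValueError):
            ChoiceRecord("p", 3, 3)
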