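"""Posterior engine: prior summaries, quadrature, Metropolis sampler, prob_best."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from rartrial import (
    ArmCounts,
    GridError,
    GridSpec,
    InvalidPriorError,
    PriorSpec,
    SamplerWarning,
    fit_posterior,
    posterior_quadrature,
    prior_summary,
    prob_best,
    sample_posterior,
)

PRIOR = PriorSpec()


class TestPriorSummary:
    def test_design_prior_is_diffuse(self):
        """Median 2.9% with 95% mass from 0.16% to 36% on the rate scale."""
        s = prior_summary(PRIOR, level=0.95)
        assert round(100 * s.point, 1) == 2.9
        assert round(100 * s.lower, 2) == 0.16
        assert round(100 * s.upper) == 36

    def test_centered_prior_is_symmetric(self):
        s = prior_summary(PriorSpec(mu=0.0, sigma=1.0), level=0.95)
        assert s.point == pytest.approx(0.5)
        assert s.lower == pytest.approx(1.0 - s.upper, abs=1e-12)

    def test_degenerate_sigma_collapses_interval(self):
        s = prior_summary(PriorSpec(mu=-3.5, sigma=1e-9), level=0.95)
        assert s.lower == pytest.approx(s.point, abs=1e-8)
        assert s.upper == pytest.approx(s.point, abs=1e-8)

    @pytest.mark.parametrize("sigma", [0.0, -1.5])
    def test_invalid_sigma_rejected(self, sigma):
        with pytest.raises(InvalidPriorError):
            PriorSpec(sigma=sigma)

    @pytest.mark.parametrize("level", [0.0, 1.0, 1.2])
    def test_invalid_level_rejected(self, level):
        with pytest.raises(ValueError):
            prior_summary(PRIOR, level=level)


class TestQuadrature:
    def test_no_data_recovers_prior(self):
        """With zero births the posterior is the prior, to 4 decimals.

        Uses a grid wide enough to hold the full prior mass (the default
        upper bound clips ~1e-4 of the prior's upper tail, which is fine for
        rate-scale data but not for recovering prior quantiles exactly).
        """
        post = posterior_quadrature(ArmCounts("a", 0, 0), PRIOR, GridSpec(-12.0, 5.0, 8001))
        s = prior_summary(PRIOR, level=0.95)
        assert post.median == pytest.approx(s.point, abs=1e-4)
        lo, hi = post.interval(0.95)
        assert lo == pytest.approx(s.lower, abs=1e-4)
        assert hi == pytest.approx(s.upper, abs=1e-4)

    def test_weights_normalized_and_moments_grid_converged(self):
        counts = ArmCounts("a", 150, 6)
        post = posterior_quadrature(counts, PRIOR)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)
        fine = posterior_quadrature(counts, PRIOR, GridSpec(-12.0, 2.0, 8001))
        assert abs(post.mean - fine.mean) < 1e-6

    def test_reference_value_six_events_in_150(self):
        """Mean frozen from the double-resolution quadrature oracle."""
        post = posterior_quadrature(ArmCounts("a", 150, 6), PRIOR)
        assert post.mean == pytest.approx(0.0393262, abs=1e-6)
        assert post.interval(0.95)[0] < post.mean < post.interval(0.95)[1]

    def test_saturated_data_overwhelm_prior(self):
        """All-events data push the mean above 0.9 despite a 3%-centered prior."""
        post = posterior_quadrature(
            ArmCounts("a", 150, 150), PRIOR, GridSpec(-12.0, 10.0, 8001)
        )
        assert post.mean > 0.9

    def test_narrow_grid_rejected(self):
        with pytest.raises(GridError):
            posterior_quadrature(ArmCounts("a", 150, 150), PRIOR)

    def test_data_dominance_at_large_n(self):
        p = 0.03
        post = posterior_quadrature(ArmCounts("a", 100_000, 3000), PRIOR)
        assert abs(post.mean - p) < 0.002

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ArmCounts("a", 10, 11)
        with pytest.raises(ValueError):
            ArmCounts("a", -1, 0)


class TestSampler:
    def test_seeded_draws_are_bitwise_reproducible(self):
        a = sample_posterior(ArmCounts("a", 150, 6), PRIOR, n_draws=2000, seed=7)
        b = sample_posterior(ArmCounts("a", 150, 6), PRIOR, n_draws=2000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_prior_sampling_matches_prior_moments(self):
        draws = sample_posterior(ArmCounts("a", 0, 0), PRIOR, n_draws=50_000, seed=1)
        ref = posterior_quadrature(ArmCounts("a", 0, 0), PRIOR)
        se = draws.std(ddof=1) / np.sqrt(_ess(draws))
        assert abs(draws.mean() - ref.mean) < 3 * se

    def test_posterior_moments_match_quadrature_oracle(self):
        draws = sample_posterior(ArmCounts("a", 150, 6), PRIOR, n_draws=20_000, seed=2)
        ref = posterior_quadrature(ArmCounts("a", 150, 6), PRIOR)
        se = draws.std(ddof=1) / np.sqrt(_ess(draws))
        assert abs(draws.mean() - ref.mean) < 3 * se
        assert np.all((draws > 0) & (draws < 1))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            sample_posterior(ArmCounts("a", 150, 6), PRIOR, n_draws=10, seed=0)

    def test_low_ess_raises_sampler_warning(self, monkeypatch):
        import rartrial.posterior as mod

        monkeypatch.setattr(mod, "effective_sample_size", lambda draws: 50.0)
        with pytest.warns(SamplerWarning):
            mod.sample_posterior(ArmCounts("a", 150, 6), PRIOR, n_draws=1000, seed=0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        births=st.integers(min_value=50, max_value=600),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_sampler_agrees_with_quadrature_across_counts(self, births, frac):
        """Oracle equivalence on a randomized grid of (events, births)."""
        events = min(int(frac * 20), births)
        counts = ArmCounts("a", births, events)
        draws = sample_posterior(counts, PRIOR, n_draws=4000, seed=3)
        ref = posterior_quadrature(counts, PRIOR)
        se = draws.std(ddof=1) / np.sqrt(_ess(draws))
        assert abs(draws.mean() - ref.mean) < 3 * se


def _ess(draws):
    from rartrial.posterior import effective_sample_size

    return effective_sample_size(draws)


class TestProbBest:
    def test_identical_arms_split_exactly(self):
        p = posterior_quadrature(ArmCounts("a", 150, 6), PRIOR)
        q = posterior_quadrature(ArmCounts("b", 150, 6), PRIOR)
        pb = prob_best([p, q])
        np.testing.assert_allclose(pb, [0.5, 0.5], atol=1e-12)
        assert pb.sum() == pytest.approx(1.0, abs=1e-9)

    def test_separated_arms(self):
        lo = posterior_quadrature(ArmCounts("a", 150, 0), PRIOR)
        hi = posterior_quadrature(ArmCounts("b", 150, 150), PRIOR, GridSpec(-12, 10, 4001))
        # same-grid requirement: refit the low arm on the wide grid
        lo = posterior_quadrature(ArmCounts("a", 150, 0), PRIOR, GridSpec(-12, 10, 4001))
        pb = prob_best([lo, hi])
        assert pb[0] > 0.999

    def test_two_dimensional_product_grid_oracle(self):
        """1-D tail-sum path vs brute-force 2-D integration on offset grids."""
        c1, c2 = ArmCounts("a", 150, 6), ArmCounts("b", 150, 2)
        g1 = posterior_quadrature(c1, PRIOR)
        g2 = posterior_quadrature(c2, PRIOR)
        impl = prob_best([g1, g2])
        # brute-force double sum over the product grid (half weight on ties)
        cmp = np.less.outer(g2.theta, g1.theta) + 0.5 * np.equal.outer(
            g2.theta, g1.theta
        )
        oracle_p2_best = float(g2.weights @ cmp @ g1.weights)
        assert impl[1] == pytest.approx(oracle_p2_best, abs=1e-9)
        # grid-independence: densities on distinct offset grids, strict inequality
        o1 = posterior_quadrature(c1, PRIOR, GridSpec(-12.0, 2.0, 5001))
        o2 = posterior_quadrature(c2, PRIOR, GridSpec(-11.9995, 2.0005, 5001))
        offset = float(o2.weights @ np.less.outer(o2.theta, o1.theta) @ o1.weights)
        assert impl[1] == pytest.approx(offset, abs=5e-4)

    def test_monotone_in_own_events(self):
        """More events in arm 1 never increases its probability of being best."""
        fixed = posterior_quadrature(ArmCounts("b", 200, 5), PRIOR)
        prev = 1.1
        for events in range(0, 15, 2):
            p = posterior_quadrature(ArmCounts("a", 150, events), PRIOR)
            pb = prob_best([p, fixed])[0]
            assert pb <= prev + 1e-12
            prev = pb

    def test_draws_route_consistent_with_quadrature(self):
        c1, c2 = ArmCounts("a", 150, 6), ArmCounts("b", 150, 2)
        quad = prob_best(
            [posterior_quadrature(c1, PRIOR), posterior_quadrature(c2, PRIOR)]
        )
        draws = np.vstack(
            [
                sample_posterior(c1, PRIOR, n_draws=40_000, seed=11),
                sample_posterior(c2, PRIOR, n_draws=40_000, seed=12),
            ]
        )
        samp = prob_best(draws)
        assert samp.sum() == pytest.approx(1.0, abs=1e-9)
        assert abs(samp[0] - quad[0]) < 0.01

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError):
            prob_best([posterior_quadrature(ArmCounts("a", 10, 1), PRIOR)])


class TestFitPosterior:
    def test_quadrature_summary_invariants(self):
        res = fit_posterior(
            [ArmCounts("ctl", 150, 6), ArmCounts("trt", 150, 2)], PRIOR
        )
        assert res.prob_best.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.lower <= res.mean) and np.all(res.mean <= res.upper)
        assert np.all((res.mean > 0) & (res.mean < 1))
        assert res.prob_best[1] > res.prob_best[0]

    def test_sampling_method_close_to_quadrature(self):
        counts = [ArmCounts("ctl", 150, 6), ArmCounts("trt", 150, 2)]
        quad = fit_posterior(counts, PRIOR, method="quadrature")
        samp = fit_posterior(counts, PRIOR, method="sampling", n_draws=20_000, seed=5)
        np.testing.assert_allclose(samp.mean, quad.mean, atol=5e-4)
        assert abs(samp.prob_best[0] - quad.prob_best[0]) < 0.02
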