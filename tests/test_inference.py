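"""Drift-null testing and selection estimation against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clonaldrift import (
    ExperimentParams,
    SiteObservation,
    allele_frequency_percent,
    bonferroni_alpha,
    drift_pvalue,
    early_frequency_posterior,
    estimate_selection,
    observed_read_prob,
    selection_likelihood,
    simulate_growth_many,
)
from clonaldrift.inference import _founder_pmf
from conftest import snap_to_grid


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "alt,total,expected",
        [
            (156, 282, 55.32),  # published final-population frequencies
            (42, 3122, 1.35),
            (642, 2996, 21.43),
            (122, 705, 17.30),
            (0, 725, 0.0),
        ],
    )
    def test_matches_published_percentages(self, alt, total, expected):
        assert allele_frequency_percent(alt, total) == pytest.approx(expected, abs=0.005)

    def test_total_zero_is_domain_error(self):
        with pytest.raises(ValueError):
            allele_frequency_percent(0, 0)

    @given(total=st.integers(1, 10_000), frac=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, total, frac):
        alt = int(frac * total)
        assert 0.0 <= allele_frequency_percent(alt, total) <= 100.0


class TestReadModel:
    def test_error_free_limits(self):
        p = ExperimentParams(seq_error=0.0)
        assert observed_read_prob(0.0, p) == 0.0
        assert observed_read_prob(1.0, p) == 1.0

    def test_background_error_is_one_third_epsilon(self):
        p = ExperimentParams(seq_error=3e-3)
        assert observed_read_prob(0.0, p) == pytest.approx(1e-3)

    def test_monotone_in_frequency(self, default_params):
        f = np.linspace(0, 1, 101)
        q = observed_read_prob(f, default_params)
        assert np.all(np.diff(q) > 0)

    def test_diploid_mode_halves_read_probability(self):
        p = ExperimentParams(seq_error=0.0, diploid=True)
        assert observed_read_prob(1.0, p) == pytest.approx(0.5)


class TestEarlyPosterior:
    def test_zero_counts_concentrate_at_zero_with_depth(self, default_params):
        shallow = early_frequency_posterior(0, 50, default_params)
        deep = early_frequency_posterior(0, 50_000, default_params)
        assert deep.mean() < shallow.mean()
        assert deep.cdf(0.001) > 0.99

    def test_balanced_counts_peak_near_half(self, default_params):
        post = early_frequency_posterior(500, 1000, ExperimentParams(seq_error=0.0))
        mode = post.grid[np.argmax(post.probabilities)]
        assert mode == pytest.approx(0.5, abs=1.0 / 512)

    def test_posterior_mean_against_dense_grid_oracle(self, default_params):
        # Brute-force normalisation of the read likelihood on a 20x finer grid.
        post = early_frequency_posterior(42, 3122, default_params)
        f = np.linspace(0, 1, 10_241)[1:-1]
        like = stats.binom.pmf(42, 3122, observed_read_prob(f, default_params))
        oracle = (f * like).sum() / like.sum()
        assert 0.010 <= post.mean() <= 0.017
        assert post.mean() == pytest.approx(oracle, rel=0.01)


class TestBonferroni:
    def test_published_threshold(self):
        # 0.05 / 2.9e5 rounds to 1.7e-7 at two significant figures
        assert bonferroni_alpha(290_000) == pytest.approx(1.7e-7, rel=0.02)

    @pytest.mark.parametrize("n,expected", [(1, 0.05), (100, 5e-4)])
    def test_simple_cases(self, n, expected):
        assert bonferroni_alpha(n) == pytest.approx(expected)


class TestDriftPvalue:
    def test_no_change_from_zero_is_certain(self, default_params):
        res = drift_pvalue(SiteObservation("s", 0, 725, 0, 282), default_params)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_stable_frequency_not_significant(self, default_params):
        res = drift_pvalue(SiteObservation("s", 50, 1000, 50, 1000), default_params)
        assert res.p_value > 0.05

    def test_direction_and_significance_flag(self, default_params):
        gain = drift_pvalue(SiteObservation("g", 0, 725, 156, 282), default_params)
        assert gain.direction == "gain"
        assert gain.significant == (gain.p_value < gain.alpha)
        loss = drift_pvalue(SiteObservation("l", 200, 1000, 5, 1000), default_params)
        assert loss.direction == "loss"

    def test_monotone_in_late_count_for_gains(self, default_params):
        ps = [
            drift_pvalue(
                SiteObservation("s", 10, 1000, k, 1000), default_params
            ).p_value
            for k in (20, 60, 120, 240)
        ]
        assert all(b <= a for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)

    @pytest.mark.parametrize(
        "early_alt,early_total,late_alt,late_total,seed",
        [
            (2, 300, 30, 250, 101),
            (0, 200, 12, 300, 102),
            (15, 400, 4, 350, 103),
            (5, 250, 5, 250, 104),
            (1, 500, 20, 200, 105),
            (8, 300, 40, 400, 106),
            (0, 150, 6, 150, 107),
            (20, 350, 60, 300, 108),
            (3, 220, 0, 260, 109),
            (6, 180, 25, 240, 110),
        ],
    )
    def test_monte_carlo_oracle_small_configurations(
        self, small_params, early_alt, early_total, late_alt, late_total, seed
    ):
        """Full Monte Carlo of the null chain reproduces the analytic p-value."""
        obs = SiteObservation("mc", early_alt, early_total, late_alt, late_total)
        res = drift_pvalue(obs, small_params)

        rng = np.random.default_rng(seed)
        n = 100_000
        post = early_frequency_posterior(early_alt, early_total, small_params)
        f0 = rng.choice(post.grid, size=n, p=post.probabilities)
        founders = rng.binomial(small_params.bottleneck_size, f0)
        f_late = simulate_growth_many(
            founders, small_params, 0.0, seed=int(rng.integers(2**31 - 1))
        )
        q = observed_read_prob(snap_to_grid(f_late, small_params), small_params)
        k = rng.binomial(late_total, q)
        if obs.direction == "gain":
            p_mc = (k >= late_alt).mean()
        else:
            p_mc = (k <= late_alt).mean()
        se = max(np.sqrt(p_mc * (1 - p_mc) / n), 1.0 / n)
        assert res.p_value == pytest.approx(p_mc, abs=max(3 * se, 5e-4))


class TestSelection:
    def test_null_likelihood_equals_null_chain_pmf(self, default_params):
        from clonaldrift.inference import late_frequency_distribution

        obs = SiteObservation("s", 10, 500, 30, 600)
        dist = late_frequency_distribution(obs, default_params, 0.0)
        q = observed_read_prob(dist.grid, default_params)
        pmf = float(dist.probabilities @ stats.binom.pmf(30, 600, q))
        assert selection_likelihood(obs, 0.0, default_params) == pytest.approx(
            np.log(pmf)
        )

    def test_no_change_prefers_neutrality_over_strong_selection(self, default_params):
        obs = SiteObservation("s", 50, 1000, 50, 1000)
        assert selection_likelihood(obs, 0.0, default_params) >= selection_likelihood(
            obs, 0.9, default_params
        )

    def test_expansion_prefers_selection(self, default_params):
        obs = SiteObservation("s", 0, 725, 156, 282)
        assert selection_likelihood(obs, 0.5, default_params) > selection_likelihood(
            obs, 0.0, default_params
        )

    def test_stable_site_estimates_near_zero(self, default_params):
        est = estimate_selection(
            SiteObservation("s", 100, 2000, 100, 2000), default_params
        )
        assert abs(est.s_hat) <= 0.05
        assert est.ci_low <= est.s_hat <= est.ci_high

    def test_profile_maximum_at_estimate(self, default_params):
        est = estimate_selection(SiteObservation("s", 0, 725, 156, 282), default_params)
        s_vals, ll = zip(*est.profile)
        assert s_vals[int(np.argmax(ll))] == est.s_hat

    def test_out_of_range_s_is_domain_error(self, default_params):
        with pytest.raises(ValueError):
            selection_likelihood(SiteObservation("s", 1, 10, 2, 10), 1.2, default_params)
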