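"""Density propagation and choice likelihoods: closed forms, oracle checks."""

import numpy as np
import pytest
from scipy.stats import norm

from pclicks.likelihood import (
    DensityCache,
    choice_probability,
    log_likelihood,
    propagate_density,
)
from pclicks.params import AccumulatorParams, BiasExtension
from pclicks.simulate import (
    generate_dataset,
    generate_trial,
    mc_choice_probability,
    simulate_choices,
)
from pclicks.trials import Trial


def _random_params(rng):
    return AccumulatorParams(
        lam=rng.uniform(-5, 5),
        sigma_a2=rng.uniform(0, 5),
        sigma_s2=rng.uniform(0, 80),
        sigma_i2=rng.uniform(0, 2),
        B=rng.uniform(6, 25),
        phi=rng.uniform(0.1, 1.5),
        tau_phi=rng.uniform(0.02, 0.5),
        sho=rng.uniform(-1, 1),
        lapse=rng.uniform(0, 0.3),
    )


class TestPropagation:
    def test_mass_conservation(self, meta_params):
        rng = np.random.default_rng(0)
        ts = generate_dataset(10, mixture={"accumulation": 1.0}, seed=1)
        for params in [meta_params, _random_params(rng),
                       meta_params.replace(lam=30.0, sigma_a2=5.0)]:
            for t in ts:
                g = propagate_density(t, params)
                assert g.total == pytest.approx(1.0, abs=1e-6)
                assert np.all(g.mass >= 0)
                assert g.absorbed_neg >= 0 and g.absorbed_pos >= 0

    def test_noise_free_terminal_density_is_click_difference(self, ideal_params):
        """Ideal-performance limit: a = #right - #left clicks exactly."""
        for seed in range(4):
            t = generate_trial(15, 25, 0.6, seed=seed)
            g = propagate_density(t, ideal_params)
            assert g.mean == pytest.approx(t.click_difference, abs=1e-9)
            assert g.absorbed_neg == 0 and g.absorbed_pos == 0

    def test_no_click_trial_matches_gaussian_closed_form(self):
        """Without clicks the terminal interior density is the exact linear-SDE
        Gaussian N(0, sigma_i2 + sigma_a2*T) restricted to (-B, B)."""
        params = AccumulatorParams(lam=0.0, sigma_a2=4.0, sigma_s2=0.0,
                                   sigma_i2=1.0, B=3.0, phi=1.0, tau_phi=0.1)
        t = Trial(trial_id=0, duration=1.0, trial_type="single_sided",
                  correct_side="L")
        g = propagate_density(t, params)
        sd = np.sqrt(params.sigma_i2 + params.sigma_a2 * t.duration)
        expected = np.diff(norm.cdf(g.edges / sd))
        assert np.abs(g.mass - expected).max() < 1e-4

    def test_no_click_absorption_matches_path_oracle(self):
        """Absorbed bound masses agree with a large Monte-Carlo path sample."""
        params = AccumulatorParams(lam=0.0, sigma_a2=4.0, sigma_s2=0.0,
                                   sigma_i2=1.0, B=3.0, phi=1.0, tau_phi=0.1)
        t = Trial(trial_id=0, duration=1.0, trial_type="single_sided",
                  correct_side="L")
        g = propagate_density(t, params)
        rng = np.random.default_rng(9)
        n = 400_000
        a = rng.normal(0, 1.0, n)
        inside = np.abs(a) < 3.0
        a2 = a + rng.normal(0, 2.0, n)
        hit_pos = inside & (a2 >= 3.0) | (~inside & (a >= 3.0))
        p_pos = hit_pos.mean()
        assert g.absorbed_pos == pytest.approx(p_pos, abs=3 * np.sqrt(p_pos / n))

    def test_grid_convergence(self, meta_params):
        """Halving the bin width changes choice probabilities by < 1e-3."""
        ts = generate_dataset(6, mixture={"accumulation": 1.0}, seed=2)
        ts = simulate_choices(ts, meta_params, seed=3)
        for t in ts:
            p1 = choice_probability(t, meta_params, dx=0.05)
            p2 = choice_probability(t, meta_params, dx=0.025)
            assert abs(p1 - p2) < 1e-3

    def test_compiled_and_numpy_backends_agree(self, meta_params):
        ts = generate_dataset(5, mixture={"accumulation": 1.0}, seed=4)
        for t in ts:
            g1 = propagate_density(t, meta_params, use_compiled=True)
            g2 = propagate_density(t, meta_params, use_compiled=False)
            assert np.abs(g1.mass - g2.mass).max() < 1e-12
            assert g1.absorbed_pos == pytest.approx(g2.absorbed_pos, abs=1e-12)
            assert g1.absorbed_neg == pytest.approx(g2.absorbed_neg, abs=1e-12)

    def test_monte_carlo_equivalence_over_random_parameters(self):
        """Density-propagated P(R) matches 20k-path simulation within 3
        binomial s.e. on >= 95% of trials, across 5 random parameter draws."""
        rng = np.random.default_rng(12)
        n_paths = 20_000
        bad = total = 0
        for draw in range(5):
            params = _random_params(rng)
            ts = generate_dataset(30, mixture={"accumulation": 1.0},
                                  seed=100 + draw)
            for t in ts:
                p = choice_probability(t, params)
                pm = mc_choice_probability(t, params, n_paths=n_paths, rng=rng)
                se = max(np.sqrt(pm * (1 - pm) / n_paths), 1e-4)
                total += 1
                if abs(p - pm) > 3 * se:
                    bad += 1
        assert bad / total <= 0.05

    def test_leak_weights_late_clicks_instability_early(self):
        """lambda < 0: a late extra click moves P(R) more than an early one;
        lambda > 0: the reverse."""
        base_left = tuple(np.arange(0.05, 0.8, 0.08))
        base_right = tuple(np.arange(0.09, 0.8, 0.08))
        common = dict(trial_id=0, duration=0.8, trial_type="accumulation",
                      generative_rate_left=12.0, generative_rate_right=13.0,
                      correct_side="R")
        noise = dict(sigma_a2=0.5, sigma_s2=4.0, sigma_i2=1.0, B=40.0,
                     phi=1.0, tau_phi=0.1, sho=0.0, lapse=0.0)
        for lam, late_wins in [(-3.0, True), (3.0, False)]:
            params = AccumulatorParams(lam=lam, **noise)
            t_early = Trial(left_clicks=base_left,
                            right_clicks=tuple(sorted(base_right + (0.02,))),
                            **common)
            t_late = Trial(left_clicks=base_left,
                           right_clicks=tuple(sorted(base_right + (0.78,))),
                           **common)
            t_base = Trial(left_clicks=base_left, right_clicks=base_right,
                           **common)
            p0 = choice_probability(t_base, params)
            d_early = choice_probability(t_early, params) - p0
            d_late = choice_probability(t_late, params) - p0
            assert d_early > 0 and d_late > 0
            assert (d_late > d_early) == late_wins

    def test_left_right_mirror_symmetry(self, meta_params):
        """Mirroring the stimulus and negating the boundary maps P -> 1-P."""
        ts = generate_dataset(5, mixture={"accumulation": 1.0}, seed=6)
        params = meta_params
        mirrored = params.replace(sho=-params.sho)
        for t in ts:
            p = choice_probability(t, params)
            pm = choice_probability(t.mirrored(), mirrored)
            assert p == pytest.approx(1.0 - pm, abs=1e-9)


class TestChoiceProbability:
    def test_lapse_one_is_exactly_half(self, meta_params):
        t = generate_trial(5, 35, 0.5, seed=7)
        assert choice_probability(t, meta_params.replace(lapse=1.0)) == 0.5

    def test_post_categorization_asymptote(self, ideal_params):
        """kappa_R = 0.498 on a noise-free easiest-right trial: P(R) = 0.502."""
        t = generate_trial(1, 39, 0.8, seed=8)
        assert t.click_difference > 0
        p = choice_probability(t, ideal_params, BiasExtension(kappa_R=0.498))
        assert p == pytest.approx(0.502, abs=1e-9)

    def test_boundary_outside_bounds_rejected(self, meta_params):
        t = generate_trial(20, 20, 0.5, seed=9)
        with pytest.raises(ValueError):
            choice_probability(t, meta_params.replace(sho=meta_params.B + 1))


class TestLogLikelihood:
    def test_lapse_one_gives_exact_coin_flip_likelihood(self, meta_params,
                                                        small_trialset):
        n = len(small_trialset)
        ll = log_likelihood(small_trialset, meta_params.replace(lapse=1.0))
        assert ll == pytest.approx(n * np.log(0.5), abs=1e-9)

    def test_appending_a_trial_decreases_likelihood(self, meta_params,
                                                    small_trialset):
        trials = list(small_trialset)
        ll_all = log_likelihood(trials, meta_params)
        ll_fewer = log_likelihood(trials[:-1], meta_params)
        assert ll_all < ll_fewer

    def test_lapse_bounds_every_trial_probability(self, meta_params,
                                                  small_trialset):
        """lapse > 0 puts a floor of lapse/2 under each trial's probability."""
        for t in small_trialset:
            p_r = choice_probability(t, meta_params)
            p = p_r if t.choice == "R" else 1.0 - p_r
            assert p >= meta_params.lapse / 2 - 1e-12

    def test_missing_choice_rejected(self, meta_params):
        t = generate_trial(20, 20, 0.5, seed=10)
        with pytest.raises(ValueError):
            log_likelihood([t], meta_params)


class TestDensityCache:
    def test_cache_matches_direct_evaluation(self, meta_params, small_trialset):
        trials = list(small_trialset)[:30]
        cache = DensityCache(trials, meta_params)
        for sho, shift, lapse, k_l, k_r in [
            (0.065, 0.0, 0.102, 0.0, 0.0),
            (-0.5, 0.3, 0.0, 0.1, 0.4),
            (1.2, -0.7, 0.5, 0.0, 0.0),
        ]:
            p_cache = cache.p_right(sho=sho, shift=shift, lapse=lapse,
                                    kappa_L=k_l, kappa_R=k_r)
            params = meta_params.replace(sho=sho, lapse=lapse)
            bias = BiasExtension(kappa_L=k_l, kappa_R=k_r, shift=shift)
            p_direct = [choice_probability(t, params, bias) for t in trials]
            assert np.allclose(p_cache, p_direct, atol=1e-12)
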