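"""Fitting machinery: MLE recovery, bootstrap, Metropolis, surfaces, CV."""

import numpy as np
import pytest

from pclicks.bias import VariantSpec, full_model_spec, make_variant
from pclicks.inference import (
    FitResult,
    bootstrap_fit,
    fit_mle,
    likelihood_surface,
    loso_cv,
    mh_sample,
    scan_fit,
)
from pclicks.params import AccumulatorParams, BiasExtension
from pclicks.simulate import generate_dataset, generate_trial, simulate_choices


def _kappa_dataset(n, kappa, seed, meta_params):
    ts = generate_dataset(n, mixture={"accumulation": 1.0}, seed=seed)
    bias = BiasExtension.from_ipsi_contra(ipsi_side="L", kappa_contra=kappa)
    return simulate_choices(ts, meta_params, bias, seed=seed + 1)


class TestFitMle:
    def test_recovers_injected_kappa(self, meta_params):
        """kappa_contra estimator is unbiased with SD ~0.023 at this n;
        tolerance is ~3.4 sigma."""
        ts = _kappa_dataset(1200, 0.5, 600, meta_params)
        spec = make_variant("post_cat", meta_params, ipsi_side="L")
        fit = fit_mle(list(ts), spec, dx=0.1)
        assert fit.theta[0] == pytest.approx(0.5, abs=0.08)
        assert fit.converged

    def test_recovers_lambda_in_identifiable_regime(self):
        """Under low sensory noise the drift rate is strongly identified;
        the scan fit lands within 3 sampling-SDs (~1.05 at this n) of truth."""
        truth = AccumulatorParams(lam=-4.0, sigma_a2=0.5, sigma_s2=0.25,
                                  sigma_i2=0.1, B=12.0, phi=1.0, tau_phi=0.1,
                                  sho=0.0, lapse=0.05)
        ts = generate_dataset(800, mixture={"accumulation": 1.0}, seed=910)
        ts = simulate_choices(ts, truth, seed=911)
        spec = VariantSpec(name="lam", free_names=("lam",),
                           control_params=truth, bounds=((-15.0, 10.0),))
        fit = scan_fit(list(ts), spec, n_grid=13, dx=0.1)
        assert fit.theta[0] == pytest.approx(-4.0, abs=3.5)

    def test_coin_flip_data_reaches_likelihood_ceiling(self, meta_params):
        """On lapse-generated (stimulus-independent) choices the fitted full
        model attains LL within 1 unit of n*ln(1/2)."""
        ts = generate_dataset(60, mixture={"accumulation": 1.0}, seed=801)
        ts = simulate_choices(ts, meta_params.replace(lapse=1.0), seed=802)
        fit = fit_mle(list(ts), full_model_spec(meta_params), n_starts=2,
                      seed=1, dx=0.1, maxiter=40)
        assert fit.log_likelihood >= 60 * np.log(0.5) - 1.0
        # the ceiling itself cannot be exceeded
        assert fit.log_likelihood <= 60 * np.log(0.5) + 1e-6

    def test_estimator_error_shrinks_with_sample_size(self, meta_params):
        """Consistency: mean |kappa_hat - kappa| decreases from n=250 to
        n=1500 over 8 replicates."""
        spec = make_variant("post_cat", meta_params, ipsi_side="L")
        errs = {}
        for n in (250, 1500):
            e = []
            for r in range(8):
                ts = _kappa_dataset(n, 0.4, 10_000 + 20 * r + n, meta_params)
                fit = fit_mle(list(ts), spec, dx=0.1)
                e.append(abs(fit.theta[0] - 0.4))
            errs[n] = np.mean(e)
        assert errs[1500] < errs[250]

    def test_no_free_parameters_rejected(self, meta_params, small_trialset):
        spec = full_model_spec(meta_params, free=())
        with pytest.raises(ValueError):
            fit_mle(list(small_trialset), spec)

    def test_fit_result_validates_bounds_and_ll(self, meta_params):
        spec = make_variant("post_cat", meta_params)
        with pytest.raises(ValueError):
            FitResult(spec=spec, theta=[1.5], log_likelihood=-1.0, n_trials=5)
        with pytest.raises(ValueError):
            FitResult(spec=spec, theta=[0.5], log_likelihood=np.nan, n_trials=5)


class TestBootstrap:
    def test_identical_trials_give_zero_width_ci(self, meta_params):
        t = generate_trial(5, 35, 0.5, seed=40).with_choice("R")
        spec = make_variant("post_cat", meta_params)
        res = bootstrap_fit([t] * 40, spec, n_boot=50, seed=41, dx=0.1)
        ci = res.ci
        assert ci[0, 1] - ci[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_minimum_resamples_enforced(self, meta_params, small_trialset):
        spec = make_variant("post_cat", meta_params)
        with pytest.raises(ValueError):
            bootstrap_fit(list(small_trialset), spec, n_boot=1)

    def test_percentile_ci_coverage(self, meta_params):
        """Over 50 simulated replicates (100 resamples each) the 95% interval
        for the injected post-categorization parameter contains the truth in
        90-100% of replicates."""
        spec = make_variant("post_cat", meta_params, ipsi_side="L")
        cover = 0
        for r in range(50):
            ts = _kappa_dataset(150, 0.4, 5000 + r * 17, meta_params)
            br = bootstrap_fit(list(ts), spec, n_boot=100, seed=7000 + r,
                               dx=0.1)
            lo, hi = br.ci[0]
            cover += lo <= 0.4 <= hi
        assert 45 <= cover <= 50

    def test_significance_rule_flags_shifted_parameter(self, meta_params):
        ts = _kappa_dataset(400, 0.5, 60, meta_params)
        spec = make_variant("post_cat", meta_params, ipsi_side="L")
        br = bootstrap_fit(list(ts), spec, n_boot=60, seed=61, dx=0.1)
        assert br.significant_vs([0.0])[0]  # control kappa=0 outside the CI


class TestMetropolis:
    MEAN = np.array([1.0, -2.0])
    COV = np.array([[1.0, 0.6], [0.6, 2.0]])

    def _logp(self):
        icov = np.linalg.inv(self.COV)

        def logp(x):
            d = x - self.MEAN
            return -0.5 * d @ icov @ d

        return logp

    def test_recovers_gaussian_mean_and_covariance(self):
        chains = mh_sample(self._logp(), [0.0, 0.0], [1.2, 1.7], n_chains=4,
                           n_samples=3000, burnin=100, thin=4, seed=7)
        pooled = chains.pooled()
        import arviz as az

        ess = az.ess(az.convert_to_dataset(chains.chains)).x.values
        se = np.sqrt(np.diag(self.COV) / ess)
        assert np.all(np.abs(pooled.mean(0) - self.MEAN) < 3 * se)
        assert np.abs(np.cov(pooled.T) - self.COV).max() < 0.3
        assert np.all(chains.rhat() < 1.1)
        assert np.all((chains.acceptance_rates > 0.05)
                      & (chains.acceptance_rates < 0.8))

    def test_default_schedule_retains_2475_per_chain(self):
        chains = mh_sample(self._logp(), [0.0, 0.0], [1.2, 1.7], n_chains=1,
                           n_samples=10_000, burnin=100, thin=4, seed=8)
        assert chains.chains.shape == (1, 2475, 2)

    def test_zero_proposal_width_rejected(self):
        with pytest.raises(ValueError):
            mh_sample(self._logp(), [0.0, 0.0], [0.0, 1.0], n_samples=10)

    def test_poor_acceptance_rate_warns(self):
        with pytest.warns(UserWarning, match="acceptance rate"):
            mh_sample(self._logp(), [0.0, 0.0], [200.0, 200.0], n_chains=1,
                      n_samples=300, burnin=10, thin=1, seed=9)

    def test_marginal_significance_check(self):
        chains = mh_sample(self._logp(), [0.0, 0.0], [1.2, 1.7], n_chains=2,
                           n_samples=2000, burnin=100, thin=4, seed=10)
        sig = chains.significant_vs([1.0, 3.0])
        assert not sig[0] and sig[1]


class TestLikelihoodSurface:
    def test_normalized_maximum_is_one(self, meta_params, small_trialset):
        surf = likelihood_surface(
            list(small_trialset), "shift", "lapse",
            np.linspace(-1, 1, 9), np.linspace(0.0, 0.5, 9), meta_params,
        )
        assert surf.values.max() == pytest.approx(1.0)
        assert surf.values.shape == (9, 9)

    def test_argmax_agrees_with_mle_within_one_cell(self, meta_params):
        ts = generate_dataset(400, mixture={"accumulation": 1.0}, seed=71)
        ts = simulate_choices(ts, meta_params, BiasExtension(shift=0.8),
                              seed=72)
        gx = np.linspace(-2.0, 2.0, 21)
        gy = np.linspace(0.0, 0.6, 16)
        surf = likelihood_surface(list(ts), "shift", "lapse", gx, gy,
                                  meta_params)
        ax, ay = surf.argmax()
        spec = VariantSpec(name="shift+lapse", free_names=("shift", "lapse"),
                           control_params=meta_params,
                           bounds=((-2.0, 2.0), (0.0, 0.6)))
        fit = fit_mle(list(ts), spec, n_starts=2, seed=3)
        assert abs(ax - fit.values["shift"]) <= gx[1] - gx[0] + 1e-9
        assert abs(ay - fit.values["lapse"]) <= gy[1] - gy[0] + 1e-9

    def test_surface_invariant_to_trial_order(self, meta_params,
                                              small_trialset):
        trials = list(small_trialset)
        gx = np.linspace(-1, 1, 7)
        gy = np.linspace(0.0, 0.4, 7)
        s1 = likelihood_surface(trials, "shift", "lapse", gx, gy, meta_params)
        s2 = likelihood_surface(trials[::-1], "shift", "lapse", gx, gy,
                                meta_params)
        assert np.allclose(s1.log_likelihood, s2.log_likelihood, atol=1e-9)

    def test_kappa_gain_surface_peaks_at_injected_kappa(self, meta_params):
        """On kappa-generated data the 2-D (gain, kappa) surface peaks at a
        clearly nonzero kappa with gain near control."""
        ts = _kappa_dataset(400, 0.5, 80, meta_params)
        gx = np.linspace(0.5, 2.0, 7)     # gain_contra (density parameter)
        gy = np.linspace(0.0, 0.8, 17)    # kappa_contra (cached parameter)
        surf = likelihood_surface(
            list(ts), "gain_contra", "kappa_contra", gx, gy, meta_params,
            control_bias=BiasExtension(ipsi_side="L"), dx=0.1,
        )
        a_gain, a_kappa = surf.argmax()
        assert a_kappa > 0.3
        assert abs(a_gain - 1.0) <= 2 * (gx[1] - gx[0])


class TestLosoCv:
    def test_single_session_rejected(self, meta_params, small_trialset):
        with pytest.raises(ValueError):
            loso_cv([small_trialset], control_params=meta_params)

    def test_returns_sessions_by_variants_matrix(self, meta_params):
        from pclicks.bias import relabel_ipsi_contra
        from pclicks.simulate import generate_unilateral_sessions

        sessions = generate_unilateral_sessions(4, 50, meta_params,
                                                kappa_contra=0.5, seed=90)
        rel = [relabel_ipsi_contra(s) for s in sessions]
        cv = loso_cv(rel, control_params=meta_params, dx=0.1, grid_size=9)
        assert cv.shape == (4, 4)
        assert list(cv.columns) == ["post_cat", "gain", "shift", "noise"]
        assert np.isfinite(cv.to_numpy(dtype=float)).all()
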