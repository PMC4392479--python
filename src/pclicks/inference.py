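"""Model fitting and uncertainty quantification.

Maximum-likelihood fits use bounded derivative-free / numeric-gradient
optimization (no analytic likelihood gradient is attempted): single-parameter
variants are bracketed by a dense 1-D scan and polished with bounded scalar
minimization; multi-parameter models use L-BFGS-B with finite-difference
gradients and jittered multistarts.  Bootstrap confidence intervals refit on
trials resampled with replacement (default 300 resamples, 95% percentile
intervals; a parameter is called significant when the control value falls
outside its interval).  Posterior exploration uses symmetric uniform
random-walk Metropolis (default 4 chains of 10,000 samples, burn-in 100,
thinning 4).

Fits over parameters that act after density propagation (``kappa``'s,
``shift``, ``sho``, ``lapse``) reuse cached per-trial terminal densities,
which makes those fits, their bootstraps, and cross-validation cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .bias import VariantSpec, make_variant
from .likelihood import POST_DENSITY_PARAMS, DensityCache, log_likelihood
from .params import AccumulatorParams, BiasExtension
from .trials import Trial, TrialSet

__all__ = [
    "FitResult",
    "BootstrapResult",
    "ChainSet",
    "fit_mle",
    "scan_fit",
    "trial_logp_grid",
    "bootstrap_fit",
    "mh_sample",
    "mh_sample_model",
    "default_proposal_widths",
    "likelihood_surface",
    "LikelihoodSurface",
    "loso_cv",
]


# ----------------------------------------------------------------------------
# results containers
# ----------------------------------------------------------------------------

@dataclass
class FitResult:
    """Point estimate for a :class:`~pclicks.bias.VariantSpec`."""

    spec: VariantSpec
    theta: np.ndarray
    log_likelihood: float
    n_trials: int
    n_evals: int = 0
    converged: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.isfinite(self.log_likelihood):
            raise ValueError("fit log-likelihood is not finite")
        for v, (lo, hi) in zip(self.theta, self.spec.bounds):
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(f"fitted value {v} outside bounds ({lo}, {hi})")

    @property
    def values(self) -> Dict[str, float]:
        return dict(zip(self.spec.free_names, map(float, self.theta)))

    def build(self) -> Tuple[AccumulatorParams, BiasExtension]:
        return self.spec.build(self.theta)


@dataclass
class BootstrapResult:
    """Refit parameters over resampled trial sets plus percentile CIs."""

    spec: VariantSpec
    samples: np.ndarray          # (n_boot, k)
    log_likelihoods: np.ndarray  # (n_boot,)
    ci_level: float = 0.95

    @property
    def n_boot(self) -> int:
        return self.samples.shape[0]

    @property
    def param_names(self) -> Tuple[str, ...]:
        return self.spec.free_names

    @property
    def ci(self) -> np.ndarray:
        """(k, 2) percentile confidence bounds."""
        alpha = 100.0 * (1.0 - self.ci_level) / 2.0
        lo = np.percentile(self.samples, alpha, axis=0)
        hi = np.percentile(self.samples, 100.0 - alpha, axis=0)
        return np.column_stack([lo, hi])

    def significant_vs(self, control_values: Sequence[float]) -> np.ndarray:
        """Control value outside the CI => parameter shifted significantly."""
        control = np.asarray(control_values, dtype=float)
        ci = self.ci
        return (control < ci[:, 0]) | (control > ci[:, 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.param_names))
        df["log_likelihood"] = self.log_likelihoods
        return df


@dataclass
class ChainSet:
    """Random-walk Metropolis output after burn-in and thinning."""

    chains: np.ndarray            # (n_chains, n_kept, k)
    acceptance_rates: np.ndarray  # (n_chains,)
    proposal_widths: np.ndarray   # (k,)
    param_names: Tuple[str, ...] = ()
    seed: Optional[int] = None

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    def pooled(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    def marginal_ci(self, level: float = 0.95) -> np.ndarray:
        alpha = 100.0 * (1.0 - level) / 2.0
        pooled = self.pooled()
        return np.column_stack(
            [np.percentile(pooled, alpha, axis=0),
             np.percentile(pooled, 100.0 - alpha, axis=0)]
        )

    def significant_vs(self, control_values: Sequence[float],
                       level: float = 0.95) -> np.ndarray:
        """Non-parametric check: control outside the marginal interval."""
        control = np.asarray(control_values, dtype=float)
        ci = self.marginal_ci(level)
        return (control < ci[:, 0]) | (control > ci[:, 1])

    def rhat(self) -> np.ndarray:
        """Gelman-Rubin potential-scale-reduction per parameter."""
        m, n, k = self.chains.shape
        means = self.chains.mean(axis=1)            # (m, k)
        variances = self.chains.var(axis=1, ddof=1)  # (m, k)
        w = variances.mean(axis=0)
        b = n * means.var(axis=0, ddof=1)
        var_hat = (n - 1) / n * w + b / n
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.sqrt(var_hat / w)


# ----------------------------------------------------------------------------
# objectives
# ----------------------------------------------------------------------------

def _is_post_density(spec: VariantSpec) -> bool:
    return set(spec.free_names) <= POST_DENSITY_PARAMS


def _make_objective(
    trials: Sequence[Trial], spec: VariantSpec, dx: Optional[float]
) -> Callable[[np.ndarray], float]:
    """Negative log-likelihood of the free-parameter vector."""
    if _is_post_density(spec):
        cache = DensityCache(trials, spec.control_params, spec.control_bias, dx=dx)

        def neg_ll(theta: np.ndarray) -> float:
            params, bias = spec.build(theta)
            return -cache.log_likelihood(
                sho=params.sho, shift=bias.shift, lapse=params.lapse,
                kappa_L=bias.kappa_L, kappa_R=bias.kappa_R,
            )

        return neg_ll

    ev = [t for t in trials if t.has_clicks]

    def neg_ll(theta: np.ndarray) -> float:
        params, bias = spec.build(theta)
        try:
            return -log_likelihood(ev, params, bias, dx=dx)
        except (ValueError, FloatingPointError):
            return np.inf

    return neg_ll


def trial_logp_grid(
    trials: Sequence[Trial],
    spec: VariantSpec,
    grid: np.ndarray,
    dx: Optional[float] = None,
) -> np.ndarray:
    """Per-trial log-probability of the observed choice on a 1-D parameter grid.

    Returns an (n_evidence_trials, len(grid)) matrix; the workhorse behind
    scan fits, fast bootstrap and cross-validation for 1-parameter variants.
    """
    if spec.k != 1:
        raise ValueError("trial_logp_grid requires a single-parameter spec")
    ev = [t for t in trials if t.has_clicks]
    if any(t.choice == "none" for t in ev):
        raise ValueError("all evidence trials must have recorded choices")
    is_right = np.array([t.choice == "R" for t in ev])
    grid = np.asarray(grid, dtype=float)
    out = np.empty((len(ev), grid.size))
    if _is_post_density(spec):
        cache = DensityCache(ev, spec.control_params, spec.control_bias, dx=dx)
        for j, g in enumerate(grid):
            params, bias = spec.build([g])
            p_r = cache.p_right(sho=params.sho, shift=bias.shift, lapse=params.lapse,
                                kappa_L=bias.kappa_L, kappa_R=bias.kappa_R)
            p = np.where(is_right, p_r, 1.0 - p_r)
            out[:, j] = np.log(np.maximum(p, 1e-300))
    else:
        from .likelihood import choice_probability

        for j, g in enumerate(grid):
            params, bias = spec.build([g])
            for i, t in enumerate(ev):
                p_r = choice_probability(t, params, bias, dx=dx)
                p = p_r if is_right[i] else 1.0 - p_r
                out[i, j] = np.log(max(p, 1e-300))
    return out


def _parabolic_refine(grid: np.ndarray, ll: np.ndarray) -> Tuple[float, float]:
    """Continuous argmax estimate from a grid scan (vertex of the fitted
    parabola through the best point and its neighbours)."""
    i = int(np.argmax(ll))
    if i == 0 or i == len(grid) - 1:
        return float(grid[i]), float(ll[i])
    h = grid[i + 1] - grid[i]
    denom = ll[i - 1] - 2.0 * ll[i] + ll[i + 1]
    if denom >= 0:  # flat or degenerate: keep the grid point
        return float(grid[i]), float(ll[i])
    delta = 0.5 * (ll[i - 1] - ll[i + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    ll_hat = ll[i] - 0.25 * (ll[i - 1] - ll[i + 1]) * delta
    return float(grid[i] + delta * h), float(ll_hat)


def scan_fit(
    trials: Sequence[Trial],
    spec: VariantSpec,
    n_grid: int = 25,
    dx: Optional[float] = None,
    refine: bool = True,
) -> FitResult:
    """Grid-scan fit of a single-parameter spec with parabolic refinement."""
    (lo, hi), = spec.bounds
    grid = np.linspace(lo, hi, n_grid)
    logp = trial_logp_grid(trials, spec, grid, dx=dx)
    ll = logp.sum(axis=0)
    if refine:
        theta, ll_hat = _parabolic_refine(grid, ll)
    else:
        i = int(np.argmax(ll))
        theta, ll_hat = float(grid[i]), float(ll[i])
    n_ev = sum(1 for t in trials if t.has_clicks)
    return FitResult(spec=spec, theta=np.array([np.clip(theta, lo, hi)]),
                     log_likelihood=ll_hat, n_trials=n_ev, n_evals=n_grid)


# ----------------------------------------------------------------------------
# maximum likelihood
# ----------------------------------------------------------------------------

def fit_mle(
    trials: Sequence[Trial],
    spec: VariantSpec,
    init: Optional[Sequence[float]] = None,
    n_starts: int = 5,
    seed: Optional[int] = None,
    dx: Optional[float] = None,
    n_scan: int = 25,
    maxiter: int = 200,
    ftol: float = 1e-6,
) -> FitResult:
    """Maximize the trial-product likelihood over a variant's free parameters.

    Single-parameter variants are fit by a dense scan over the bounds (their
    likelihoods have a single global maximum) followed by bounded scalar
    polish.  Multi-parameter specs run L-BFGS-B with numeric gradients from
    ``n_starts`` starting points jittered around the control values; the best
    is returned and flagged if no start converged.
    """
    trials = list(trials)
    ev_count = sum(1 for t in trials if t.has_clicks)
    if ev_count == 0:
        raise ValueError("no evidence trials to fit")
    if spec.k < 1:
        raise ValueError("spec has no free parameters")
    neg_ll = _make_objective(trials, spec, dx)
    bounds = list(spec.bounds)

    if spec.k == 1:
        (lo, hi) = bounds[0]
        grid = np.linspace(lo, hi, n_scan)
        vals = np.array([neg_ll(np.array([g])) for g in grid])
        i = int(np.argmin(vals))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, n_scan - 1)]
        res = minimize_scalar(
            lambda x: neg_ll(np.array([x])), bounds=(blo, bhi), method="bounded",
            options={"xatol": max(1e-6, 1e-5 * (hi - lo))},
        )
        theta = np.array([float(np.clip(res.x, lo, hi))])
        ll = -float(res.fun)
        # the scan may have beaten the polish on a flat objective
        if -vals[i] > ll:
            theta, ll = np.array([grid[i]]), -float(vals[i])
        return FitResult(spec=spec, theta=theta, log_likelihood=ll,
                         n_trials=ev_count, n_evals=n_scan + res.nfev,
                         converged=bool(res.success), seed=seed)

    rng = np.random.default_rng(seed)
    x0 = np.asarray(spec.control_values() if init is None else init, dtype=float)
    span = np.array([hi - lo for lo, hi in bounds])
    lo_v = np.array([lo for lo, _ in bounds])
    hi_v = np.array([hi for _, hi in bounds])
    x0 = np.clip(x0, lo_v, hi_v)

    best = None
    n_evals = 0
    any_converged = False
    for s in range(max(1, n_starts)):
        start = x0 if s == 0 else np.clip(
            x0 + rng.normal(0.0, 0.1, x0.size) * span, lo_v, hi_v
        )
        res = minimize(
            neg_ll, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol},
        )
        n_evals += res.nfev
        any_converged |= bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn("no optimizer start converged; returning best point found")
    theta = np.clip(best.x, lo_v, hi_v)
    return FitResult(spec=spec, theta=theta, log_likelihood=-float(best.fun),
                     n_trials=ev_count, n_evals=n_evals,
                     converged=any_converged, seed=seed)


# ----------------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------------

def bootstrap_fit(
    trials: Sequence[Trial],
    spec: VariantSpec,
    n_boot: int = 300,
    seed: Optional[int] = None,
    dx: Optional[float] = None,
    grid_size: int = 41,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Refit on trial sets resampled with replacement (original n each time).

    Single-parameter specs evaluate every trial's log-probability once on a
    dense parameter grid, after which each resample is a weighted grid argmax
    with parabolic refinement; multi-parameter specs run full refits.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    trials = [t for t in trials if t.has_clicks]
    n = len(trials)
    if n == 0:
        raise ValueError("no evidence trials to bootstrap")
    rng = np.random.default_rng(seed)
    samples = np.empty((n_boot, spec.k))
    lls = np.empty(n_boot)

    if spec.k == 1:
        (lo, hi), = spec.bounds
        grid = np.linspace(lo, hi, grid_size)
        logp = trial_logp_grid(trials, spec, grid, dx=dx)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            counts = np.bincount(idx, minlength=n).astype(float)
            ll_g = counts @ logp
            theta, ll_hat = _parabolic_refine(grid, ll_g)
            samples[b, 0] = np.clip(theta, lo, hi)
            lls[b] = ll_hat
    else:
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            resampled = [trials[i] for i in idx]
            fit = fit_mle(resampled, spec, n_starts=1,
                          seed=int(rng.integers(2**31)), dx=dx)
            samples[b] = fit.theta
            lls[b] = fit.log_likelihood
    return BootstrapResult(spec=spec, samples=samples, log_likelihoods=lls,
                           ci_level=ci_level)


# ----------------------------------------------------------------------------
# Metropolis-Hastings
# ----------------------------------------------------------------------------

def default_proposal_widths(spec: VariantSpec, fraction: float = 0.05) -> np.ndarray:
    """Per-parameter half-widths: a fraction of each bound range."""
    return np.array([fraction * (hi - lo) for lo, hi in spec.bounds])


def mh_sample(
    log_density: Callable[[np.ndarray], float],
    x0: Sequence[float],
    proposal_widths: Sequence[float],
    n_chains: int = 4,
    n_samples: int = 10_000,
    burnin: int = 100,
    thin: int = 4,
    seed: Optional[int] = None,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    param_names: Tuple[str, ...] = (),
) -> ChainSet:
    """Symmetric uniform random-walk Metropolis.

    Proposals add an independent U(-w_j, +w_j) step per coordinate; moves
    outside ``bounds`` are rejected.  Samples at iterations >= ``burnin``
    are kept, thinned by ``thin`` (defaults keep 2,475 per chain).
    """
    widths = np.asarray(proposal_widths, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("proposal widths must be positive")
    x0 = np.asarray(x0, dtype=float)
    k = x0.size
    if widths.shape != (k,):
        raise ValueError("one proposal width per parameter required")
    lo = hi = None
    if bounds is not None:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
    ss = np.random.SeedSequence(seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(n_chains)]

    kept_idx = np.arange(burnin, n_samples, thin)
    chains = np.empty((n_chains, kept_idx.size, k))
    acc_rates = np.empty(n_chains)
    for c, rng in enumerate(chain_rngs):
        x = x0.copy()
        lp = float(log_density(x))
        n_acc = 0
        kept = []
        for it in range(n_samples):
            prop = x + rng.uniform(-widths, widths)
            if lo is not None and (np.any(prop < lo) or np.any(prop > hi)):
                lp_prop = -np.inf
            else:
                lp_prop = float(log_density(prop))
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                n_acc += 1
            if it >= burnin and (it - burnin) % thin == 0:
                kept.append(x.copy())
        chains[c] = np.asarray(kept)
        acc_rates[c] = n_acc / n_samples
        if not 0.05 <= acc_rates[c] <= 0.8:
            warnings.warn(
                f"chain {c} acceptance rate {acc_rates[c]:.3f} outside [0.05, 0.8]; "
                "consider retuning proposal widths"
            )
    return ChainSet(chains=chains, acceptance_rates=acc_rates,
                    proposal_widths=widths, param_names=tuple(param_names),
                    seed=seed)


def mh_sample_model(
    trials: Sequence[Trial],
    spec: VariantSpec,
    proposal_widths: Optional[Sequence[float]] = None,
    n_chains: int = 4,
    n_samples: int = 10_000,
    burnin: int = 100,
    thin: int = 4,
    seed: Optional[int] = None,
    dx: Optional[float] = None,
) -> ChainSet:
    """Metropolis sampling of a variant's likelihood (flat prior in bounds).

    Chains start from the control parameter values, mirroring the protocol
    used for the 8-parameter unilateral model.
    """
    neg_ll = _make_objective(list(trials), spec, dx)
    if proposal_widths is None:
        proposal_widths = default_proposal_widths(spec)
    x0 = np.clip(
        spec.control_values(),
        [b[0] for b in spec.bounds],
        [b[1] for b in spec.bounds],
    )
    return mh_sample(
        lambda th: -neg_ll(th), x0, proposal_widths,
        n_chains=n_chains, n_samples=n_samples, burnin=burnin, thin=thin,
        seed=seed, bounds=spec.bounds, param_names=spec.free_names,
    )


# ----------------------------------------------------------------------------
# likelihood surfaces
# ----------------------------------------------------------------------------

@dataclass
class LikelihoodSurface:
    """Likelihood over a 2-D parameter grid, normalized to max 1."""

    param_x: str
    param_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    log_likelihood: np.ndarray  # (len(grid_x), len(grid_y))

    @property
    def values(self) -> np.ndarray:
        return np.exp(self.log_likelihood - self.log_likelihood.max())

    def argmax(self) -> Tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.log_likelihood),
                                self.log_likelihood.shape)
        return float(self.grid_x[i]), float(self.grid_y[j])


def likelihood_surface(
    trials: Sequence[Trial],
    param_x: str,
    param_y: str,
    grid_x: Sequence[float],
    grid_y: Sequence[float],
    control_params: AccumulatorParams,
    control_bias: Optional[BiasExtension] = None,
    dx: Optional[float] = None,
) -> LikelihoodSurface:
    """LL on a 2-D grid with all other parameters fixed at control.

    When one of the two parameters acts after density propagation the inner
    loop reuses cached densities, so e.g. (lambda, lapse) and
    (gain_contra, kappa_contra) surfaces cost one propagation sweep per
    density-relevant grid value.
    """
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    if not (np.all(np.isfinite(grid_x)) and np.all(np.isfinite(grid_y))):
        raise ValueError("grids must be finite")
    control_bias = control_bias or BiasExtension()
    spec2 = VariantSpec(
        name=f"{param_x}+{param_y}", free_names=(param_x, param_y),
        control_params=control_params, control_bias=control_bias,
    )
    ev = [t for t in trials if t.has_clicks]
    is_right = np.array([t.choice == "R" for t in ev])
    ll = np.empty((grid_x.size, grid_y.size))

    x_post = param_x in POST_DENSITY_PARAMS
    y_post = param_y in POST_DENSITY_PARAMS
    if x_post and not y_post:
        # transpose so the cached parameter is always the inner loop
        inner = likelihood_surface(
            trials, param_y, param_x, grid_y, grid_x, control_params,
            control_bias, dx=dx,
        )
        return LikelihoodSurface(param_x, param_y, grid_x, grid_y,
                                 inner.log_likelihood.T)
    if y_post:
        shared_cache = (
            DensityCache(ev, control_params, control_bias, dx=dx) if x_post else None
        )
        for i, gx in enumerate(grid_x):
            if shared_cache is None:
                params_i, bias_i = spec2.build([gx, spec2.control_values()[1]])
                cache = DensityCache(ev, params_i, bias_i, dx=dx)
            else:
                cache = shared_cache
            for j, gy in enumerate(grid_y):
                params, bias = spec2.build([gx, gy])
                ll[i, j] = cache.log_likelihood(
                    sho=params.sho, shift=bias.shift, lapse=params.lapse,
                    kappa_L=bias.kappa_L, kappa_R=bias.kappa_R,
                )
    else:
        for i, gx in enumerate(grid_x):
            for j, gy in enumerate(grid_y):
                params, bias = spec2.build([gx, gy])
                ll[i, j] = log_likelihood(ev, params, bias, dx=dx)
    return LikelihoodSurface(param_x, param_y, grid_x, grid_y, ll)


# ----------------------------------------------------------------------------
# leave-one-session-out cross-validation
# ----------------------------------------------------------------------------

def loso_cv(
    sessions: Sequence[TrialSet],
    variants: Sequence[str] = ("post_cat", "gain", "shift", "noise"),
    control_params: Optional[AccumulatorParams] = None,
    ipsi_side: str = "L",
    dx: Optional[float] = None,
    grid_size: int = 33,
    first_n: Optional[int] = 250,
) -> pd.DataFrame:
    """Held-out log-likelihood per trial, sessions x variants.

    For each session, each variant is fit (dense-scan over its free
    parameter) on all other sessions and evaluated on the held-out session.
    Per-trial log-probabilities on the parameter grid are shared across
    folds, so the whole matrix costs one grid sweep per variant.
    ``first_n`` truncates each session to its first trials before fitting.
    """
    if len(sessions) < 2:
        raise ValueError("leave-one-session-out needs at least 2 sessions")
    if control_params is None:
        raise ValueError("control_params (the control 9-parameter fit) is required")
    all_trials: List[Trial] = []
    labels: List[int] = []
    for s_idx, sess in enumerate(sessions):
        ts = sess.first_n_per_session(first_n) if first_n else sess
        for t in ts.evidence_trials():
            all_trials.append(t)
            labels.append(s_idx)
    labels_arr = np.asarray(labels)
    session_names = [
        sess.trials[0].session_id if len(sess) else f"session{i}"
        for i, sess in enumerate(sessions)
    ]
    out = pd.DataFrame(index=session_names, columns=list(variants), dtype=float)
    for variant in variants:
        spec = make_variant(variant, control_params, ipsi_side=ipsi_side)
        (lo, hi), = spec.bounds
        grid = np.linspace(lo, hi, grid_size)
        logp = trial_logp_grid(all_trials, spec, grid, dx=dx)
        for s_idx, name in enumerate(session_names):
            train = labels_arr != s_idx
            test = ~train
            if not test.any():
                out.loc[name, variant] = np.nan
                continue
            g_best = int(np.argmax(logp[train].sum(axis=0)))
            out.loc[name, variant] = float(logp[test, g_best].mean())
    return out
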