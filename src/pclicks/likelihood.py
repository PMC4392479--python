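"""Exact trial-level choice likelihoods by density propagation.

The distribution of the accumulator ``a`` is represented on a uniform grid
over ``(-B, B)`` plus two absorbed point masses at the sticky bounds.  The
propagation is event driven: the only discretization is of the ``a`` axis.
Between consecutive clicks the linear SDE ``da = lambda*a dt + sigma_a dW``
has an exact Gaussian transition kernel (conditional mean ``a*exp(lambda*dt)``,
variance ``sigma_a2*(exp(2*lambda*dt)-1)/(2*lambda)``, with the ``lambda -> 0``
limit ``sigma_a2*dt``), which is applied as a deterministic rescaling of the
grid followed by a constant-variance Gaussian convolution.  Each click applies
a Gaussian kick with mean ``+/- gain*C_k`` and variance
``gain^2*C_k^2*sigma_s2`` (the per-click multiplicative noise
``eta ~ N(1, sigma_s2)`` scales with the adapted amplitude).  After every
step, mass outside ``(-B, B)`` is transferred to the absorbed bins and never
returns.

The probability of a rightward choice is the mass strictly above the decision
boundary (the boundary bin contributing fractionally by linear
interpolation), mixed with the lapse, then passed through the
post-categorization reversal probabilities ``kappa_L``/``kappa_R``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
from scipy.signal import convolve as _sig_convolve
from scipy.special import ndtr

from . import _kernels
from .adaptation import adapt_click_amplitudes
from .params import AccumulatorParams, BiasExtension
from .trials import Trial

__all__ = [
    "DensityGrid",
    "propagate_density",
    "choice_probability",
    "log_likelihood",
    "DensityCache",
    "default_bin_width",
]

_NSIG = 5.5  # Gaussian kernels truncated at +/- _NSIG sigma; tails -> absorbed
_NO_BIAS = BiasExtension()


def default_bin_width(B: float) -> float:
    """Default grid resolution: ``min(B/200, 0.05)`` accumulator units."""
    return min(B / 200.0, 0.05)


@dataclass
class DensityGrid:
    """Discretized accumulator density with absorbed bound masses.

    ``mass[i]`` is the probability in the bin with edges
    ``[-B + i*dx, -B + (i+1)*dx)``; ``absorbed_neg``/``absorbed_pos`` hold the
    mass stuck at the bounds ``-B``/``+B``.
    """

    edges: np.ndarray
    mass: np.ndarray
    absorbed_neg: float
    absorbed_pos: float
    B: float

    @property
    def dx(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.mass.sum() + self.absorbed_neg + self.absorbed_pos)

    @property
    def mean(self) -> float:
        """First moment, counting absorbed mass at the bounds."""
        return float(
            (self.mass * self.centers).sum()
            + self.B * (self.absorbed_pos - self.absorbed_neg)
        )

    def prob_above(self, threshold: float) -> float:
        """Mass with ``a`` strictly above ``threshold`` (frozen mass included
        according to the bound it sits at)."""
        p = 0.0
        if self.B > threshold:
            p += self.absorbed_pos
        if -self.B > threshold:
            p += self.absorbed_neg
        if threshold < -self.B:
            p += float(self.mass.sum())
        elif threshold < self.B:
            dx = self.dx
            idx = int(np.floor((threshold + self.B) / dx))
            idx = min(max(idx, 0), len(self.mass) - 1)
            frac = (self.edges[idx + 1] - threshold) / dx
            frac = min(max(frac, 0.0), 1.0)
            p += float(self.mass[idx]) * frac + float(self.mass[idx + 1 :].sum())
        return min(max(p, 0.0), 1.0)


# ----------------------------------------------------------------------------
# grid primitives
# ----------------------------------------------------------------------------

def _make_edges(B: float, dx: Optional[float]) -> np.ndarray:
    if dx is None:
        dx = default_bin_width(B)
    if dx <= 0:
        raise ValueError("grid bin width must be > 0")
    m = max(2, int(np.ceil(B / dx)))
    return np.linspace(-B, B, 2 * m + 1)


def _initial_mass(edges: np.ndarray, sigma_i2: float) -> Tuple[np.ndarray, float, float]:
    n = len(edges) - 1
    if sigma_i2 <= 0:
        m = np.zeros(n)
        # point mass at a = 0, which sits on the central edge: split evenly
        m[n // 2 - 1] = 0.5
        m[n // 2] = 0.5
        return m, 0.0, 0.0
    si = np.sqrt(sigma_i2)
    cdf = ndtr(edges / si)
    return np.diff(cdf), float(cdf[0]), float(1.0 - cdf[-1])


def _remap(
    mass: np.ndarray, edges: np.ndarray, gamma: float, shift: float
) -> Tuple[np.ndarray, float, float]:
    """Deterministic affine map ``a -> gamma*a + shift`` of a piecewise-constant
    density, conservatively rebinned; returns (new_mass, absorbed_lo, absorbed_hi)."""
    cum = np.empty(edges.size)
    cum[0] = 0.0
    np.cumsum(mass, out=cum[1:])
    total = cum[-1]
    src = (edges - shift) / gamma
    cs = np.interp(src, edges, cum)  # clamps outside the source support
    new_mass = cs[1:] - cs[:-1]
    return np.maximum(new_mass, 0.0), float(cs[0]), float(total - cs[-1])


def _convolve_absorb(
    mass: np.ndarray, edges: np.ndarray, mu: float, sigma: float
) -> Tuple[np.ndarray, float, float]:
    """Convolve interior mass with a Gaussian N(mu, sigma^2) kick; mass pushed
    past the bounds (and the truncated kernel tails) is absorbed."""
    n = len(mass)
    dx = edges[1] - edges[0]
    total = float(mass.sum())
    if total <= 0:
        return mass.copy(), 0.0, 0.0
    l_lo = int(np.floor((mu - _NSIG * sigma) / dx))
    l_hi = int(np.ceil((mu + _NSIG * sigma) / dx))
    kedges = (np.arange(l_lo, l_hi + 2) - 0.5) * dx
    cdf = ndtr((kedges - mu) / sigma)
    w = cdf[1:] - cdf[:-1]
    tail_lo, tail_hi = float(cdf[0]), float(1.0 - cdf[-1])
    if n * w.size > 1_500_000:
        c = _sig_convolve(mass, w, mode="full", method="fft")
    else:
        c = np.convolve(mass, w)
    np.maximum(c, 0.0, out=c)
    # c[t] lands in bin i = t + l_lo
    t_lo = max(0, -l_lo)
    t_hi = min(len(c), n - l_lo)
    new_mass = np.zeros(n)
    if t_hi > t_lo:
        new_mass[t_lo + l_lo : t_hi + l_lo] = c[t_lo:t_hi]
    a_lo = float(c[:t_lo].sum()) + total * tail_lo
    a_hi = float(c[t_hi:].sum()) + total * tail_hi
    return new_mass, a_lo, a_hi


def _drift_variance(lam: float, sigma_a2: float, dt: float) -> float:
    if abs(lam) < 1e-12:
        return sigma_a2 * dt
    return sigma_a2 * (np.exp(2.0 * lam * dt) - 1.0) / (2.0 * lam)


# ----------------------------------------------------------------------------
# propagation
# ----------------------------------------------------------------------------

def _trial_events(
    trial: Trial, params: AccumulatorParams, bias: BiasExtension
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-sequence arrays: inter-event intervals ``dts`` (K+1 of them,
    the last reaching stimulus end) and per-click kick mean/sd (K each)."""
    seq = adapt_click_amplitudes(
        trial.left_clicks, trial.right_clicks, params.phi, params.tau_phi
    )
    times = np.concatenate([seq.times, [trial.duration]])
    dts = np.diff(np.concatenate([[0.0], times]))
    is_right = seq.sides > 0
    gains = np.where(is_right, bias.gain_R, bias.gain_L)
    ss2 = np.where(
        is_right,
        bias.effective_sigma_s2("R", params.sigma_s2),
        bias.effective_sigma_s2("L", params.sigma_s2),
    )
    mus = seq.sides * gains * seq.amplitudes
    sds = np.abs(gains * seq.amplitudes) * np.sqrt(ss2)
    return dts, mus, sds


def _propagate_numpy(mass, a_neg, a_pos, edges, lam, sigma_a2, dts, mus, sds):
    """Reference event loop (numerically identical to the compiled core)."""
    for k in range(len(dts)):
        dt = dts[k]
        if dt > 0:
            gamma = float(np.exp(lam * dt))
            v = _drift_variance(lam, sigma_a2, dt)
            if gamma != 1.0:
                mass, lo, hi = _remap(mass, edges, gamma, 0.0)
                a_neg += lo
                a_pos += hi
            if v > 0:
                mass, lo, hi = _convolve_absorb(mass, edges, 0.0, np.sqrt(v))
                a_neg += lo
                a_pos += hi
        if k < len(mus):
            mu, sd = mus[k], sds[k]
            if sd > 0:
                mass, lo, hi = _convolve_absorb(mass, edges, mu, sd)
            elif mu != 0.0:
                mass, lo, hi = _remap(mass, edges, 1.0, mu)
            else:
                lo = hi = 0.0
            a_neg += lo
            a_pos += hi
    return mass, a_neg, a_pos


def propagate_density(
    trial: Trial,
    params: AccumulatorParams,
    bias: Optional[BiasExtension] = None,
    dx: Optional[float] = None,
    use_compiled: Optional[bool] = None,
) -> DensityGrid:
    """Propagate the accumulator density through one trial's click train."""
    bias = bias or _NO_BIAS
    for name in ("lam", "sigma_a2", "sigma_s2", "sigma_i2", "B", "phi", "tau_phi"):
        if not np.isfinite(getattr(params, name)):
            raise ValueError(f"non-finite parameter {name}")
    edges = _make_edges(params.B, dx)
    mass, a_neg, a_pos = _initial_mass(edges, params.sigma_i2)
    dts, mus, sds = _trial_events(trial, params, bias)
    if use_compiled is None:
        use_compiled = _kernels.HAVE_NUMBA
    if use_compiled and _kernels.HAVE_NUMBA:
        a_neg, a_pos = _kernels.propagate_core(
            mass, a_neg, a_pos, edges, params.lam, params.sigma_a2,
            dts, mus, sds, _NSIG,
        )
    else:
        mass, a_neg, a_pos = _propagate_numpy(
            mass, a_neg, a_pos, edges, params.lam, params.sigma_a2, dts, mus, sds
        )
    return DensityGrid(edges=edges, mass=mass, absorbed_neg=float(a_neg),
                       absorbed_pos=float(a_pos), B=params.B)


def _transform_p0(p0, params: AccumulatorParams, bias: BiasExtension):
    """Lapse mixing followed by post-categorization reversals."""
    p1 = (1.0 - params.lapse) * p0 + params.lapse / 2.0
    return p1 * (1.0 - bias.kappa_R) + (1.0 - p1) * bias.kappa_L


def choice_probability(
    trial: Trial,
    params: AccumulatorParams,
    bias: Optional[BiasExtension] = None,
    dx: Optional[float] = None,
    grid: Optional[DensityGrid] = None,
) -> float:
    """P(choice = Right | click times, parameters)."""
    bias = bias or _NO_BIAS
    if not -params.B <= params.sho <= params.B:
        raise ValueError(f"decision boundary sho={params.sho} outside [-B, B]")
    if grid is None:
        grid = propagate_density(trial, params, bias, dx=dx)
    p0 = grid.prob_above(params.sho - bias.shift)
    p = _transform_p0(p0, params, bias)
    return float(min(max(p, 0.0), 1.0))


def log_likelihood(
    trials: Iterable[Trial],
    params: AccumulatorParams,
    bias: Optional[BiasExtension] = None,
    dx: Optional[float] = None,
) -> float:
    """Summed log choice probability over evidence trials.

    Only accumulation and single-sided trials enter the product; a trial of
    those types without a recorded choice is an error.
    """
    bias = bias or _NO_BIAS
    ll = 0.0
    n_used = 0
    for trial in trials:
        if not trial.has_clicks:
            continue
        if trial.choice == "none":
            raise ValueError(f"trial {trial.trial_id} has no recorded choice")
        p_r = choice_probability(trial, params, bias, dx=dx)
        p = p_r if trial.choice == "R" else 1.0 - p_r
        ll += np.log(max(p, 1e-300))
        n_used += 1
    if n_used == 0:
        raise ValueError("no evidence trials with choices in input")
    return float(ll)


# ----------------------------------------------------------------------------
# cached per-trial densities for fits over post-categorization parameters
# ----------------------------------------------------------------------------

#: free parameters that do not alter the propagated density
POST_DENSITY_PARAMS = frozenset(
    {"kappa_L", "kappa_R", "kappa_ipsi", "kappa_contra", "shift", "sho", "lapse"}
)


class DensityCache:
    """Per-trial terminal densities, reusable across likelihood evaluations.

    The post-categorization parameters (``kappa``'s, ``shift``, ``sho``,
    ``lapse``) only re-read the terminal density, so fits that free just
    those can propagate each trial once and then evaluate the likelihood in
    O(n) per candidate parameter value.
    """

    def __init__(
        self,
        trials: Iterable[Trial],
        params: AccumulatorParams,
        bias: Optional[BiasExtension] = None,
        dx: Optional[float] = None,
        require_choices: bool = True,
    ) -> None:
        bias = bias or _NO_BIAS
        self.params = params
        self.bias = bias
        ev = [t for t in trials if t.has_clicks]
        if not ev:
            raise ValueError("no evidence trials in input")
        if require_choices and any(t.choice == "none" for t in ev):
            raise ValueError("all evidence trials must have recorded choices")
        self.trials = ev
        self.choice_is_right = np.array([t.choice == "R" for t in ev])
        grids = [propagate_density(t, params, bias, dx=dx) for t in ev]
        self.edges = grids[0].edges
        self.B = params.B
        self.dx_ = grids[0].dx
        M = np.stack([g.mass for g in grids])
        # suffix[i] = mass in bins >= i
        self.suffix = np.concatenate(
            [np.cumsum(M[:, ::-1], axis=1)[:, ::-1], np.zeros((len(ev), 1))], axis=1
        )
        self.M = M
        self.a_neg = np.array([g.absorbed_neg for g in grids])
        self.a_pos = np.array([g.absorbed_pos for g in grids])

    def __len__(self) -> int:
        return len(self.trials)

    def p0_above(self, threshold: float) -> np.ndarray:
        """Vector of per-trial P(a > threshold)."""
        n_bins = self.M.shape[1]
        p = np.zeros(len(self.trials))
        if self.B > threshold:
            p += self.a_pos
        if -self.B > threshold:
            p += self.a_neg
        if threshold < -self.B:
            p += self.suffix[:, 0]
        elif threshold < self.B:
            idx = int(np.floor((threshold + self.B) / self.dx_))
            idx = min(max(idx, 0), n_bins - 1)
            frac = (self.edges[idx + 1] - threshold) / self.dx_
            frac = min(max(frac, 0.0), 1.0)
            p += self.M[:, idx] * frac + self.suffix[:, idx + 1]
        return np.clip(p, 0.0, 1.0)

    def p_right(
        self,
        sho: Optional[float] = None,
        shift: Optional[float] = None,
        lapse: Optional[float] = None,
        kappa_L: Optional[float] = None,
        kappa_R: Optional[float] = None,
    ) -> np.ndarray:
        """Per-trial P(Right) with post-categorization parameters overridden."""
        sho = self.params.sho if sho is None else sho
        shift = self.bias.shift if shift is None else shift
        lapse = self.params.lapse if lapse is None else lapse
        kappa_L = self.bias.kappa_L if kappa_L is None else kappa_L
        kappa_R = self.bias.kappa_R if kappa_R is None else kappa_R
        p0 = self.p0_above(sho - shift)
        p1 = (1.0 - lapse) * p0 + lapse / 2.0
        return np.clip(p1 * (1.0 - kappa_R) + (1.0 - p1) * kappa_L, 0.0, 1.0)

    def log_likelihood(self, weights: Optional[np.ndarray] = None, **kwargs) -> float:
        """LL with optional per-trial weights (e.g. bootstrap counts)."""
        p_r = self.p_right(**kwargs)
        p = np.where(self.choice_is_right, p_r, 1.0 - p_r)
        logp = np.log(np.maximum(p, 1e-300))
        return float(logp.sum() if weights is None else weights @ logp)
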