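# Methods

## The model

`pclicks` models choice behavior in the Poisson Clicks task: on each trial a
rat (or a synthetic subject) hears two concurrent click trains, left and
right, generated by independent Poisson processes, and reports which side had
more clicks.  The core model is a one-dimensional bounded stochastic
accumulator with nine parameters.  Writing `a(t)` for the accumulated
evidence (positive = rightward),

* `a(0) ~ N(0, sigma_i2)` — noisy initial condition;
* between clicks `da = lambda * a dt + sigma_a dW` — a linear drift
  (`lambda < 0` leaky, forgetting old evidence; `lambda > 0` unstable,
  overweighting early evidence; `tau = 1/lambda` is the memory time
  constant) plus accumulation diffusion with variance rate `sigma_a2`;
* each click at time `t_k` kicks `a` by `s_k * C_k * eta_k`, where
  `s_k = +1` (right) or `-1` (left), `C_k` is the adapted click amplitude
  (below) and `eta_k ~ N(1, sigma_s2)` is i.i.d. multiplicative sensory
  noise, so the kick has mean `s_k C_k` and variance `C_k^2 sigma_s2`;
* `a` is absorbed (frozen) on reaching the sticky bounds `±B`;
* at stimulus end the model answers Right iff `a > sho` (the decision
  boundary); a `lapse` fraction of trials instead answers at random.

Sensory adaptation follows a shared (binaural) state `C` with
`C(0) = 1`: between clicks `C` relaxes towards 1 with time constant
`tau_phi` (closed form `C(t0+dt) = 1 - (1 - C(t0)) exp(-dt/tau_phi)`), and
immediately after each click `C <- phi * C`.  Clicks are delivered at the
pre-multiplication value of `C`, so the first click always has unit
amplitude; `phi < 1` is depression, `phi > 1` facilitation.  Exactly
simultaneous left/right clicks are processed left-then-right and flagged;
no cancellation is applied.

The trial likelihood is `P(d_i | t_{i,R}, t_{i,L}, theta)` — the model's
probability of the recorded choice given the exact click times — and the
dataset log-likelihood is the sum over trials, treating trials as
independent.  Only accumulation and single-sided trials enter the product.

### Lateralized extensions

For unilateral-inactivation analyses the model is extended with four bias
mechanisms (module `pclicks.bias`):

* **post_cat** — a fraction `kappa_L` of Left decisions and `kappa_R` of
  Right decisions is reversed after categorization.  This scales the
  psychometric curve vertically and biases performance identically on easy
  and hard trials.
* **gain** — left and right clicks get different impact magnitudes
  (`gain_L`, `gain_R`; control 1).
* **shift** — a constant added to `a` before categorization, equivalent to
  moving the decision boundary; shifts the psychometric curve horizontally.
* **noise** — per-side sensory-noise variances `sigma_s2_L`, `sigma_s2_R`.

Single-parameter variants free exactly the contralateral parameter and pin
the ipsilateral one at control; the 8-parameter variant frees
`{lambda, sigma_a2, sigma_s2_ipsi, shift, kappa_ipsi, sigma_s2_contra,
gain_contra, kappa_contra}` with initial noise, bounds and the two
adaptation parameters fixed at control and the ipsilateral gain pinned at 1.
The **bias** of a fitted variant is the contralateral minus ipsilateral
parameter value (the shift variant reports the shift itself).

Reversals (`kappa`) are applied after lapse mixing, i.e. they act on all
emitted decisions including lapses.  Consequence worth noting: on easy
trials the ipsi-minus-contra percent-correct bias equals `kappa_contra`
exactly, independent of the lapse rate, because `kappa` flips also rescue
errors on ipsilateral trials (`bias = 1 - (1-kappa)(P_err + P_corr) =
kappa`).  This also means `kappa` is identifiable only with the lapse held
fixed, which matches the fixed-control-parameters fitting protocol.

## Likelihood computation

`pclicks.likelihood` computes choice probabilities exactly (to grid
tolerance) by propagating the accumulator density, event-driven:

* the density lives on a uniform grid over `(-B, B)` (bin width
  `min(B/200, 0.05)` by default, edges exactly at `±B`) plus two absorbed
  point masses at the bounds;
* between clicks the exact linear-SDE transition kernel is applied as a
  deterministic rescaling `a -> a exp(lambda dt)` (conservative
  piecewise-constant rebinning via the CDF) followed by convolution with a
  zero-mean Gaussian of variance `sigma_a2 (exp(2 lambda dt) - 1)/(2
  lambda)` (limit `sigma_a2 dt` as `lambda -> 0`) — there is no Euler time
  stepping, so the only discretization error is on the `a` axis;
* each click convolves the interior density with a Gaussian kick
  `N(± gain C_k, gain^2 C_k^2 sigma_s2)`; a zero-variance kick degenerates
  to the same CDF rebinning;
* after every step, mass outside `(-B, B)` moves to the absorbed bins and
  never returns;
* Gaussian kernels are bin-integrated (CDF differences) and truncated at
  5.5 standard deviations, with the truncated tails routed to the absorbed
  bins so total mass is conserved exactly (the conservation test requires
  1e-6; float round-off keeps it near 1e-15).

`P(Right)` is the interior mass strictly above `sho - shift` (the boundary
bin contributes fractionally by linear interpolation) plus the absorbed
mass at `+B`, then lapse-mixed (`(1-lapse) P0 + lapse/2`) and passed
through the reversal transform `P1 (1-kappa_R) + (1-P1) kappa_L`.

The event loop has two interchangeable backends: a numba-compiled core
(`pclicks._kernels`) and a pure numpy/scipy path, numerically identical to
~1e-15 (tested).  The compiled path exists because per-event call overhead
dominates for trials with tens of clicks; a typical meta-rat trial costs
~2.5 ms at bin width 0.1 and ~8 ms at the default width.

Grid resolution: halving the default bin width changes choice probabilities
by less than 1e-3 (tested), and fits/cross-validation use bin width 0.1
(changes well below the statistical noise of the fits) to keep runtimes in
minutes on one CPU.

The Monte-Carlo oracle (`pclicks.simulate.simulate_trial_paths`) simulates
the same generative process path-by-path with absorption checked at the
same event schedule, so density propagation and simulation agree to
Monte-Carlo error; this dual route (grid vs paths) is the package's
internal correctness check and is never collapsed onto one implementation.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: total click rate 40/s on
accumulation trials, stimulus durations 0.1-1 s, single-sided trials at
100/s, session mixtures of 65% accumulation / 25% free-choice / 10%
side-LED (single-sided trials ≈8% when enabled), and an 8-pair difficulty
ladder of symmetric (rate_L, rate_R) pairs with evenly spaced log rate
ratios from ≈29:11 to ≈39:1 (the task controls difficulty through the rate
ratio; the exact ladder and the duration distribution are not fixed by the
task description, so both are config-exposed with these defaults; durations
are uniform as the neutral choice).  Choices come from the accumulator
itself; free-choice and side-LED trials (which carry no clicks) use simple
preference parameters documented in `simulate_choices` and exist only so
the full session pipeline is exercised.  Simulated inactivation sessions
alternate left/right infusion labels and mirror the requested contralateral
perturbation onto physical sides.

Not modelled: fixation violations, reward timing, inter-trial dependencies,
response times, and any within-session nonstationarity.  Passing tests
therefore demonstrate that the estimation machinery recovers known
mechanisms from data generated by the model itself — not that the model is
a correct description of any particular animal.

A note on parameter identifiability under the bundled "meta-rat" values:
with the printed sensory-noise variance (`sigma_s2 = 57.6`) the drift rate
`lambda` is only weakly identified — the expected log-likelihood gain of
the true `lambda` over values several units away is ~0.003 per trial, so
its sampling SD is ~1 even at n = 5000 (consistent with the width of the
published bootstrap interval for `lambda`).  Recovery tests for the fitting
machinery therefore use a low-noise regime where `lambda` is strongly
identified, and meta-rat-conditions tests target the post-categorization
parameter, whose estimator is well behaved (SD ≈ 0.023 at n = 1200).

## Fitting and inference

* **MLE** (`fit_mle`): single-parameter variants are fit by a dense scan
  over the box bounds (their profiles have a single maximum) plus bounded
  scalar polish; multi-parameter models use L-BFGS-B with numeric gradients
  (no analytic gradient is attempted) from 5 multistarts jittered by 10% of
  the bound range around the control values; LL convergence tolerance 1e-6.
  Box bounds: `lambda ∈ [-40, 40]`, variances ≥ 0 with generous caps
  (`sigma_a2 ≤ 200`, `sigma_s2 ≤ 400`, `sigma_i2 ≤ 40`), `B ∈ (0.5, 40]`,
  `phi ∈ (0, 2]`, `tau_phi ∈ (0.005, 1]`, `sho ∈ [-5, 5]`, probabilities in
  [0, 1], `gain ∈ [0, 5]`, `shift ∈ [-10, 10]`.
* **Caching**: parameters acting after density propagation (`kappa`'s,
  `shift`, `sho`, `lapse`) reuse per-trial terminal densities, making their
  fits O(n) per candidate value.  Grid-based refits (`scan_fit`,
  `trial_logp_grid`) evaluate each trial once per grid point and are shared
  across bootstrap resamples and cross-validation folds.
* **Bootstrap** (`bootstrap_fit`): trials resampled with replacement at the
  original n, 300 refits by default, 95% percentile intervals; a parameter
  is flagged significant when the control value falls outside its interval.
  Single-parameter bootstraps refit by weighted grid argmax with parabolic
  refinement (the grid log-probabilities are computed once).
* **Metropolis-Hastings** (`mh_sample`): symmetric random-walk with
  independent uniform proposals per coordinate (half-width per parameter;
  default 5% of the bound range, tuned toward 20-50% acceptance), 4 chains
  of 10,000 samples, burn-in 100, thinning 4 (2,475 retained per chain);
  moves outside the bounds are rejected (flat prior on the box).
  Acceptance rates outside [0.05, 0.8] trigger a warning.  Split-free
  Gelman-Rubin diagnostics are provided; marginal intervals give the
  non-parametric significance check.
* **Cross-validation** (`loso_cv`): leave-one-session-out; each variant is
  fit (dense scan) on the other sessions and scored by held-out
  log-likelihood per trial.  Only the first 250 trials of each session
  enter fits by default, mirroring the session-truncation protocol.
* **Model comparison**: `BIC = -2 LL + k ln n`, `AIC = -2 LL + 2 k`; tables
  carry full precision and are rounded to one decimal for display.

Numerical details: per-trial probabilities are floored at 1e-300 before the
log; with `lapse > 0` every trial probability is bounded below by
`lapse/2` times the reversal terms, so no single trial can dominate a fit.
Degenerate inputs (empty trial sets, single sessions, zero proposal widths,
non-finite parameters, boundaries outside `[-B, B]`) raise `ValueError`.

## Descriptive analyses

* **Psychometric**: 4-parameter logistic `y = y0 + a / (1 + exp(-(x -
  x0)/b))` fit to binned P(went right) vs click difference by nonlinear
  least squares (visualization only; bounded at [0, 1] with the inflection
  restricted to the observed range).  On near-flat data the 4-parameter
  sigmoid is not identifiable (a shallow compressed curve is fit equally
  well by a distant broad sigmoid); tests use one-sided perturbations where
  the geometry is well posed.
* **Chronometric**: difficulty = |log(rate_R/rate_L)| split into
  equal-count terciles (easy/medium/hard), then accuracy by duration
  quantile bins with Wilson 95% binomial intervals; tied-count trials are
  excluded from accuracy.
* **Reverse correlation**: click trains binned at 50 ms (config-exposed),
  converted to local right-minus-left rate minus the generative mean
  difference; only bins fully inside the trial's duration enter (partial
  trailing bins carry biased rate estimates).  Trials are averaged by
  choice group, or, for the model-predicted kernel, each trial contributes
  its predicted P(Right) to the right group and the complement to the left
  group.  The exact smoothing of the original analysis is not restated in
  the task description, so the bin width is a documented stand-in.
* **Bias summary**: per-session ipsilateral minus contralateral percent
  correct on ipsi/contra-relabelled trials (infusion side reads as left),
  with sessions missing either category excluded; free-choice ipsilateral
  fraction reported where present.

## Problem sizes used in tests and the acceptance script

Simulation sizes were chosen so the full suite and the acceptance script
each run in minutes on one CPU while keeping every check's statistical
power adequate: oracle agreement uses 200 trials × 1e5 paths; kappa
recovery 5,000 trials; cross-validation 30 sessions × 80 trials with a
13-point scan grid; bootstrap coverage 50 replicates of 150 trials with 100
resamples; Metropolis checks 4 chains × 3,000 samples on a known Gaussian.
Fits in these checks use grid bin width 0.1 (see grid-convergence note).

## Known limitations

* `lambda` (and the strongly covarying noise/lapse parameters) are weakly
  identified under the bundled meta-rat regime; see the identifiability
  note above.
* The published 8-parameter AIC cell in the unilateral comparison table is
  internally inconsistent with its own LL and k; the package reports the
  formula value (the BIC cell is consistent).
* Absorption is enforced at event boundaries (initial condition, each
  click, stimulus end), matching the event-driven kernel; a path that
  crosses a bound and returns strictly between events is not absorbed, in
  either the density or the path simulation, so the two routes agree by
  construction.
* The 4-parameter sigmoid fit is descriptive and can be degenerate on flat
  psychometric data; its `converged` flag and the binned proportions are
  returned so callers can tell.
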