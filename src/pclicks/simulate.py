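"""Synthetic Poisson-clicks stimuli and model-driven choices.

The generators emulate the study conditions of the rat task: two independent
Poisson click trains whose rates sum to 40 clicks/s on accumulation trials,
stimulus durations of 0.1-1 s, single-sided control trials at 100 clicks/s,
and session mixtures of accumulation / free-choice / side-LED trials.
Choices are produced by simulating the accumulator's exact generative
process; with many paths per trial the same routine serves as the
Monte-Carlo oracle for the density-propagated likelihood.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .adaptation import adapt_click_amplitudes
from .params import AccumulatorParams, BiasExtension
from .trials import Trial, TrialSet

__all__ = [
    "TOTAL_RATE",
    "SINGLE_SIDED_RATE",
    "DEFAULT_MIXTURE",
    "default_difficulty_set",
    "generate_trial",
    "generate_single_sided_trial",
    "generate_dataset",
    "simulate_trial_paths",
    "mc_choice_probability",
    "simulate_choices",
    "generate_unilateral_sessions",
]

#: summed generative click rate on accumulation trials (clicks/s)
TOTAL_RATE = 40.0
#: click rate of single-sided control trials (clicks/s)
SINGLE_SIDED_RATE = 100.0
#: session trial-type mixture (accumulation / free choice / side LED)
DEFAULT_MIXTURE: Dict[str, float] = {
    "accumulation": 0.65,
    "free_choice": 0.25,
    "side_led": 0.10,
}
DEFAULT_DURATION_RANGE = (0.1, 1.0)

_TIME_DECIMALS = 9  # click times kept at nanosecond resolution for lossless io


def default_difficulty_set(
    n_pairs: int = 8, total_rate: float = TOTAL_RATE
) -> List[Tuple[float, float]]:
    """Symmetric (rate_L, rate_R) ladder with evenly spaced log rate ratios.

    Returns ``n_pairs`` pairs summing to ``total_rate``, half favouring each
    side, spanning easy (≈39:1) to hard (≈29:11).
    """
    if n_pairs % 2:
        raise ValueError("n_pairs must be even (ladder is left/right symmetric)")
    k = n_pairs // 2
    g_max = np.log((total_rate - 1.0) / 1.0)  # easiest pair ~ 39:1
    gammas = g_max * np.arange(1, k + 1) / k
    pairs = []
    for g in gammas:
        r_hi = total_rate / (1.0 + np.exp(-g))
        pairs.append((total_rate - r_hi, r_hi))  # right-favoured
        pairs.append((r_hi, total_rate - r_hi))  # left-favoured
    return pairs


def _poisson_train(rate: float, duration: float, rng: np.random.Generator):
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    return tuple(np.round(t, _TIME_DECIMALS))


def _correct_side(n_left: int, n_right: int) -> str:
    if n_right > n_left:
        return "R"
    if n_left > n_right:
        return "L"
    return "either"


def generate_trial(
    rate_left: float,
    rate_right: float,
    duration: float,
    seed=None,
    trial_id: int = 0,
    trial_type: str = "accumulation",
    **trial_kwargs,
) -> Trial:
    """One trial with independent Poisson click trains on each side.

    Click counts are Poisson(rate * duration) and, given the counts, times
    are i.i.d. uniform on [0, duration].  ``seed`` may be an int or an
    ``np.random.Generator``.
    """
    if rate_left < 0 or rate_right < 0:
        raise ValueError("click rates must be >= 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if trial_type == "accumulation" and not (0.1 <= duration <= 1.0):
        raise ValueError(
            f"accumulation-trial duration must lie in [0.1, 1] s, got {duration}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    left = _poisson_train(rate_left, duration, rng)
    right = _poisson_train(rate_right, duration, rng)
    return Trial(
        trial_id=trial_id,
        duration=duration,
        left_clicks=left,
        right_clicks=right,
        trial_type=trial_type,
        generative_rate_left=rate_left,
        generative_rate_right=rate_right,
        correct_side=_correct_side(len(left), len(right)),
        **trial_kwargs,
    )


def generate_single_sided_trial(
    side: str, duration: float, seed=None, trial_id: int = 0, **trial_kwargs
) -> Trial:
    """All clicks on one side at the fixed 100 clicks/s control rate."""
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    rate_l = SINGLE_SIDED_RATE if side == "L" else 0.0
    rate_r = SINGLE_SIDED_RATE if side == "R" else 0.0
    t = generate_trial(
        rate_l, rate_r, duration, seed=seed, trial_id=trial_id,
        trial_type="single_sided", **trial_kwargs,
    )
    # the lit side is correct by definition, even on a zero-click draw
    return Trial(**{**t.__dict__, "correct_side": side})


def generate_dataset(
    n_trials: int,
    mixture: Optional[Dict[str, float]] = None,
    difficulty_set: Optional[Sequence[Tuple[float, float]]] = None,
    duration_range: Tuple[float, float] = DEFAULT_DURATION_RANGE,
    seed=None,
    single_sided_fraction: float = 0.0,
    session_id: str = "S000",
    id_offset: int = 0,
    **trial_kwargs,
) -> TrialSet:
    """Generate a session-like set of trials.

    Trial types are assigned multinomially from ``mixture`` (default 65%
    accumulation / 25% free choice / 10% side LED); accumulation trials draw
    a (rate_L, rate_R) pair uniformly from ``difficulty_set`` and a duration
    uniformly from ``duration_range``.  ``single_sided_fraction`` carves the
    given fraction of trials out of the mixture for single-sided controls
    (≈0.08 when enabled in the task).
    """
    mixture = dict(DEFAULT_MIXTURE) if mixture is None else dict(mixture)
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("mixture proportions must sum to 1")
    if single_sided_fraction:
        mixture = {k: v * (1.0 - single_sided_fraction) for k, v in mixture.items()}
        mixture["single_sided"] = (
            mixture.get("single_sided", 0.0) + single_sided_fraction
        )
    if mixture.get("accumulation", 0.0) > 0:
        if difficulty_set is None:
            difficulty_set = default_difficulty_set()
        if not len(difficulty_set):
            raise ValueError(
                "difficulty_set must be non-empty when accumulation trials are requested"
            )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    types = list(mixture)
    probs = np.array([mixture[k] for k in types])
    assigned = rng.choice(len(types), size=n_trials, p=probs)
    trials: List[Trial] = []
    for i, ti in enumerate(assigned):
        ttype = types[ti]
        # durations quantized like click times so trial tables round-trip
        dur = float(np.round(rng.uniform(*duration_range), _TIME_DECIMALS))
        common = dict(trial_id=id_offset + i, session_id=session_id, **trial_kwargs)
        if ttype == "accumulation":
            rl, rr = difficulty_set[rng.integers(len(difficulty_set))]
            trials.append(generate_trial(rl, rr, dur, seed=rng, **common))
        elif ttype == "single_sided":
            side = "L" if rng.random() < 0.5 else "R"
            trials.append(generate_single_sided_trial(side, dur, seed=rng, **common))
        elif ttype == "side_led":
            side = "L" if rng.random() < 0.5 else "R"
            trials.append(
                Trial(duration=dur, trial_type="side_led", correct_side=side, **common)
            )
        else:  # free_choice
            trials.append(
                Trial(duration=dur, trial_type="free_choice", correct_side="either",
                      **common)
            )
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return TrialSet(trials, mixture=mixture, seed=seed_val)


# ----------------------------------------------------------------------------
# path simulation (generative process / Monte-Carlo oracle)
# ----------------------------------------------------------------------------

def simulate_trial_paths(
    trial: Trial,
    params: AccumulatorParams,
    bias: Optional[BiasExtension] = None,
    n_paths: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate ``n_paths`` accumulator runs; returns a boolean Right array.

    The exact generative process: ``a(0) ~ N(0, sigma_i2)``; between events
    the exact linear-SDE update; per-click kicks ``side*gain*C_k*eta`` with
    ``eta ~ N(1, sigma_s2_side)``; sticky absorption at ``+/-B`` checked
    after every step; decision ``a + shift > sho``; lapse mixing; then
    ``kappa`` reversals.
    """
    if not trial.has_clicks:
        raise ValueError("trial has no click stimulus to simulate")
    bias = bias or BiasExtension()
    rng = rng or np.random.default_rng()
    p = params
    a = rng.normal(0.0, np.sqrt(p.sigma_i2), n_paths) if p.sigma_i2 > 0 else np.zeros(n_paths)
    done = np.abs(a) >= p.B
    a = np.where(done, np.sign(a) * p.B, a)

    seq = adapt_click_amplitudes(trial.left_clicks, trial.right_clicks, p.phi, p.tau_phi)
    t_cur = 0.0
    events = list(zip(seq.times, seq.sides, seq.amplitudes)) + [(trial.duration, 0.0, 0.0)]
    for t_ev, side, amp in events:
        dt = t_ev - t_cur
        if dt > 0:
            gamma = np.exp(p.lam * dt)
            if abs(p.lam) < 1e-12:
                v = p.sigma_a2 * dt
            else:
                v = p.sigma_a2 * (np.exp(2.0 * p.lam * dt) - 1.0) / (2.0 * p.lam)
            upd = a * gamma
            if v > 0:
                upd = upd + rng.normal(0.0, np.sqrt(v), n_paths)
            a = np.where(done, a, upd)
            hit = (~done) & (np.abs(a) >= p.B)
            a = np.where(hit, np.sign(a) * p.B, a)
            done |= hit
            t_cur = t_ev
        if side != 0.0:
            s = "R" if side > 0 else "L"
            gain = bias.gain_R if side > 0 else bias.gain_L
            ss2 = bias.effective_sigma_s2(s, p.sigma_s2)
            eta = rng.normal(1.0, np.sqrt(ss2), n_paths) if ss2 > 0 else 1.0
            kick = side * gain * amp * eta
            a = np.where(done, a, a + kick)
            hit = (~done) & (np.abs(a) >= p.B)
            a = np.where(hit, np.sign(a) * p.B, a)
            done |= hit

    right = (a + bias.shift) > p.sho
    if p.lapse > 0:
        is_lapse = rng.random(n_paths) < p.lapse
        right = np.where(is_lapse, rng.random(n_paths) < 0.5, right)
    if bias.kappa_R > 0 or bias.kappa_L > 0:
        flip_to_left = right & (rng.random(n_paths) < bias.kappa_R)
        flip_to_right = (~right) & (rng.random(n_paths) < bias.kappa_L)
        right = (right & ~flip_to_left) | flip_to_right
    return right


def mc_choice_probability(
    trial: Trial,
    params: AccumulatorParams,
    bias: Optional[BiasExtension] = None,
    n_paths: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo estimate of P(Right) — the independent oracle for
    :func:`pclicks.likelihood.choice_probability`."""
    right = simulate_trial_paths(trial, params, bias, n_paths=n_paths, rng=rng)
    return float(right.mean())


def simulate_choices(
    trials: TrialSet,
    params: AccumulatorParams,
    bias: Optional[BiasExtension] = None,
    n_paths_per_trial: int = 1,
    seed=None,
    led_accuracy: float = 0.95,
    free_choice_p_right: float = 0.5,
) -> TrialSet:
    """Fill in choices for every trial of a set.

    Evidence trials are decided by simulating the accumulator (one sampled
    path; with ``n_paths_per_trial > 1`` the first path decides but all are
    drawn, which keeps the stream aligned with the oracle).  Side-LED trials
    follow the lit side with probability ``led_accuracy`` and free-choice
    trials go right with probability ``free_choice_p_right`` — simple
    preference rules for trial types the accumulator does not model.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: List[Trial] = []
    for t in trials:
        if t.has_clicks:
            right = simulate_trial_paths(t, params, bias, n_paths=n_paths_per_trial,
                                         rng=rng)
            out.append(t.with_choice("R" if right[0] else "L"))
        elif t.trial_type == "side_led":
            correct = rng.random() < led_accuracy
            side = t.correct_side if correct else ("L" if t.correct_side == "R" else "R")
            out.append(t.with_choice(side))
        else:
            out.append(t.with_choice("R" if rng.random() < free_choice_p_right else "L"))
    return TrialSet(out, mixture=dict(trials.mixture), seed=trials.seed,
                    frame=trials.frame)


def generate_unilateral_sessions(
    n_sessions: int,
    trials_per_session: int,
    params: AccumulatorParams,
    kappa_contra: float = 0.0,
    gain_contra: float = 1.0,
    sigma_s2_contra: Optional[float] = None,
    shift_toward_ipsi: float = 0.0,
    seed=None,
    mixture: Optional[Dict[str, float]] = None,
    duration_range: Tuple[float, float] = DEFAULT_DURATION_RANGE,
) -> List[TrialSet]:
    """Simulated unilateral-infusion sessions with a lateralized perturbation.

    Sessions alternate left/right infusion; the requested contralateral
    perturbation is mirrored onto the physical sides accordingly, so pooling
    the sessions after ipsi/contra relabelling recovers a consistent bias.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mixture = mixture or {"accumulation": 1.0}
    sessions: List[TrialSet] = []
    for s in range(n_sessions):
        infusion = "left_infusion" if s % 2 == 0 else "right_infusion"
        ipsi = "L" if infusion == "left_infusion" else "R"
        bias = BiasExtension.from_ipsi_contra(
            ipsi_side=ipsi,
            kappa_contra=kappa_contra,
            gain_contra=gain_contra,
            sigma_s2_contra=sigma_s2_contra,
            shift=(shift_toward_ipsi if ipsi == "R" else -shift_toward_ipsi),
        )
        ts = generate_dataset(
            trials_per_session,
            mixture=mixture,
            duration_range=duration_range,
            seed=rng,
            session_id=f"S{s:03d}",
            id_offset=s * trials_per_session,
            condition=infusion,
            region="FOF",
        )
        sessions.append(simulate_choices(ts, params, bias, seed=rng))
    return sessions
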