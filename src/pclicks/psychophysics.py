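"""Descriptive behavioral analyses.

Psychometric curves (4-parameter sigmoid of choice vs click difference,
visualization only), chronometric curves (accuracy vs stimulus duration in
difficulty terciles), psychophysical reverse correlation (time-resolved
excess click rate conditioned on the choice, or weighted by a model's
predicted choice probabilities), and ipsi-minus-contra bias summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.stats.proportion import proportion_confint

from .trials import Trial, TrialSet

__all__ = [
    "PsychometricFit",
    "fit_psychometric",
    "chronometric",
    "ReverseCorrelation",
    "reverse_correlation",
    "bias_summary",
]


# ----------------------------------------------------------------------------
# psychometric sigmoid
# ----------------------------------------------------------------------------

def sigmoid(x, y0, a, x0, b):
    """4-parameter logistic: ``y = y0 + a / (1 + exp(-(x - x0)/b))``.

    ``y0`` is the floor, ``y0 + a`` the ceiling, ``x0`` the inflection point
    in clicks and ``b`` the slope in clicks.
    """
    return y0 + a / (1.0 + np.exp(-(np.asarray(x, float) - x0) / b))


@dataclass
class PsychometricFit:
    y0: float
    a: float
    x0: float
    b: float
    converged: bool = True
    n_trials: int = 0
    bins: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def predict(self, x):
        return sigmoid(x, self.y0, self.a, self.x0, self.b)


def fit_psychometric(trials: Iterable[Trial]) -> PsychometricFit:
    """Fit P(went Right) vs #right-#left clicks with the 4-parameter sigmoid.

    Trials are binned by their integer click difference; the sigmoid is fit
    to the binned proportions by nonlinear least squares.  These fits are
    descriptive (visualization), not part of the accumulator likelihood.
    """
    ev = [t for t in trials if t.has_clicks and t.choice in ("L", "R")]
    if not ev:
        raise ValueError("no evidence trials with choices")
    x = np.array([t.click_difference for t in ev])
    y = np.array([t.choice == "R" for t in ev], dtype=float)
    df = pd.DataFrame({"x": x, "y": y}).groupby("x")["y"].agg(["mean", "count"])
    if len(df) < 4:
        raise ValueError("need >= 4 distinct click-difference bins to fit")
    xb = df.index.to_numpy(dtype=float)
    yb = df["mean"].to_numpy()
    p0 = (max(yb.min(), 1e-3), max(yb.max() - yb.min(), 1e-3), 0.0, 2.0)
    try:
        popt, _ = curve_fit(
            sigmoid, xb, yb, p0=p0,
            bounds=([0.0, 0.0, xb.min(), 1e-3], [1.0, 1.0, xb.max(), 100.0]),
            maxfev=10_000,
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    return PsychometricFit(*map(float, popt), converged=converged,
                           n_trials=len(ev), bins=df.reset_index())


# ----------------------------------------------------------------------------
# chronometric curves
# ----------------------------------------------------------------------------

def chronometric(
    trials: Iterable[Trial],
    n_difficulty_bins: int = 3,
    n_duration_bins: int = 5,
) -> pd.DataFrame:
    """Accuracy vs stimulus duration, within difficulty quantile bins.

    Difficulty is the absolute log ratio of the generative left/right click
    rates; trials are split into ``n_difficulty_bins`` quantile groups of
    equal size (easy/medium/hard for the default 3), then binned by duration.
    Returns one row per (difficulty bin, duration bin) with accuracy and a
    95% binomial CI.  Tied-count trials (``correct_side == 'either'``) are
    excluded from accuracy.
    """
    ev = [
        t for t in trials
        if t.has_clicks and t.choice in ("L", "R") and t.correct_side in ("L", "R")
    ]
    if not ev:
        raise ValueError("no scoreable evidence trials")
    for t in ev:
        if t.generative_rate_left <= 0 and t.generative_rate_right <= 0:
            raise ValueError(f"trial {t.trial_id} lacks generative rates")
    eps = 1e-12
    diff = np.array([
        abs(np.log((t.generative_rate_right + eps) / (t.generative_rate_left + eps)))
        for t in ev
    ])
    dur = np.array([t.duration for t in ev])
    correct = np.array([t.choice == t.correct_side for t in ev], dtype=float)

    # equal-count difficulty groups (easy = largest |log ratio|)
    order = np.argsort(np.argsort(-diff, kind="stable"), kind="stable")
    dbin = (order * n_difficulty_bins) // len(ev)

    rows = []
    labels = (
        ["easy", "medium", "hard"] if n_difficulty_bins == 3
        else [f"difficulty{i}" for i in range(n_difficulty_bins)]
    )
    for d in range(n_difficulty_bins):
        sel = dbin == d
        durs = dur[sel]
        edges = np.quantile(durs, np.linspace(0, 1, n_duration_bins + 1))
        edges = np.unique(edges)
        if edges.size < 2:  # all durations identical: one bin
            edges = np.array([edges[0], edges[0] + 1e-9])
        tbin = np.clip(np.searchsorted(edges, durs, side="right") - 1,
                       0, len(edges) - 2)
        for b in range(len(edges) - 1):
            in_bin = tbin == b
            if not in_bin.any():
                continue
            n = int(in_bin.sum())
            k = int(correct[sel][in_bin].sum())
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            rows.append({
                "difficulty": labels[d],
                "difficulty_bin": d,
                "n_trials": n,
                "duration_mid": float(durs[in_bin].mean()),
                "accuracy": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------------
# psychophysical reverse correlation
# ----------------------------------------------------------------------------

@dataclass
class ReverseCorrelation:
    """Choice-conditioned excess click-rate traces.

    ``times`` are bin centers (s from stimulus onset); ``right``/``left`` are
    the mean excess right-minus-left click rate (clicks/s, relative to the
    generative mean) for the right- and left-choice trial groups, with
    standard errors and the effective trial weights per bin.
    """

    times: np.ndarray
    right: np.ndarray
    left: np.ndarray
    right_sem: np.ndarray
    left_sem: np.ndarray
    n_right: np.ndarray
    n_left: np.ndarray
    bin_width: float

    @property
    def separation(self) -> np.ndarray:
        return self.right - self.left


def reverse_correlation(
    trials: Iterable[Trial],
    model_weights: Optional[Sequence[float]] = None,
    bin_width: float = 0.05,
) -> ReverseCorrelation:
    """Time-resolved excess click rate conditioned on choice.

    Each trial's click trains are binned at ``bin_width`` and converted to a
    local right-minus-left rate minus the generative mean difference; only
    bins fully contained in the trial's duration enter (partial trailing
    bins would carry a systematically biased rate estimate).  Trials are
    averaged within the
    right-choice and left-choice groups.  With ``model_weights`` (per-trial
    model-predicted P(Right)) each trial contributes its weight to the right
    group and its complement to the left group instead of its hard choice.
    """
    ev = [t for t in trials if t.has_clicks]
    if not ev:
        raise ValueError("no evidence trials for reverse correlation")
    if model_weights is None and any(t.choice not in ("L", "R") for t in ev):
        raise ValueError("trials need choices (or pass model_weights)")
    if model_weights is not None:
        w_r = np.asarray(list(model_weights), dtype=float)
        if w_r.size != len(ev):
            raise ValueError("one model weight per evidence trial required")
    else:
        w_r = np.array([1.0 if t.choice == "R" else 0.0 for t in ev])

    t_max = max(t.duration for t in ev)
    n_bins = int(np.floor(t_max / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("bin_width exceeds every trial duration")
    centers = (np.arange(n_bins) + 0.5) * bin_width

    sum_r = np.zeros(n_bins)
    sum_l = np.zeros(n_bins)
    sumsq_r = np.zeros(n_bins)
    sumsq_l = np.zeros(n_bins)
    n_r = np.zeros(n_bins)
    n_l = np.zeros(n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    for t, w in zip(ev, w_r):
        valid = min(int(np.floor(t.duration / bin_width + 1e-9)), n_bins)
        cr, _ = np.histogram(t.right_clicks, bins=edges)
        cl, _ = np.histogram(t.left_clicks, bins=edges)
        excess = (cr - cl)[:valid] / bin_width - (
            t.generative_rate_right - t.generative_rate_left
        )
        sum_r[:valid] += w * excess
        sumsq_r[:valid] += w * excess**2
        n_r[:valid] += w
        sum_l[:valid] += (1.0 - w) * excess
        sumsq_l[:valid] += (1.0 - w) * excess**2
        n_l[:valid] += 1.0 - w

    def _mean_sem(s, ss, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1e-300), np.nan)
            var = np.where(n > 1, ss / np.maximum(n, 1e-300) - mean**2, np.nan)
            sem = np.sqrt(np.maximum(var, 0.0) / np.maximum(n, 1e-300))
        return mean, np.where(n > 1, sem, np.nan)

    mean_r, sem_r = _mean_sem(sum_r, sumsq_r, n_r)
    mean_l, sem_l = _mean_sem(sum_l, sumsq_l, n_l)
    return ReverseCorrelation(times=centers, right=mean_r, left=mean_l,
                              right_sem=sem_r, left_sem=sem_l,
                              n_right=n_r, n_left=n_l, bin_width=bin_width)


# ----------------------------------------------------------------------------
# inactivation bias summaries
# ----------------------------------------------------------------------------

def bias_summary(
    trials: TrialSet,
    warn_on_skip: bool = True,
) -> pd.DataFrame:
    """Per-session ipsilateral minus contralateral percent correct.

    Expects trials in the ipsi/contra frame (infusion side reads as 'L');
    ipsi trials are those whose correct side is ipsilateral.  Sessions
    missing either trial category are excluded.  Also reports the fraction
    of free-choice trials answered ipsilaterally where such trials exist.
    """
    import warnings as _warnings

    if trials.frame != "ipsi_contra":
        raise ValueError(
            "bias_summary expects an ipsi/contra-relabelled TrialSet "
            "(see pclicks.bias.relabel_ipsi_contra)"
        )
    rows = []
    for sid, sess in trials.by_session().items():
        ev = [
            t for t in sess
            if t.has_clicks and t.choice in ("L", "R") and t.correct_side in ("L", "R")
        ]
        ipsi = [t for t in ev if t.correct_side == "L"]
        contra = [t for t in ev if t.correct_side == "R"]
        if not ipsi or not contra:
            if warn_on_skip:
                _warnings.warn(f"session {sid}: missing ipsi or contra trials; skipped")
            continue
        pc_ipsi = float(np.mean([t.choice == t.correct_side for t in ipsi]))
        pc_contra = float(np.mean([t.choice == t.correct_side for t in contra]))
        fc = [t for t in sess if t.trial_type == "free_choice" and t.choice in ("L", "R")]
        rows.append({
            "session_id": sid,
            "n_ipsi": len(ipsi),
            "n_contra": len(contra),
            "pct_correct_ipsi": 100.0 * pc_ipsi,
            "pct_correct_contra": 100.0 * pc_contra,
            "bias_pct": 100.0 * (pc_ipsi - pc_contra),
            "free_choice_ipsi_frac": (
                float(np.mean([t.choice == "L" for t in fc])) if fc else np.nan
            ),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df.attrs["mean_bias_pct"] = float(df.bias_pct.mean())
        df.attrs["sem_bias_pct"] = (
            float(df.bias_pct.std(ddof=1) / np.sqrt(len(df))) if len(df) > 1 else np.nan
        )
    return df
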