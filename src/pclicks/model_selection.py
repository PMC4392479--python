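"""Information-criterion arithmetic and model-comparison tables.

``BIC = -2*LL + k*ln(n)`` and ``AIC = -2*LL + 2*k``; the model with the
lowest value of each criterion is flagged.  Tables are kept at full
precision internally and rounded to one decimal only for display/export.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["bic", "aic", "compare_models", "comparison_from_rows"]


def bic(ll: float, k: int, n: int) -> float:
    """Bayesian information criterion: ``-2*LL + k*ln(n)``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return -2.0 * ll + k * float(np.log(n))


def aic(ll: float, k: int) -> float:
    """Akaike information criterion: ``-2*LL + 2*k``."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return -2.0 * ll + 2.0 * k


def comparison_from_rows(
    names: Sequence[str],
    lls: Sequence[float],
    ks: Sequence[int],
    n: int,
) -> pd.DataFrame:
    """Model-comparison table from (name, LL, k) rows sharing one trial count.

    Columns: model, k, log_likelihood, BIC, AIC, lowest_bic, lowest_aic.
    Row order is preserved; ``attrs['criteria_agree']`` records whether BIC
    and AIC select the same model.
    """
    if not (len(names) == len(lls) == len(ks)):
        raise ValueError("names, lls and ks must have equal length")
    df = pd.DataFrame(
        {
            "model": list(names),
            "k": list(ks),
            "log_likelihood": [float(v) for v in lls],
        }
    )
    df["BIC"] = [bic(ll, k, n) for ll, k in zip(df.log_likelihood, df.k)]
    df["AIC"] = [aic(ll, k) for ll, k in zip(df.log_likelihood, df.k)]
    df["lowest_bic"] = df.BIC == df.BIC.min()
    df["lowest_aic"] = df.AIC == df.AIC.min()
    df.attrs["n"] = n
    df.attrs["criteria_agree"] = bool(
        df.index[df.lowest_bic][0] == df.index[df.lowest_aic][0]
    )
    return df


def compare_models(fits: Iterable, n: Optional[int] = None) -> pd.DataFrame:
    """Comparison table for a list of :class:`pclicks.inference.FitResult`.

    All fits must be on the same trial set; ``n`` defaults to the fits' common
    ``n_trials`` and a mismatch is an error.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n_trials for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are on different trial counts: {sorted(ns)}")
    n_fit = ns.pop()
    if n is None:
        n = n_fit
    elif n != n_fit:
        raise ValueError(f"n={n} disagrees with the fits' n_trials={n_fit}")
    return comparison_from_rows(
        [f.spec.name for f in fits],
        [f.log_likelihood for f in fits],
        [f.spec.k for f in fits],
        n,
    )


def format_table(df: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Display copy with LL/BIC/AIC rounded (tables report one decimal)."""
    out = df.copy()
    for col in ("log_likelihood", "BIC", "AIC"):
        out[col] = out[col].round(decimals)
    return out
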