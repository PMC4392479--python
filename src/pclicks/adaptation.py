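"""Sensory adaptation: deterministic per-click effective amplitudes.

Click impact is scaled by an adaptation state ``C`` shared by both ears.
Between clicks ``C`` relaxes towards its unadapted value 1 with time constant
``tau_phi``; immediately after each click it is multiplied by ``phi``
(depression for ``phi < 1``, facilitation for ``phi > 1``).  The click itself
is delivered at the pre-multiplication value of ``C``, so the first click of
every trial has unit amplitude.

The relaxation has the closed form ``C(t0 + dt) = 1 - (1 - C(t0)) * exp(-dt/tau_phi)``,
which is what :func:`adapt_click_amplitudes` uses — no ODE stepping.
Exactly simultaneous left/right clicks are processed deterministically
left-then-right and flagged so callers may choose to cancel them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AdaptedClickSeq", "adapt_click_amplitudes"]


@dataclass(frozen=True)
class AdaptedClickSeq:
    """Merged click train with per-click effective amplitudes.

    ``times`` are sorted seconds, ``sides`` are +1 for right / -1 for left,
    ``amplitudes`` are the adapted magnitudes ``C_k >= 0`` delivered with each
    click, and ``simultaneous`` flags clicks that share their time stamp with
    a click on the opposite side.
    """

    times: np.ndarray
    sides: np.ndarray
    amplitudes: np.ndarray
    simultaneous: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def adapt_click_amplitudes(
    left_clicks, right_clicks, phi: float, tau_phi: float
) -> AdaptedClickSeq:
    """Compute adapted amplitudes for a trial's merged click train.

    Parameters
    ----------
    left_clicks, right_clicks:
        Sorted click times in seconds.
    phi:
        Adaptation multiplier (>= 0); ``phi == 1`` disables adaptation.
    tau_phi:
        Recovery time constant in seconds (> 0).
    """
    if tau_phi <= 0:
        raise ValueError(f"tau_phi must be > 0, got {tau_phi}")
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    lt = np.asarray(left_clicks, dtype=float)
    rt = np.asarray(right_clicks, dtype=float)
    for name, t in (("left_clicks", lt), ("right_clicks", rt)):
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError(f"{name} must be sorted ascending")

    # Merge; ties between sides resolved left-then-right (stable and flagged).
    times = np.concatenate([lt, rt])
    sides = np.concatenate([-np.ones(lt.size), np.ones(rt.size)])
    order = np.lexsort((sides, times))
    times, sides = times[order], sides[order]

    simultaneous = np.zeros(times.size, dtype=bool)
    if times.size > 1:
        same_t = np.isclose(np.diff(times), 0.0, atol=0.0)
        opposite = sides[1:] != sides[:-1]
        pair = same_t & opposite
        simultaneous[1:] |= pair
        simultaneous[:-1] |= pair

    amplitudes = np.empty(times.size)
    c = 1.0
    t_prev = None
    for k in range(times.size):
        if t_prev is not None:
            dt = times[k] - t_prev
            c = 1.0 - (1.0 - c) * np.exp(-dt / tau_phi)
        amplitudes[k] = c  # delivered at the pre-update value
        c = phi * c
        t_prev = times[k]
    return AdaptedClickSeq(times=times, sides=sides, amplitudes=amplitudes,
                           simultaneous=simultaneous)
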