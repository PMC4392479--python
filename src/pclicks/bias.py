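"""Lateralized-bias model variants for unilateral-inactivation fits.

Four single-parameter mechanisms can each produce a side bias on top of a
fixed control fit of the nine accumulator parameters:

* ``post_cat`` — a fraction ``kappa_contra`` of contralateral decisions is
  reversed after categorization (vertically scales the psychometric curve);
* ``gain`` — contralateral clicks get a different impact magnitude
  (``gain_contra``, ipsilateral gain pinned at 1);
* ``shift`` — a constant added to the accumulator before categorization
  (equivalent to moving the decision boundary; horizontal psychometric shift);
* ``noise`` — contralateral clicks get a different noise variance
  (``sigma_s2_contra``).

Each variant frees exactly the contralateral parameter while the ipsilateral
counterpart stays at its control value.  The ``eight_param`` variant frees
all four bias parameters plus ``lam``, ``sigma_a2``, ``sigma_s2_ipsi`` and
``kappa_ipsi``, keeping initial noise, bounds and the two adaptation
parameters fixed at control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .params import AccumulatorParams, BiasExtension
from .trials import TrialSet

__all__ = [
    "VariantSpec",
    "VARIANT_NAMES",
    "make_variant",
    "full_model_spec",
    "variant_bias",
    "relabel_ipsi_contra",
    "DEFAULT_BOUNDS",
]

VARIANT_NAMES = ("post_cat", "gain", "shift", "noise", "eight_param")
_ALIASES = {
    "post_categorization": "post_cat",
    "input_gain": "gain",
    "accumulator_shift": "shift",
    "input_noise": "noise",
}

#: optimizer box bounds per parameter name
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "lam": (-40.0, 40.0),
    "sigma_a2": (0.0, 200.0),
    "sigma_s2": (0.0, 400.0),
    "sigma_i2": (0.0, 40.0),
    "B": (0.5, 40.0),
    "phi": (1e-3, 2.0),
    "tau_phi": (5e-3, 1.0),
    "sho": (-5.0, 5.0),
    "lapse": (0.0, 1.0),
    "kappa_ipsi": (0.0, 1.0),
    "kappa_contra": (0.0, 1.0),
    "gain_contra": (0.0, 5.0),
    "sigma_s2_ipsi": (0.0, 400.0),
    "sigma_s2_contra": (0.0, 400.0),
    "shift": (-10.0, 10.0),
}

_ACCUM_FIELDS = (
    "lam", "sigma_a2", "sigma_s2", "sigma_i2", "B", "phi", "tau_phi", "sho", "lapse",
)


@dataclass(frozen=True)
class VariantSpec:
    """A model parameterization: which parameters are free, and the control
    values everything else is pinned to."""

    name: str
    free_names: Tuple[str, ...]
    control_params: AccumulatorParams
    control_bias: BiasExtension = field(default_factory=BiasExtension)
    bounds: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.bounds:
            object.__setattr__(
                self,
                "bounds",
                tuple(DEFAULT_BOUNDS[n] for n in self.free_names),
            )
        if len(self.bounds) != len(self.free_names):
            raise ValueError("one (lo, hi) bound required per free parameter")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free_names)

    def build(self, theta: Sequence[float]) -> Tuple[AccumulatorParams, BiasExtension]:
        """Materialize (params, bias) from a free-parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ValueError(f"theta must have length {self.k}")
        p_kw = {}
        b_kw = {}
        for name, val in zip(self.free_names, theta):
            if name in _ACCUM_FIELDS:
                p_kw[name] = float(val)
            else:
                b_kw[name] = float(val)
        params = self.control_params.replace(**p_kw) if p_kw else self.control_params
        bias = self.control_bias.with_updates(**b_kw) if b_kw else self.control_bias
        return params, bias

    def control_values(self) -> np.ndarray:
        """Free-parameter vector at the control (unperturbed) point."""
        out = []
        for name in self.free_names:
            if name in _ACCUM_FIELDS:
                out.append(getattr(self.control_params, name))
            elif name == "shift":
                out.append(self.control_bias.shift)
            elif name.startswith("sigma_s2"):
                v = getattr(self.control_bias, name)
                out.append(self.control_params.sigma_s2 if v is None else v)
            else:
                out.append(getattr(self.control_bias, name))
        return np.asarray(out, dtype=float)


def make_variant(
    variant: str,
    control_params: AccumulatorParams,
    ipsi_side: str = "L",
    control_bias: Optional[BiasExtension] = None,
) -> VariantSpec:
    """Build the parameterization of one bias-mechanism variant.

    ``control_params`` is the 9-parameter fit to control data; the variant
    starts from it and frees only its own parameter(s).
    """
    variant = _ALIASES.get(variant, variant)
    if variant not in VARIANT_NAMES:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANT_NAMES}")
    if control_bias is None:
        control_bias = BiasExtension(ipsi_side=ipsi_side)
    elif control_bias.ipsi_side != ipsi_side:
        raise ValueError("control_bias.ipsi_side disagrees with ipsi_side")
    free: List[str]
    if variant == "post_cat":
        free = ["kappa_contra"]
    elif variant == "gain":
        free = ["gain_contra"]
    elif variant == "shift":
        free = ["shift"]
    elif variant == "noise":
        free = ["sigma_s2_contra"]
    else:  # eight_param: ipsilateral gain pinned to 1
        free = [
            "lam", "sigma_a2", "sigma_s2_ipsi", "shift",
            "kappa_ipsi", "sigma_s2_contra", "gain_contra", "kappa_contra",
        ]
    return VariantSpec(
        name=variant,
        free_names=tuple(free),
        control_params=control_params,
        control_bias=control_bias,
    )


def full_model_spec(
    control_params: AccumulatorParams,
    free: Sequence[str] = _ACCUM_FIELDS,
) -> VariantSpec:
    """The (up to) 9-parameter accumulator model as a VariantSpec."""
    bad = set(free) - set(_ACCUM_FIELDS)
    if bad:
        raise ValueError(f"unknown accumulator parameters: {sorted(bad)}")
    return VariantSpec(
        name="full", free_names=tuple(free), control_params=control_params
    )


def variant_bias(fit, variant: Optional[str] = None) -> float:
    """Bias of a fitted variant: contralateral minus ipsilateral parameter.

    For ``shift`` (which has no contra/ipsi pair) the fitted shift itself is
    returned.  ``fit`` is a :class:`pclicks.inference.FitResult`; ``variant``
    defaults to the variant the fit was made with.
    """
    spec: VariantSpec = fit.spec
    variant = _ALIASES.get(variant, variant) if variant else spec.name
    params, bias = spec.build(fit.theta)
    if variant == "shift":
        return float(bias.shift)
    if variant == "post_cat" or variant == "eight_param":
        return float(bias.kappa_contra - bias.kappa_ipsi)
    if variant == "gain":
        return float(bias.gain_contra - bias.gain_ipsi)
    if variant == "noise":
        shared = params.sigma_s2
        return float(
            bias.effective_sigma_s2(bias.contra_side, shared)
            - bias.effective_sigma_s2(bias.ipsi_side, shared)
        )
    if variant == "full":
        return 0.0
    raise ValueError(f"unknown variant {variant!r}")


def relabel_ipsi_contra(trials: TrialSet) -> TrialSet:
    """Remap left/right fields so the infusion side reads as 'L' (ipsi).

    Left-infusion trials are untouched; right-infusion trials are mirrored.
    Applying the relabelling twice restores the physical frame (involution),
    tracked by ``TrialSet.frame``.
    """
    new_trials = []
    for t in trials:
        if t.condition not in ("left_infusion", "right_infusion"):
            raise ValueError(
                f"trial {t.trial_id}: condition {t.condition!r} has no infusion side"
            )
        new_trials.append(t.mirrored() if t.condition == "right_infusion" else t)
    frame = "ipsi_contra" if trials.frame == "lr" else "lr"
    return TrialSet(new_trials, mixture=dict(trials.mixture), seed=trials.seed,
                    frame=frame)
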