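"""Parameter containers for the bounded-accumulator choice model.

The core model maps the click times of a single trial onto a probability of a
rightward choice through a one-dimensional stochastic accumulator ``a``:

* ``a(0) ~ N(0, sigma_i2)``;
* between clicks ``da = lambda*a dt + sigma_a dW`` (leaky for ``lambda < 0``,
  unstable for ``lambda > 0``; the memory time constant is ``tau = 1/lambda``);
* each click kicks ``a`` by ``+/- C_k * eta`` where ``C_k`` is the adapted
  click amplitude and ``eta ~ N(1, sigma_s2)`` is per-click multiplicative
  noise (right clicks kick up, left clicks kick down);
* ``a`` sticks (freezes) on hitting the absorbing bounds at ``+/-B``;
* at stimulus end the model answers Right iff ``a > sho`` (the decision
  boundary), a ``lapse`` fraction of trials answer at random instead.

:class:`BiasExtension` adds the lateralized mechanisms used to model
unilateral inactivations: per-side input gains, per-side click-noise
variances, an accumulator shift applied before categorization, and
post-categorization reversal probabilities ``kappa_L``/``kappa_R``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = ["AccumulatorParams", "BiasExtension"]


@dataclass(frozen=True)
class AccumulatorParams:
    """The nine free parameters of the accumulator model.

    Attributes
    ----------
    lam:
        Drift rate of the accumulator (1/s). ``tau = 1/lam`` is the
        accumulation time constant; ``lam = 0`` is a perfect integrator.
    sigma_a2:
        Diffusion variance rate of the accumulator (units^2/s).
    sigma_s2:
        Variance of the multiplicative per-click noise ``eta ~ N(1, sigma_s2)``.
    sigma_i2:
        Variance of the initial value ``a(0)`` (units^2).
    B:
        Height of the sticky absorbing bounds (> 0).
    phi:
        Adaptation multiplier applied to the click magnitude immediately after
        each click; ``phi < 1`` is depression, ``phi > 1`` facilitation.
    tau_phi:
        Recovery time constant of adaptation towards 1 (s, > 0).
    sho:
        Decision boundary compared against ``a`` at stimulus end
        (Right iff ``a > sho``).
    lapse:
        Fraction of trials with a stimulus-independent random response.
    """

    lam: float = 0.0
    sigma_a2: float = 0.0
    sigma_s2: float = 0.0
    sigma_i2: float = 0.0
    B: float = 16.0
    phi: float = 1.0
    tau_phi: float = 0.1
    sho: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise ValueError(f"B must be > 0, got {self.B}")
        if not self.tau_phi > 0:
            raise ValueError(f"tau_phi must be > 0, got {self.tau_phi}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")
        for name in ("sigma_a2", "sigma_s2", "sigma_i2"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")

    @property
    def tau(self) -> float:
        """Accumulation time constant 1/lam (inf for a perfect integrator)."""
        return float("inf") if self.lam == 0 else 1.0 / self.lam

    def replace(self, **kwargs) -> "AccumulatorParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BiasExtension:
    """Lateralized extension parameters, symmetric (no-op) by default.

    ``kappa_L``/``kappa_R`` are the fractions of already-made Left/Right
    decisions reversed to the other side (post-categorization bias).
    ``gain_L``/``gain_R`` multiply the impact of left/right clicks.
    ``sigma_s2_L``/``sigma_s2_R`` override the shared click-noise variance per
    side (``None`` falls back to ``AccumulatorParams.sigma_s2``).  ``shift``
    is added to the accumulator before categorization (equivalent to lowering
    the decision boundary by the same amount).  ``ipsi_side`` maps the
    ipsi/contra vocabulary of unilateral-inactivation analyses onto L/R.
    """

    kappa_L: float = 0.0
    kappa_R: float = 0.0
    gain_L: float = 1.0
    gain_R: float = 1.0
    sigma_s2_L: Optional[float] = None
    sigma_s2_R: Optional[float] = None
    shift: float = 0.0
    ipsi_side: str = "L"

    def __post_init__(self) -> None:
        for name in ("kappa_L", "kappa_R"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gain_L", "gain_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma_s2_L", "sigma_s2_R"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0 or None")
        if self.ipsi_side not in ("L", "R"):
            raise ValueError("ipsi_side must be 'L' or 'R'")

    # -- ipsi/contra views ---------------------------------------------------
    @property
    def contra_side(self) -> str:
        return "R" if self.ipsi_side == "L" else "L"

    def _get(self, prefix: str, side: str):
        return getattr(self, f"{prefix}_{side}")

    @property
    def kappa_ipsi(self) -> float:
        return self._get("kappa", self.ipsi_side)

    @property
    def kappa_contra(self) -> float:
        return self._get("kappa", self.contra_side)

    @property
    def gain_ipsi(self) -> float:
        return self._get("gain", self.ipsi_side)

    @property
    def gain_contra(self) -> float:
        return self._get("gain", self.contra_side)

    @property
    def sigma_s2_ipsi(self) -> Optional[float]:
        return self._get("sigma_s2", self.ipsi_side)

    @property
    def sigma_s2_contra(self) -> Optional[float]:
        return self._get("sigma_s2", self.contra_side)

    @classmethod
    def from_ipsi_contra(
        cls,
        ipsi_side: str = "L",
        kappa_ipsi: float = 0.0,
        kappa_contra: float = 0.0,
        gain_ipsi: float = 1.0,
        gain_contra: float = 1.0,
        sigma_s2_ipsi: Optional[float] = None,
        sigma_s2_contra: Optional[float] = None,
        shift: float = 0.0,
    ) -> "BiasExtension":
        """Build an extension from ipsi/contra-labelled parameters."""
        if ipsi_side not in ("L", "R"):
            raise ValueError("ipsi_side must be 'L' or 'R'")
        contra = "R" if ipsi_side == "L" else "L"
        kw = {
            f"kappa_{ipsi_side}": kappa_ipsi,
            f"kappa_{contra}": kappa_contra,
            f"gain_{ipsi_side}": gain_ipsi,
            f"gain_{contra}": gain_contra,
            f"sigma_s2_{ipsi_side}": sigma_s2_ipsi,
            f"sigma_s2_{contra}": sigma_s2_contra,
        }
        return cls(shift=shift, ipsi_side=ipsi_side, **kw)

    def with_updates(self, **kwargs) -> "BiasExtension":
        """Copy with ipsi/contra- or L/R-named fields replaced."""
        lr: dict = {}
        for key, val in kwargs.items():
            if key.endswith("_ipsi"):
                lr[key[: -len("_ipsi")] + f"_{self.ipsi_side}"] = val
            elif key.endswith("_contra"):
                lr[key[: -len("_contra")] + f"_{self.contra_side}"] = val
            else:
                lr[key] = val
        return replace(self, **lr)

    def effective_sigma_s2(self, side: str, shared: float) -> float:
        v = self._get("sigma_s2", side)
        return shared if v is None else v
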