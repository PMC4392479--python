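"""Trial containers for the Poisson Clicks task.

A :class:`Trial` is one behavioral trial: two click trains (times in seconds
from stimulus onset), the stimulus duration, the trial type, the generative
click rates, and the subject's choice plus condition labels.  A
:class:`TrialSet` is an ordered collection of trials with bookkeeping about
how it was generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np

__all__ = ["Trial", "TrialSet", "TRIAL_TYPES", "CONDITIONS"]

TRIAL_TYPES = ("accumulation", "single_sided", "side_led", "free_choice")
CONDITIONS = ("control", "left_infusion", "right_infusion", "bilateral", "combo")
_CHOICES = ("L", "R", "none")
_SIDES = ("L", "R", "either")


@dataclass(frozen=True)
class Trial:
    trial_id: int
    duration: float
    left_clicks: tuple = ()
    right_clicks: tuple = ()
    trial_type: str = "accumulation"
    generative_rate_left: float = 0.0
    generative_rate_right: float = 0.0
    correct_side: str = "either"
    choice: str = "none"
    rat_id: str = "synth"
    session_id: str = "S000"
    condition: str = "control"
    region: str = ""
    dose: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.choice not in _CHOICES:
            raise ValueError(f"unknown choice {self.choice!r}")
        if self.correct_side not in _SIDES:
            raise ValueError(f"unknown correct_side {self.correct_side!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        object.__setattr__(self, "left_clicks", tuple(self.left_clicks))
        object.__setattr__(self, "right_clicks", tuple(self.right_clicks))
        for name in ("left_clicks", "right_clicks"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.size:
                if np.any(np.diff(t) < 0):
                    raise ValueError(f"{name} must be sorted ascending")
                if t[0] < 0 or t[-1] > self.duration:
                    raise ValueError(
                        f"{name} must lie within [0, duration={self.duration}]"
                    )

    @property
    def n_left(self) -> int:
        return len(self.left_clicks)

    @property
    def n_right(self) -> int:
        return len(self.right_clicks)

    @property
    def click_difference(self) -> int:
        """#right - #left clicks, the standard difficulty axis."""
        return self.n_right - self.n_left

    @property
    def has_clicks(self) -> bool:
        return self.trial_type in ("accumulation", "single_sided")

    def mirrored(self) -> "Trial":
        """Swap the left/right roles of clicks, rates, choice and correct side."""
        flip = {"L": "R", "R": "L"}
        return replace(
            self,
            left_clicks=self.right_clicks,
            right_clicks=self.left_clicks,
            generative_rate_left=self.generative_rate_right,
            generative_rate_right=self.generative_rate_left,
            correct_side=flip.get(self.correct_side, self.correct_side),
            choice=flip.get(self.choice, self.choice),
        )

    def with_choice(self, choice: str) -> "Trial":
        return replace(self, choice=choice)


@dataclass
class TrialSet:
    """Ordered collection of trials.

    ``frame`` records whether the left/right fields are in the physical
    ("lr") frame or have been remapped so that the infusion side reads as
    "L" (the "ipsi_contra" frame used by unilateral-inactivation fits).
    """

    trials: List[Trial] = field(default_factory=list)
    mixture: Dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None
    frame: str = "lr"

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("trial_ids must be unique within a TrialSet")
        if self.mixture:
            total = sum(self.mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture proportions must sum to 1, got {total}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return TrialSet(self.trials[i], dict(self.mixture), self.seed, self.frame)
        return self.trials[i]

    def subset(self, indices: Sequence[int]) -> "TrialSet":
        return TrialSet(
            [self.trials[i] for i in indices], dict(self.mixture), self.seed, self.frame
        )

    def filter(self, pred) -> "TrialSet":
        return TrialSet(
            [t for t in self.trials if pred(t)], dict(self.mixture), self.seed, self.frame
        )

    def evidence_trials(self) -> "TrialSet":
        """Trials that carry clicks (accumulation + single-sided)."""
        return self.filter(lambda t: t.has_clicks)

    def sessions(self) -> List[str]:
        seen: List[str] = []
        for t in self.trials:
            if t.session_id not in seen:
                seen.append(t.session_id)
        return seen

    def by_session(self) -> Dict[str, "TrialSet"]:
        out: Dict[str, TrialSet] = {}
        for sid in self.sessions():
            out[sid] = self.filter(lambda t, s=sid: t.session_id == s)
        return out

    def first_n_per_session(self, n: int = 250) -> "TrialSet":
        """Keep at most the first ``n`` trials of each session (fit protocol)."""
        kept: List[Trial] = []
        counts: Dict[str, int] = {}
        for t in self.trials:
            c = counts.get(t.session_id, 0)
            if c < n:
                kept.append(t)
                counts[t.session_id] = c + 1
        return TrialSet(kept, dict(self.mixture), self.seed, self.frame)

    def realized_mixture(self) -> Dict[str, float]:
        n = len(self.trials)
        out: Dict[str, float] = {}
        for t in self.trials:
            out[t.trial_type] = out.get(t.trial_type, 0) + 1
        return {k: v / n for k, v in out.items()} if n else out
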