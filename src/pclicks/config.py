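"""Run configuration: seeds, grid tolerances, optimizer and generator settings.

A :class:`RunConfig` mirrors the CLI flags and serializes to YAML, so that a
run can be reproduced from its logged configuration alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 0
    n_trials: int = 1000
    grid_dx: Optional[float] = None  # None -> min(B/200, 0.05)
    mixture: Dict[str, float] = field(
        default_factory=lambda: {"accumulation": 1.0}
    )
    duration_range: Tuple[float, float] = (0.1, 1.0)
    n_difficulty_pairs: int = 8
    single_sided_fraction: float = 0.0
    variant: str = "post_cat"
    n_starts: int = 5
    n_boot: int = 300
    n_chains: int = 4
    n_samples: int = 10_000
    burnin: int = 100
    thin: int = 4
    revcorr_bin_width: float = 0.05
    out_dir: str = "pclicks_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["duration_range"] = list(self.duration_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "duration_range" in d:
            d["duration_range"] = tuple(d["duration_range"])
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
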