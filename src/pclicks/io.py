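"""Trial-table readers/writers and run artifacts.

Trial tables are comma-separated UTF-8 text with one row per trial; the
click-time list fields are semicolon-delimited seconds printed at nanosecond
(9-decimal) precision, which round-trips losslessly because all generators
quantize click times to that resolution.  Every artifact written by the CLI
carries a JSON sidecar log with the seed, package version and a hash of the
resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .trials import Trial, TrialSet

__all__ = ["write_trials", "read_trials", "write_run_log"]

_COLUMNS = [
    "rat_id", "session_id", "trial_id", "trial_type", "duration_s",
    "left_clicks", "right_clicks", "generative_rate_left",
    "generative_rate_right", "choice", "correct_side", "condition",
    "region", "dose_ng",
]


def _fmt_clicks(clicks) -> str:
    return ";".join(f"{t:.9f}" for t in clicks)


def _parse_clicks(s, row: int, col: str):
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return ()
    try:
        times = tuple(float(x) for x in str(s).split(";"))
    except ValueError as err:
        raise ValueError(f"row {row}, column {col}: unparsable click list") from err
    for a, b in zip(times, times[1:]):
        if b < a:
            raise ValueError(f"row {row}, column {col}: click times not sorted")
    return times


def to_frame(trials: TrialSet) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "rat_id": t.rat_id,
            "session_id": t.session_id,
            "trial_id": t.trial_id,
            "trial_type": t.trial_type,
            "duration_s": f"{t.duration:.9f}",
            "left_clicks": _fmt_clicks(t.left_clicks),
            "right_clicks": _fmt_clicks(t.right_clicks),
            "generative_rate_left": t.generative_rate_left,
            "generative_rate_right": t.generative_rate_right,
            "choice": t.choice,
            "correct_side": t.correct_side,
            "condition": t.condition,
            "region": t.region,
            "dose_ng": t.dose,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_trials(trials: TrialSet, path) -> None:
    """Write a trial table as CSV (UTF-8, '.' decimal, ';' list delimiter)."""
    to_frame(trials).to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> TrialSet:
    """Read and validate a trial table; raises with row/column context."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    trials = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            duration = float(row.duration_s)
            trials.append(Trial(
                trial_id=int(row.trial_id),
                rat_id=row.rat_id,
                session_id=row.session_id,
                trial_type=row.trial_type,
                duration=duration,
                left_clicks=_parse_clicks(row.left_clicks, i, "left_clicks"),
                right_clicks=_parse_clicks(row.right_clicks, i, "right_clicks"),
                generative_rate_left=float(row.generative_rate_left),
                generative_rate_right=float(row.generative_rate_right),
                choice=row.choice,
                correct_side=row.correct_side,
                condition=row.condition,
                region=row.region,
                dose=float(row.dose_ng) if row.dose_ng != "" else 0.0,
            ))
        except ValueError as err:
            raise ValueError(f"{path}: row {i}: {err}") from err
    return TrialSet(trials)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_log(path, seed: Optional[int], config: dict, outputs=()) -> None:
    """JSON sidecar recording seed, version and resolved configuration."""
    from . import __version__

    log = {
        "seed": seed,
        "version": __version__,
        "config_hash": config_hash(config),
        "config": config,
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(log, indent=2, default=str))
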