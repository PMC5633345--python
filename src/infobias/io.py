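"""Delimited-text readers/writers for the pipeline's interchange files.

All files are plain CSV with a mandatory header row:

* schedule: ``block,trial,p_win_A,p_loss_A,win_side,loss_side``
* trials:   ``block,trial,choice,win_side,loss_side[,earnings_delta]``
* fits:     ``participant,model,block,<param columns>,loglik,n_trials,bic``
* pupil trace: ``time_s,pupil,valid``; markers:
  ``block,trial,event_sample,win_obtained,loss_obtained``
* binned differences: ``participant,block,valence,bin,difference`` and
  ``participant,block,valence,mean6s``
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .fitting import ModelFit
from .schedule import SessionSchedule

__all__ = [
    "write_schedule",
    "read_schedule",
    "write_trials",
    "read_trials",
    "write_fits",
    "read_fits",
    "write_pupil",
    "read_pupil",
]

TRIAL_COLUMNS = ["block", "trial", "choice", "win_side", "loss_side"]


def write_schedule(schedule: SessionSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"block", "trial", "p_win_A", "p_loss_A", "win_side", "loss_side"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns {sorted(missing)}")
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns {sorted(missing)}")
    return df


def write_fits(fits: ModelFit | Iterable[ModelFit], path) -> None:
    if isinstance(fits, ModelFit):
        fits = [fits]
    pd.concat([f.to_frame() for f in fits], ignore_index=True).to_csv(
        path, index=False
    )


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pupil(trace: pd.DataFrame, markers: pd.DataFrame, trace_path, marker_path) -> None:
    trace.to_csv(trace_path, index=False)
    markers.to_csv(marker_path, index=False)


def read_pupil(trace_path, marker_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    trace = pd.read_csv(trace_path)
    markers = pd.read_csv(marker_path)
    for df, req in (
        (trace, {"time_s", "pupil", "valid"}),
        (markers, {"block", "trial", "event_sample", "win_obtained", "loss_obtained"}),
    ):
        missing = req - set(df.columns)
        if missing:
            raise ValueError(f"pupil file missing columns {sorted(missing)}")
    return trace, markers
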