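"""Trial-file input/output.

One delimited text file per trial with header
``time,f_index,f_middle,f_ring,f_little`` (time in s, forces in N), laid out
as ``<subject>/<mode>_<uncertainty>/trial<k>.csv`` under a study root.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from audiomotor.feedback import ConditionSpec
from audiomotor.hvd import TrialRecording

FINGER_COLUMNS = ("f_index", "f_middle", "f_ring", "f_little")
_TRIAL_RE = re.compile(r"trial(\d+)\.csv$")


def condition_dirname(mode: str, uncertainty: str) -> str:
    return f"{mode}_{uncertainty}"


def write_trial(trial: TrialRecording, path: str | Path, float_fmt: str = "%.6f") -> Path:
    """Write one trial as a CSV file; returns the path written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if trial.n_fingers == len(FINGER_COLUMNS):
        cols = list(FINGER_COLUMNS)
    else:
        cols = [f"f{j}" for j in range(trial.n_fingers)]
    frame = pd.DataFrame(trial.forces, columns=cols)
    frame.insert(0, "time", trial.times)
    frame.to_csv(path, index=False, float_format=float_fmt)
    return path


def write_trial_set(
    trials: list[TrialRecording],
    root: str | Path,
    subject: str,
    mode: str,
    uncertainty: str,
) -> list[Path]:
    """Write a trial set under ``<root>/<subject>/<mode>_<uncertainty>/``."""
    cond_dir = Path(root) / subject / condition_dirname(mode, uncertainty)
    return [
        write_trial(trial, cond_dir / f"trial{k + 1}.csv")
        for k, trial in enumerate(trials)
    ]


def read_trial(
    path: str | Path,
    subject_id: str | None = None,
    condition: ConditionSpec | None = None,
) -> TrialRecording:
    """Read one trial CSV; the sampling rate is inferred from the time column."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"trial file not found: {path}")
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus force columns")
    time = frame.iloc[:, 0].to_numpy(dtype=float)
    forces = frame.iloc[:, 1:].to_numpy(dtype=float)
    dt = np.median(np.diff(time))
    if dt <= 0:
        raise ValueError(f"{path}: time column must be strictly increasing")
    return TrialRecording(
        forces=forces,
        sample_rate=1.0 / dt,
        t0=float(time[0]),
        subject_id=subject_id,
        condition=condition,
    )


def read_condition_dir(
    directory: str | Path,
    subject_id: str | None = None,
    condition: ConditionSpec | None = None,
) -> list[TrialRecording]:
    """Read all ``trial<k>.csv`` files of a condition directory, in trial order."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"condition directory not found: {directory}")
    entries = []
    for path in directory.iterdir():
        match = _TRIAL_RE.fullmatch(path.name)
        if match:
            entries.append((int(match.group(1)), path))
    if not entries:
        raise FileNotFoundError(f"no trial<k>.csv files in {directory}")
    return [
        read_trial(path, subject_id=subject_id, condition=condition)
        for _, path in sorted(entries)
    ]
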