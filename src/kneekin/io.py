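"""Trial CSV reading and writing.

The dialect is a package convention (the source measurements were exported
by in-house software with no public format): one row per time point with
columns ``participant, activity, time_index`` followed by the 12 canonical
parameter names, plus a per-participant ``bicondylar_width`` column (mm).
UTF-8, header required.  If the width column is absent the cohort
reference width (81.7 mm) is assumed.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import KinematicTrial
from .params import ALL_PARAMETERS, REFERENCE_BICONDYLAR_WIDTH_MM

GROUP_COLUMNS = ("participant", "activity", "time_index")
WIDTH_COLUMN = "bicondylar_width"


class TrialParseError(ValueError):
    """Raised when a trial CSV fails structural validation."""


def read_trials(path, *, sample_rate: float | None = None) -> list[KinematicTrial]:
    """Read a trial CSV into a list of :class:`KinematicTrial`.

    Trials are grouped by (participant, activity) in order of first
    appearance and sorted by ``time_index`` within a trial.  Pass
    ``sample_rate`` for raw (not yet time-normalized) recordings;
    the default ``None`` marks trials as on the normalized-time grid.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in (*GROUP_COLUMNS, *ALL_PARAMETERS) if c not in frame.columns]
    if missing:
        raise TrialParseError(f"{path}: missing column(s) {missing}")
    values = frame.loc[:, list(ALL_PARAMETERS)]
    bad = ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise TrialParseError(
            f"{path}: non-finite value in row {r + 2} (column {ALL_PARAMETERS[c]!r})"
        )
    dup = frame.duplicated(subset=list(GROUP_COLUMNS), keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = tuple(frame.loc[row, list(GROUP_COLUMNS)])
        raise TrialParseError(
            f"{path}: duplicate (participant, activity, time_index) = {key} at row {row + 2}"
        )
    if WIDTH_COLUMN not in frame.columns:
        frame = frame.assign(**{WIDTH_COLUMN: REFERENCE_BICONDYLAR_WIDTH_MM})

    trials: list[KinematicTrial] = []
    seen: list[tuple] = []
    for key, _ in frame.groupby(["participant", "activity"], sort=False):
        seen.append(key)
    for participant, activity in seen:
        block = frame[(frame["participant"] == participant) & (frame["activity"] == activity)]
        block = block.sort_values("time_index")
        widths = block[WIDTH_COLUMN].unique()
        if len(widths) != 1:
            raise TrialParseError(
                f"{path}: inconsistent bicondylar_width for ({participant}, {activity})"
            )
        trials.append(
            KinematicTrial(
                participant_id=str(participant),
                activity=str(activity),
                samples=block.loc[:, list(ALL_PARAMETERS)].reset_index(drop=True),
                bicondylar_width=float(widths[0]),
                sample_rate=sample_rate,
            )
        )
    return trials


def write_trials(trials: Iterable[KinematicTrial] | Sequence[KinematicTrial], path) -> None:
    """Write trials to the CSV dialect read by :func:`read_trials`."""
    frames = []
    for trial in trials:
        block = trial.samples.copy()
        block.insert(0, "time_index", np.arange(len(block)))
        block.insert(0, "activity", trial.activity)
        block.insert(0, "participant", trial.participant_id)
        block[WIDTH_COLUMN] = trial.bicondylar_width
        frames.append(block)
    if not frames:
        raise ValueError("no trials to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
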