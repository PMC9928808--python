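"""Core domain containers: parameter vectors, trials, reports.

Time-series data are carried as pandas DataFrames with the canonical
12-parameter column layout (see :mod:`kneekin.params`); the thin dataclass
wrappers here add the metadata (participant, activity, bicondylar width,
sampling) and the validation the raw frames cannot express.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ACTIVITIES, ALL_PARAMETERS, PF_PARAMETERS, TF_PARAMETERS


@dataclass(frozen=True)
class JointParameterVector:
    """One observation of the 12 knee kinematic parameters.

    Six tibiofemoral parameters followed by six patellofemoral parameters;
    translations in millimetres, rotations in degrees.
    """

    tf_lateral_shift: float
    tf_anterior_drawer: float
    tf_joint_distraction: float
    tf_flexion: float
    tf_abduction: float
    tf_external_rotation: float
    pf_lateral_shift: float
    pf_anterior_translation: float
    pf_superior_translation: float
    pf_flexion: float
    pf_lateral_rotation: float
    pf_lateral_tilt: float

    def __post_init__(self):
        for name in ALL_PARAMETERS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite value {v!r} for parameter {name}")

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "JointParameterVector":
        missing = [n for n in ALL_PARAMETERS if n not in values]
        if missing:
            raise ValueError(f"missing parameter value(s): {missing}")
        return cls(**{n: float(values[n]) for n in ALL_PARAMETERS})

    def to_array(self) -> np.ndarray:
        """Values in canonical order as a length-12 float array."""
        return np.array([getattr(self, n) for n in ALL_PARAMETERS], dtype=float)

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_array(), index=list(ALL_PARAMETERS))

    def __getitem__(self, name: str) -> float:
        if name not in ALL_PARAMETERS:
            raise KeyError(name)
        return getattr(self, name)


def _validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ALL_PARAMETERS if c not in samples.columns]
    if missing:
        raise ValueError(f"trial samples missing column(s): {missing}")
    samples = samples.loc[:, list(ALL_PARAMETERS)].reset_index(drop=True)
    if not np.isfinite(samples.to_numpy()).all():
        raise ValueError("trial samples contain non-finite values")
    return samples.astype(float)


@dataclass
class KinematicTrial:
    """One participant x activity time series of knee kinematics.

    Parameters
    ----------
    participant_id : str
        Participant label (e.g. ``"P1"``).
    activity : str
        One of the six functional activities in :data:`kneekin.params.ACTIVITIES`.
    samples : pandas.DataFrame
        One row per time point, canonical 12-parameter columns.
    bicondylar_width : float
        Femoral bicondylar width of the participant in mm (> 0).
    sample_rate : float or None
        Sampling rate in Hz for raw trials; ``None`` marks a trial already
        resampled onto the normalized-time grid [0, 1].
    """

    participant_id: str
    activity: str
    samples: pd.DataFrame
    bicondylar_width: float
    sample_rate: float | None = None

    def __post_init__(self):
        if self.activity not in ACTIVITIES:
            raise ValueError(
                f"unknown activity {self.activity!r}; expected one of {list(ACTIVITIES)}"
            )
        if not self.bicondylar_width > 0:
            raise ValueError(f"bicondylar_width must be > 0, got {self.bicondylar_width}")
        if self.sample_rate is not None and not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0 or None, got {self.sample_rate}")
        self.samples = _validate_samples(self.samples)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_time_normalized(self) -> bool:
        return self.sample_rate is None

    def with_samples(self, samples: pd.DataFrame, *, sample_rate: float | None = "keep"):
        """Copy of the trial with replaced samples (and optionally sampling)."""
        rate = self.sample_rate if sample_rate == "keep" else sample_rate
        return KinematicTrial(
            participant_id=self.participant_id,
            activity=self.activity,
            samples=samples,
            bicondylar_width=self.bicondylar_width,
            sample_rate=rate,
        )

    def vectors(self) -> list[JointParameterVector]:
        return [
            JointParameterVector(*row)
            for row in self.samples.to_numpy()
        ]


def pool_observations(trials: Iterable[KinematicTrial]) -> pd.DataFrame:
    """Pool trials into one observation table.

    Returns a DataFrame with grouping columns ``participant``, ``activity``,
    ``time_index`` followed by the 12 canonical parameter columns; one row
    per time point, trials stacked in the given order.
    """
    frames = []
    for trial in trials:
        block = trial.samples.copy()
        block.insert(0, "time_index", np.arange(len(block)))
        block.insert(0, "activity", trial.activity)
        block.insert(0, "participant", trial.participant_id)
        frames.append(block)
    if not frames:
        raise ValueError("no trials to pool")
    return pd.concat(frames, ignore_index=True)


@dataclass
class ResidualReport:
    """Training-residual summary of one fitted or evaluated model.

    ``rmsr_tfj`` pools the squared residuals of the (6 - n) predicted TF
    parameters; ``rmsr_pfj`` pools all six PF parameters.  Rotations (deg)
    and translations (mm) are weighted equally, so pooled values carry the
    combined deg|mm unit.  Input parameters appear with an RMSE of zero by
    construction.
    """

    per_parameter_rmse: dict[str, float]
    rmsr_tfj: float
    rmsr_pfj: float
    n_inputs: int
    n_observations: int

    def __post_init__(self):
        if self.rmsr_tfj < 0 or self.rmsr_pfj < 0:
            raise ValueError("RMS residuals must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = [(name, self.per_parameter_rmse[name]) for name in ALL_PARAMETERS]
        rows.append(("rmsr_tfj", self.rmsr_tfj))
        rows.append(("rmsr_pfj", self.rmsr_pfj))
        return pd.DataFrame(rows, columns=["parameter", "rmse"]).set_index("parameter")


@dataclass
class CVReport:
    """Leave-one-participant-out cross-validation error table.

    Two panels (TF and PF), each with one row per joint parameter plus a
    pooled ``All`` row, one column per left-out participant plus an
    arithmetic ``Mean`` column.  The ``All`` row pools squared errors over
    the *predicted* parameters only — model inputs, whose error is zero by
    construction, are excluded.
    """

    tf_table: pd.DataFrame
    pf_table: pd.DataFrame
    input_names: tuple[str, ...]
    order: int
    fold_errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        tf = self.tf_table.copy()
        pf = self.pf_table.copy()
        tf.index = pd.MultiIndex.from_product([["tibiofemoral"], tf.index])
        pf.index = pd.MultiIndex.from_product([["patellofemoral"], pf.index])
        out = pd.concat([tf, pf])
        out.index.names = ["joint", "parameter"]
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_json_dict(self) -> dict:
        return {
            "input_names": list(self.input_names),
            "order": self.order,
            "tibiofemoral": self.tf_table.to_dict(),
            "patellofemoral": self.pf_table.to_dict(),
            "fold_errors": dict(self.fold_errors),
        }


@dataclass
class ModelSelectionResult:
    """Residuals of candidate input sets (and/or polynomial orders).

    ``table`` has one row per candidate with columns ``inputs`` (comma-joined
    names), ``n_inputs``, ``order``, ``rmsr_tfj``, ``rmsr_pfj``; sorted by
    ``rmsr_tfj`` ascending (the ranking criterion for input selection).
    """

    table: pd.DataFrame

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# re-export convenience
__all__ = [
    "JointParameterVector",
    "KinematicTrial",
    "ResidualReport",
    "CVReport",
    "ModelSelectionResult",
    "pool_observations",
    "TF_PARAMETERS",
    "PF_PARAMETERS",
    "ALL_PARAMETERS",
]
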