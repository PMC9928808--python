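"""Signal conditioning for kinematic trials.

The chain applied to a raw recording is: zero-phase low-pass Butterworth
filtering on the true-time grid, resampling onto a uniform normalized-time
grid (default 201 points over [0, 1]), then scaling of the six translation
channels by the ratio of a reference bicondylar width to the participant's
own width so translations are comparable across knee sizes.  Rotations are
never rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .datamodel import KinematicTrial
from .params import REFERENCE_BICONDYLAR_WIDTH_MM, TRANSLATION_PARAMETERS


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults mirror typical gait-lab practice for biplane-X-ray knee
    kinematics: 4th-order Butterworth at 10 Hz on 200 Hz recordings,
    201-point normalized-time grid, 81.7 mm reference bicondylar width.
    ``zero_phase`` selects forward–backward filtering (no phase lag);
    set it False for a causal single pass.
    """

    filter_order: int = 4
    cutoff_hz: float = 10.0
    sample_rate_hz: float = 200.0
    n_points: int = 201
    reference_width_mm: float = REFERENCE_BICONDYLAR_WIDTH_MM
    zero_phase: bool = True

    def __post_init__(self):
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not 0 < self.cutoff_hz < self.sample_rate_hz / 2:
            raise ValueError(
                f"cutoff ({self.cutoff_hz} Hz) must lie in (0, Nyquist = "
                f"{self.sample_rate_hz / 2} Hz)"
            )
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.reference_width_mm <= 0:
            raise ValueError("reference_width_mm must be > 0")


def lowpass_filter(series: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter along axis 0.

    Edge handling: reflective ("even") padding of length 3 x filter order
    before the forward–backward pass.  DC gain is exactly 1, so constant
    signals pass through unchanged.
    """
    x = np.asarray(series, dtype=float)
    padlen = 3 * config.filter_order
    if x.shape[0] <= padlen:
        raise ValueError(
            f"series of length {x.shape[0]} too short to filter; "
            f"need more than {padlen} samples (3 x filter order)"
        )
    b, a = signal.butter(config.filter_order, config.cutoff_hz, fs=config.sample_rate_hz)
    if config.zero_phase:
        return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)
    return signal.lfilter(b, a, x, axis=0)


def filter_trial(trial: KinematicTrial, config: PreprocessConfig) -> KinematicTrial:
    """Low-pass filter every channel of a raw trial."""
    if trial.sample_rate is None:
        raise ValueError("trial is already time-normalized; filter raw trials")
    cfg = replace(config, sample_rate_hz=trial.sample_rate)
    filtered = lowpass_filter(trial.samples.to_numpy(), cfg)
    return trial.with_samples(pd.DataFrame(filtered, columns=trial.samples.columns))


def resample_series(values: np.ndarray, n_points: int) -> np.ndarray:
    """Resample columns of ``values`` onto a uniform [0, 1] grid.

    Cubic-spline interpolation on the uniform source grid; linear for
    records shorter than 4 samples.  End points are grid points of both
    grids, so first and last samples are preserved exactly, and affine-in-
    time signals are reproduced exactly.
    """
    x = np.asarray(values, dtype=float)
    n_in = x.shape[0]
    if n_in < 2:
        raise ValueError("cannot resample a series with fewer than 2 samples")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if n_points == n_in:
        return x.copy()
    t_in = np.linspace(0.0, 1.0, n_in)
    t_out = np.linspace(0.0, 1.0, n_points)
    if n_in < 4:
        f = interpolate.interp1d(t_in, x, axis=0, kind="linear")
        return f(t_out)
    spline = interpolate.CubicSpline(t_in, x, axis=0)
    out = spline(t_out)
    out[0] = x[0]
    out[-1] = x[-1]
    return out


def time_normalize(trial: KinematicTrial, n_points: int = 201) -> KinematicTrial:
    """Resample a trial to ``n_points`` samples on normalized time [0, 1]."""
    if trial.n_samples < 2:
        raise ValueError("cannot time-normalize a single-sample trial")
    resampled = resample_series(trial.samples.to_numpy(), n_points)
    return trial.with_samples(
        pd.DataFrame(resampled, columns=trial.samples.columns), sample_rate=None
    )


def scale_translations(
    trial: KinematicTrial, reference_width: float = REFERENCE_BICONDYLAR_WIDTH_MM
) -> KinematicTrial:
    """Scale the six translation channels toward a reference-width knee.

    Each translation is multiplied by ``reference_width /
    trial.bicondylar_width``; rotation channels are returned bitwise
    unchanged.  Applying the operation with the inverse ratio restores the
    original trial.
    """
    if reference_width <= 0:
        raise ValueError("reference_width must be > 0")
    factor = reference_width / trial.bicondylar_width
    samples = trial.samples.copy()
    samples.loc[:, list(TRANSLATION_PARAMETERS)] *= factor
    return trial.with_samples(samples)


def preprocess_trial(trial: KinematicTrial, config: PreprocessConfig | None = None) -> KinematicTrial:
    """Full chain: filter (raw trials only) -> time-normalize -> scale."""
    config = config or PreprocessConfig()
    if trial.sample_rate is not None:
        trial = filter_trial(trial, config)
    trial = time_normalize(trial, config.n_points)
    return scale_translations(trial, config.reference_width_mm)


def preprocess_cohort(trials, config: PreprocessConfig | None = None) -> list[KinematicTrial]:
    return [preprocess_trial(t, config) for t in trials]
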