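"""Synthetic cohorts and synthetic bone geometry with known ground truth.

The cohort generator is statistical, not biomechanical: it drives a
ground-truth polynomial coupling model with stylized per-activity flexion
profiles and a partially flexion-coupled external-rotation signal, adds
participant-level coefficient heterogeneity and i.i.d. Gaussian
measurement noise per output channel, and attaches a drawn bicondylar
width.  Everything is a deterministic function of the seed: the global
seed expands into independent per-participant / per-trial substreams via
``numpy.random.SeedSequence`` spawning.

Measurement noise is applied to the model's OUTPUT channels; the driver
(input) trajectories are clean unless ``input_noise_sd`` is set.  This
keeps the generator's design matrix fixed and known, so closed-form OLS
standard errors describe fitted-coefficient variability exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import KinematicTrial
from .model import PolynomialKneeModel, load_packaged_model
from .params import (
    ACTIVITIES,
    ALL_PARAMETERS,
    REFERENCE_BICONDYLAR_WIDTH_MM,
    ROTATION_PARAMETERS,
)
from .polymodel import predict_table

#: Stylized peak flexion (deg) per activity: open-chain activities sweep a
#: large arc; walking shows a stance bump and a larger swing bump; stairs
#: flex deeper than level gait.
DEFAULT_FLEXION_AMPLITUDE = {
    "open_flexion": 100.0,
    "open_extension": 100.0,
    "level_walk": 60.0,
    "downhill_walk": 65.0,
    "stair_ascent": 90.0,
    "stair_descent": 90.0,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions the generator emulates.

    Defaults mirror a cohort of 10 participants performing 6 activities,
    each trial resampled to 201 normalized-time points, driven by the
    packaged 2-DOF coupling model.  ``participant_effect_sd`` is the
    relative (fractional) spread applied to every ground-truth coefficient
    per participant; ``noise_sd_rotation`` / ``noise_sd_translation`` are
    the per-sample measurement noise (deg / mm) on output channels, with
    magnitudes motivated by biplane-X-ray error bounds (< 1 deg|mm).
    External rotation is built as ``coupling_fraction * slope * flexion``
    plus an independent smooth component so it is only weakly related to
    flexion.
    """

    n_participants: int = 10
    activities: tuple[str, ...] = ACTIVITIES
    samples_per_trial: int = 201
    ground_truth: str | PolynomialKneeModel = "table1_2dof"
    participant_effect_sd: float = 0.05
    noise_sd_rotation: float = 0.5
    noise_sd_translation: float = 0.5
    input_noise_sd: float = 0.0
    flexion_amplitude: dict = field(default_factory=lambda: dict(DEFAULT_FLEXION_AMPLITUDE))
    coupling_fraction: float = 0.5
    coupling_slope: float = 0.15
    independent_rotation_sd: float = 4.0
    width_mean: float = REFERENCE_BICONDYLAR_WIDTH_MM
    width_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.samples_per_trial < 2:
            raise ValueError("samples_per_trial must be >= 2")
        unknown = set(self.activities) - set(ACTIVITIES)
        if unknown:
            raise ValueError(f"unknown activities {sorted(unknown)}")
        for name in (
            "participant_effect_sd",
            "noise_sd_rotation",
            "noise_sd_translation",
            "input_noise_sd",
            "independent_rotation_sd",
            "width_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.coupling_fraction <= 1:
            raise ValueError("coupling_fraction must be in [0, 1]")
        if self.width_mean <= 0:
            raise ValueError("width_mean must be > 0")

    def resolve_model(self) -> PolynomialKneeModel:
        if isinstance(self.ground_truth, PolynomialKneeModel):
            return self.ground_truth
        return load_packaged_model(self.ground_truth)


def _flexion_profile(activity: str, amplitude: float, t: np.ndarray) -> np.ndarray:
    """Stylized flexion trajectory on normalized time t in [0, 1]."""
    if activity == "open_flexion":
        return amplitude * np.sin(0.5 * np.pi * t) ** 2
    if activity == "open_extension":
        return amplitude * np.cos(0.5 * np.pi * t) ** 2
    # gait-like double bump: small stance-phase flexion, larger swing peak
    stance = 0.35 * np.exp(-(((t - 0.18) / 0.10) ** 2))
    swing = 1.0 * np.exp(-(((t - 0.72) / 0.11) ** 2))
    return amplitude * (stance + swing) / 1.0


def _smooth_random(rng: np.random.Generator, t: np.ndarray, sd: float, n_harmonics: int = 3) -> np.ndarray:
    """Zero-mean smooth random signal with marginal sd ``sd``.

    Random-phase low-order Fourier series; each harmonic's sine/cosine pair
    has variance sd^2 / n_harmonics, so the pointwise variance is sd^2.
    """
    if sd == 0:
        return np.zeros_like(t)
    out = np.zeros_like(t)
    scale = sd / np.sqrt(n_harmonics)
    for k in range(1, n_harmonics + 1):
        a, b = rng.normal(0.0, scale, size=2)
        out += a * np.sin(2 * np.pi * k * t) + b * np.cos(2 * np.pi * k * t)
    return out


def _perturbed_model(model: PolynomialKneeModel, rng: np.random.Generator, rel_sd: float) -> PolynomialKneeModel:
    if rel_sd == 0:
        return model
    coefs = {
        name: row * (1.0 + rng.normal(0.0, rel_sd, size=row.shape))
        for name, row in model.coefficients.items()
    }
    return PolynomialKneeModel(
        input_names=model.input_names,
        order=model.order,
        coefficients=coefs,
        provenance=model.provenance + "+participant-effect",
    )


def simulate_cohort(config: SyntheticCohortConfig) -> list[KinematicTrial]:
    """Generate a deterministic synthetic cohort of kinematic trials.

    Per participant: coefficients of the ground-truth model are perturbed
    by the participant effect and a bicondylar width is drawn.  Per
    activity: a flexion profile and a weakly flexion-coupled external
    rotation drive the perturbed model; Gaussian noise is added to each
    output channel.  The same config (same seed) always returns bitwise
    identical trials.
    """
    base_model = config.resolve_model()
    t = np.linspace(0.0, 1.0, config.samples_per_trial)
    root = np.random.SeedSequence(config.seed)
    participant_seqs = root.spawn(config.n_participants)

    trials: list[KinematicTrial] = []
    for p_idx, p_seq in enumerate(participant_seqs):
        pid = f"P{p_idx + 1}"
        p_streams = p_seq.spawn(len(config.activities) + 1)
        p_rng = np.random.default_rng(p_streams[0])
        model = _perturbed_model(base_model, p_rng, config.participant_effect_sd)
        width = float(p_rng.normal(config.width_mean, config.width_sd))
        width = max(width, 1.0)
        for a_idx, activity in enumerate(config.activities):
            rng = np.random.default_rng(p_streams[a_idx + 1])
            amp = config.flexion_amplitude.get(activity, 60.0)
            f = _flexion_profile(activity, amp, t)
            e = config.coupling_fraction * config.coupling_slope * f + _smooth_random(
                rng, t, config.independent_rotation_sd
            )
            inputs = {"tf_flexion": f}
            if "tf_external_rotation" in model.input_names:
                inputs["tf_external_rotation"] = e
            table = predict_table(model, {k: inputs[k] for k in model.input_names})
            # 1-DOF ground truth: external rotation is an output; overwrite
            # nothing — the model already produced it.
            for name in ALL_PARAMETERS:
                if name in model.input_names:
                    if config.input_noise_sd > 0:
                        table[name] = table[name] + rng.normal(
                            0.0, config.input_noise_sd, size=len(t)
                        )
                    continue
                sd = (
                    config.noise_sd_rotation
                    if name in ROTATION_PARAMETERS
                    else config.noise_sd_translation
                )
                if sd > 0:
                    table[name] = table[name] + rng.normal(0.0, sd, size=len(t))
            trials.append(
                KinematicTrial(
                    participant_id=pid,
                    activity=activity,
                    samples=table,
                    bicondylar_width=width,
                    sample_rate=None,
                )
            )
    return trials


# --------------------------------------------------------------------------
# synthetic bone geometry
# --------------------------------------------------------------------------


@dataclass
class BoneFixture:
    """Labelled synthetic bone surfaces plus the frames they imply.

    All point clouds are synthetic stand-ins for segmented bone surfaces;
    ``femur_frame`` / ``tibia_frame`` / ``patella_frame`` are the exact
    ground-truth frames of the generating geometry, and ``landmarks``
    holds the notch apex, plateau centers, eminence midpoint, patellar
    ridge direction and the orientation hint vectors.
    """

    condyle_points: np.ndarray
    femoral_diaphysis_points: np.ndarray
    tibial_diaphysis_points: np.ndarray
    patella_points: np.ndarray
    landmarks: dict
    femur_frame: "object"
    tibia_frame: "object"
    patella_frame: "object"


def sample_bone_surfaces(
    seed: int = 0,
    *,
    condyle_radius: float = 22.0,
    condyle_length: float = 60.0,
    diaphysis_half_angle_deg: float = 3.0,
    noise_sd: float = 0.0,
    n_points: int = 400,
    transform: np.ndarray | None = None,
) -> BoneFixture:
    """Sample synthetic bone surface patches in a canonical pose.

    In the canonical pose the femoral and tibial ground-truth frames are
    both the identity basis at the origin.  ``transform`` (4x4) rigidly
    moves all geometry, landmarks and ground-truth frames together.
    """
    from .anatomy import BoneFrame, _apply, build_patellar_frame

    if condyle_radius <= 0 or condyle_length <= 0:
        raise ValueError("condyle radius and length must be > 0")
    if not 0 < diaphysis_half_angle_deg < 45:
        raise ValueError("diaphysis_half_angle_deg must be in (0, 45)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # condylar cylinder about the x-axis, posterior-distal quarter arc
    x = rng.uniform(-condyle_length / 2, condyle_length / 2, n_points)
    phi = rng.uniform(np.pi, 2.0 * np.pi, n_points)  # posterior/distal half
    condyle = np.column_stack(
        [x, condyle_radius * np.cos(phi), condyle_radius * np.sin(phi)]
    )

    # femoral diaphysis: cone about +z, apex below the joint
    tan_a = np.tan(np.radians(diaphysis_half_angle_deg))
    apex_f = np.array([0.0, 0.0, 60.0 - 14.0 / tan_a])  # radius 14 mm at z = 60
    z_f = rng.uniform(60.0, 140.0, n_points)
    phi_f = rng.uniform(0, 2 * np.pi, n_points)
    r_f = (z_f - apex_f[2]) * tan_a
    fem_diaph = np.column_stack(
        [r_f * np.cos(phi_f), r_f * np.sin(phi_f), z_f]
    )

    # tibial diaphysis: cone about +z below the plateau, widening downward
    apex_t = np.array([0.0, 0.0, -40.0 + 12.0 / tan_a])
    z_t = rng.uniform(-120.0, -40.0, n_points)
    phi_t = rng.uniform(0, 2 * np.pi, n_points)
    r_t = (apex_t[2] - z_t) * tan_a
    tib_diaph = np.column_stack(
        [r_t * np.cos(phi_t), r_t * np.sin(phi_t), z_t]
    )

    # patellar ellipsoid: wide (x), thin (y, anterior), tall (z)
    center_p = np.array([0.0, 45.0, 5.0])
    semi = np.array([22.0, 9.0, 25.0])
    u = rng.normal(size=(n_points, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(0, 1, n_points) ** (1 / 3)
    patella = center_p + semi * (u * r[:, None])
    patella_noiseless = patella.copy()

    if noise_sd > 0:
        condyle = condyle + rng.normal(0.0, noise_sd, size=condyle.shape)
        fem_diaph = fem_diaph + rng.normal(0.0, noise_sd, size=fem_diaph.shape)
        tib_diaph = tib_diaph + rng.normal(0.0, noise_sd, size=tib_diaph.shape)
        patella = patella + rng.normal(0.0, noise_sd, size=patella.shape)

    landmarks = {
        "notch_apex": np.array([0.0, -5.0, 4.0]),
        "plateau_centers": (np.array([-22.0, 0.0, -12.0]), np.array([22.0, 0.0, -12.0])),
        "eminence_midpoint": np.array([0.0, 0.0, -10.0]),
        "ridge_direction": np.array([0.0, 0.0, 1.0]),
        "anterior_hint": np.array([0.0, 1.0, 0.0]),
        "proximal_hint": np.array([0.0, 0.0, 1.0]),
        "right_hint": np.array([1.0, 0.0, 0.0]),
    }
    femur_frame = BoneFrame(origin=np.zeros(3), axes=np.eye(3))
    tibia_frame = BoneFrame(origin=np.zeros(3), axes=np.eye(3))
    # The patellar frame is defined by the inertia of the sampled cloud
    # itself, so its ground truth is the frame of the noiseless sample.
    patella_frame = build_patellar_frame(
        patella_noiseless, landmarks["ridge_direction"], landmarks["anterior_hint"]
    )

    if transform is not None:
        T = np.asarray(transform, dtype=float)
        condyle = _apply(T, condyle)
        fem_diaph = _apply(T, fem_diaph)
        tib_diaph = _apply(T, tib_diaph)
        patella = _apply(T, patella)
        landmarks = {
            "notch_apex": _apply(T, landmarks["notch_apex"][None])[0],
            "plateau_centers": tuple(
                _apply(T, p[None])[0] for p in landmarks["plateau_centers"]
            ),
            "eminence_midpoint": _apply(T, landmarks["eminence_midpoint"][None])[0],
            "ridge_direction": T[:3, :3] @ landmarks["ridge_direction"],
            "anterior_hint": T[:3, :3] @ landmarks["anterior_hint"],
            "proximal_hint": T[:3, :3] @ landmarks["proximal_hint"],
            "right_hint": T[:3, :3] @ landmarks["right_hint"],
        }
        femur_frame = femur_frame.transformed(T)
        tibia_frame = tibia_frame.transformed(T)
        patella_frame = patella_frame.transformed(T)

    return BoneFixture(
        condyle_points=condyle,
        femoral_diaphysis_points=fem_diaph,
        tibial_diaphysis_points=tib_diaph,
        patella_points=patella,
        landmarks=landmarks,
        femur_frame=femur_frame,
        tibia_frame=tibia_frame,
        patella_frame=patella_frame,
    )
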