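"""Canonical knee kinematic parameter names, ordering and units.

Twelve parameters describe the full 3D motion of the knee-joint complex:
six at the tibiofemoral (TF) joint — three translations (mm) and three
rotations (deg) of the tibia relative to the femur — and six at the
patellofemoral (PF) joint for the patella relative to the femur.

The ordering below is canonical throughout the package: every tabular
structure (trial CSVs, design matrices, reports) lists the six TF
parameters first, then the six PF parameters, translations before
rotations within each joint.  Rotations are always carried in degrees and
translations in millimetres; the packaged model coefficients assume these
units.
"""

from __future__ import annotations

TF_PARAMETERS: tuple[str, ...] = (
    "tf_lateral_shift",
    "tf_anterior_drawer",
    "tf_joint_distraction",
    "tf_flexion",
    "tf_abduction",
    "tf_external_rotation",
)

PF_PARAMETERS: tuple[str, ...] = (
    "pf_lateral_shift",
    "pf_anterior_translation",
    "pf_superior_translation",
    "pf_flexion",
    "pf_lateral_rotation",
    "pf_lateral_tilt",
)

ALL_PARAMETERS: tuple[str, ...] = TF_PARAMETERS + PF_PARAMETERS

TRANSLATION_PARAMETERS: tuple[str, ...] = TF_PARAMETERS[:3] + PF_PARAMETERS[:3]
ROTATION_PARAMETERS: tuple[str, ...] = TF_PARAMETERS[3:] + PF_PARAMETERS[3:]

#: Unit of each canonical parameter ("mm" or "deg").
UNITS: dict[str, str] = {
    **{name: "mm" for name in TRANSLATION_PARAMETERS},
    **{name: "deg" for name in ROTATION_PARAMETERS},
}

#: The six functional activities a cohort trial may be labelled with.
ACTIVITIES: tuple[str, ...] = (
    "open_flexion",
    "open_extension",
    "level_walk",
    "downhill_walk",
    "stair_ascent",
    "stair_descent",
)

#: Primary motion of the knee; always an input of a coupling model.
PRIMARY_INPUT = "tf_flexion"

#: Mean femoral bicondylar width (mm) used as the translation-scaling
#: reference for an average-sized knee.
REFERENCE_BICONDYLAR_WIDTH_MM = 81.7


def validate_parameter_names(names, *, subset_of=ALL_PARAMETERS) -> tuple[str, ...]:
    """Validate a sequence of parameter names against the canon.

    Returns the names as a tuple, preserving order.  Raises ``ValueError``
    on unknown names or duplicates.
    """
    names = tuple(names)
    unknown = [n for n in names if n not in subset_of]
    if unknown:
        raise ValueError(
            f"unknown parameter name(s) {unknown!r}; expected a subset of {list(subset_of)}"
        )
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate parameter names in {names!r}")
    return names
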