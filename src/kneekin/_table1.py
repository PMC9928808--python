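"""Packaged polynomial coefficient sets for the 1-DOF and 2-DOF knee models.

Coefficients are kept as the decimal strings they were published with so
that serialization round-trips them digit-for-digit; floats are parsed
from these strings at load time.  Units: the model maps flexion f (deg)
— and, for the 2-DOF model, external tibial rotation e (deg) — to
translations in mm and rotations in deg.

1-DOF rows are (c0, c11, c21) over the basis (1, f, f^2); 2-DOF rows are
(c0, c11, c12, c21, c22) over (1, f, e, f^2, e^2).  The two model inputs
have no rows: they pass through the model unchanged.
"""

# y = c0 + c11 f + c21 f^2
TABLE1_1DOF: dict[str, tuple[str, ...]] = {
    "tf_lateral_shift": ("1.57", "-0.0488", "1.37E-04"),
    "tf_anterior_drawer": ("0.58", "0.0390", "4.74E-04"),
    "tf_joint_distraction": ("-1.74", "0.0161", "-3.47E-04"),
    "tf_abduction": ("-4.79", "-0.0213", "3.79E-04"),
    "tf_external_rotation": ("-0.16", "-0.1944", "1.39E-03"),
    "pf_lateral_shift": ("4.78", "-0.0433", "3.71E-04"),
    "pf_anterior_translation": ("49.59", "-0.0940", "-6.86E-04"),
    "pf_superior_translation": ("13.21", "-0.2192", "7.15E-04"),
    "pf_flexion": ("0.30", "0.6284", "6.49E-04"),
    "pf_lateral_rotation": ("-3.87", "0.0019", "2.34E-04"),
    "pf_lateral_tilt": ("1.08", "0.0328", "-2.90E-04"),
}

# y = c0 + c11 f + c12 e + c21 f^2 + c22 e^2
TABLE1_2DOF: dict[str, tuple[str, ...]] = {
    "tf_lateral_shift": ("1.54", "-0.0585", "-0.029", "2.00E-04", "2.35E-03"),
    "tf_anterior_drawer": ("0.51", "0.0014", "-0.155", "7.32E-04", "4.30E-03"),
    "tf_joint_distraction": ("-1.76", "0.0220", "0.053", "-3.96E-04", "2.61E-03"),
    "tf_abduction": ("-4.87", "-0.0567", "-0.136", "6.19E-04", "5.16E-03"),
    "pf_lateral_shift": ("4.76", "-0.0252", "0.121", "2.33E-04", "3.21E-03"),
    "pf_anterior_translation": ("49.63", "-0.0694", "0.108", "-8.57E-04", "-2.09E-03"),
    "pf_superior_translation": ("13.26", "-0.1907", "0.124", "5.17E-04", "-2.54E-03"),
    "pf_flexion": ("0.42", "0.7115", "0.382", "6.71E-05", "-5.14E-03"),
    "pf_lateral_rotation": ("-3.83", "-0.0558", "-0.371", "6.71E-04", "-8.38E-03"),
    "pf_lateral_tilt": ("1.15", "0.0851", "0.244", "-6.58E-04", "-2.89E-03"),
}

PACKAGED: dict[str, dict] = {
    "table1_1dof": {
        "input_names": ("tf_flexion",),
        "order": 2,
        "rows": TABLE1_1DOF,
    },
    "table1_2dof": {
        "input_names": ("tf_flexion", "tf_external_rotation"),
        "order": 2,
        "rows": TABLE1_2DOF,
    },
}
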