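"""Polynomial knee model container, JSON serialization, packaged models.

A :class:`PolynomialKneeModel` maps a small set of input tibiofemoral
parameters (always including flexion) to every remaining kinematic
parameter through per-output polynomials with no cross terms: the basis
is ``{1} ∪ {x_i^k : input i, k = 1..order}``, so an order-2, 2-input
model has 5 coefficients per output.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._table1 import PACKAGED
from .params import ALL_PARAMETERS, PRIMARY_INPUT, TF_PARAMETERS, validate_parameter_names


def basis_terms(input_names: Sequence[str], order: int) -> tuple[str, ...]:
    """Ordered basis term labels: constant, then degree-major powers.

    ``("tf_flexion", "tf_external_rotation")`` at order 2 gives
    ``("1", "tf_flexion", "tf_external_rotation", "tf_flexion^2",
    "tf_external_rotation^2")`` — matching the coefficient order
    (c0, c11, c12, c21, c22).  No cross terms at any order.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    terms = ["1"]
    for k in range(1, order + 1):
        for name in input_names:
            terms.append(name if k == 1 else f"{name}^{k}")
    return tuple(terms)


@dataclass
class PolynomialKneeModel:
    """Coefficients of a fitted or packaged polynomial coupling model.

    Parameters
    ----------
    input_names : tuple of str
        Ordered input TF parameters; must contain ``tf_flexion``.
    order : int
        Polynomial order (>= 1).
    coefficients : dict
        Output parameter name -> coefficient row (length
        ``1 + order * n_inputs``) over :func:`basis_terms`.
    coefficient_strings : dict or None
        Decimal-string form of each row, preserved verbatim through
        serialization so published coefficients survive digit-for-digit.
    provenance : str
        Free-form origin label, e.g. ``"packaged:table1_2dof"`` or
        ``"fitted"``.
    """

    input_names: tuple[str, ...]
    order: int
    coefficients: dict[str, np.ndarray]
    coefficient_strings: dict[str, tuple[str, ...]] | None = None
    provenance: str = "unspecified"

    def __post_init__(self):
        self.input_names = validate_parameter_names(self.input_names, subset_of=TF_PARAMETERS)
        if PRIMARY_INPUT not in self.input_names:
            raise ValueError(f"model inputs must contain {PRIMARY_INPUT!r}")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        expected_outputs = set(ALL_PARAMETERS) - set(self.input_names)
        got_outputs = set(self.coefficients)
        if got_outputs != expected_outputs:
            overlap = got_outputs & set(self.input_names)
            if overlap:
                raise ValueError(
                    f"input parameter(s) {sorted(overlap)} must not have coefficient rows"
                )
            raise ValueError(
                f"coefficient rows must cover exactly the non-input parameters; "
                f"missing {sorted(expected_outputs - got_outputs)}, "
                f"unexpected {sorted(got_outputs - expected_outputs)}"
            )
        ncoef = self.n_coefficients
        coefs: dict[str, np.ndarray] = {}
        for name, row in self.coefficients.items():
            arr = np.asarray(row, dtype=float)
            if arr.shape != (ncoef,):
                raise ValueError(
                    f"coefficient row for {name!r} has length {arr.size}, expected {ncoef}"
                )
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite coefficient in row for {name!r}")
            coefs[name] = arr
        self.coefficients = coefs
        if self.coefficient_strings is not None:
            for name, row in self.coefficient_strings.items():
                if name not in self.coefficients:
                    raise ValueError(f"coefficient_strings row {name!r} has no float row")
                if len(row) != ncoef:
                    raise ValueError(f"coefficient_strings row for {name!r} has wrong length")

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_coefficients(self) -> int:
        return 1 + self.order * self.n_inputs

    @property
    def output_names(self) -> tuple[str, ...]:
        """Predicted parameters, in canonical order (inputs excluded)."""
        return tuple(n for n in ALL_PARAMETERS if n not in self.input_names)

    @property
    def tf_output_names(self) -> tuple[str, ...]:
        return tuple(n for n in TF_PARAMETERS if n not in self.input_names)

    def basis_terms(self) -> tuple[str, ...]:
        return basis_terms(self.input_names, self.order)

    def coefficient_matrix(self) -> np.ndarray:
        """(n_outputs, n_coefficients) array, outputs in canonical order."""
        return np.vstack([self.coefficients[name] for name in self.output_names])

    def strings_or_repr(self) -> dict[str, tuple[str, ...]]:
        """Decimal strings for every row, synthesizing exact reprs if needed."""
        out = {}
        for name in self.output_names:
            if self.coefficient_strings is not None and name in self.coefficient_strings:
                out[name] = tuple(self.coefficient_strings[name])
            else:
                out[name] = tuple(format(v, ".17g") for v in self.coefficients[name])
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, PolynomialKneeModel):
            return NotImplemented
        return (
            self.input_names == other.input_names
            and self.order == other.order
            and set(self.coefficients) == set(other.coefficients)
            and all(
                np.array_equal(self.coefficients[k], other.coefficients[k])
                for k in self.coefficients
            )
        )


def load_packaged_model(name: str) -> PolynomialKneeModel:
    """Load one of the packaged coupling models by name.

    Available names: ``"table1_1dof"`` (input: TF flexion; 11 outputs) and
    ``"table1_2dof"`` (inputs: TF flexion + external tibial rotation; 10
    outputs).  Coefficients are returned exactly as published.
    """
    if name not in PACKAGED:
        raise KeyError(
            f"no such packaged model {name!r}; available: {sorted(PACKAGED)}"
        )
    entry = PACKAGED[name]
    rows = entry["rows"]
    return PolynomialKneeModel(
        input_names=tuple(entry["input_names"]),
        order=entry["order"],
        coefficients={k: np.array([float(v) for v in row]) for k, row in rows.items()},
        coefficient_strings={k: tuple(row) for k, row in rows.items()},
        provenance=f"packaged:{name}",
    )


def model_to_json_dict(model: PolynomialKneeModel) -> dict:
    terms = model.basis_terms()
    strings = model.strings_or_repr()
    return {
        "input_names": list(model.input_names),
        "order": model.order,
        "coefficients": {
            name: [[t, s] for t, s in zip(terms, strings[name])]
            for name in model.output_names
        },
        "provenance": model.provenance,
    }


def model_from_json_dict(doc: Mapping) -> PolynomialKneeModel:
    try:
        input_names = tuple(doc["input_names"])
        order = int(doc["order"])
        coef_doc = doc["coefficients"]
        provenance = str(doc.get("provenance", "unspecified"))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed model document: {exc}") from exc
    expected_terms = basis_terms(input_names, order)
    coefficients: dict[str, np.ndarray] = {}
    strings: dict[str, tuple[str, ...]] = {}
    for name, pairs in coef_doc.items():
        got_terms = tuple(t for t, _ in pairs)
        if got_terms != expected_terms:
            raise ValueError(
                f"coefficient row for {name!r} has basis terms {got_terms}, "
                f"expected {expected_terms}"
            )
        row = tuple(str(s) for _, s in pairs)
        strings[name] = row
        coefficients[name] = np.array([float(s) for s in row])
    return PolynomialKneeModel(
        input_names=input_names,
        order=order,
        coefficients=coefficients,
        coefficient_strings=strings,
        provenance=provenance,
    )


def write_model(model: PolynomialKneeModel, path) -> None:
    """Serialize a model to JSON; coefficient decimal strings are exact."""
    Path(path).write_text(json.dumps(model_to_json_dict(model), indent=2) + "\n")


def read_model(path) -> PolynomialKneeModel:
    """Read a model JSON file written by :func:`write_model`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model JSON in {path}: {exc}") from exc
    return model_from_json_dict(doc)


def resolve_model(spec: str) -> PolynomialKneeModel:
    """Resolve ``"packaged:<name>"`` or a JSON file path to a model."""
    if spec.startswith("packaged:"):
        return load_packaged_model(spec.split(":", 1)[1])
    return read_model(spec)
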