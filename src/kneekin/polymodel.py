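"""Polynomial coupling regression: design matrices, fitting, prediction.

The model family couples a small set of input tibiofemoral parameters
(always containing flexion) to every remaining knee kinematic parameter
through independent per-output polynomials sharing one basis with no
cross terms:

    y = c0 + sum_i sum_k c_{k i} x_i^k,   k = 1..order.

Fitting is ordinary least squares per output, solved through an
orthogonal (SVD) factorization; rank-deficient designs raise instead of
falling back to a pseudo-inverse.  Angles are in DEGREES and translations
in millimetres everywhere — radian inputs will silently produce wrong
predictions, so convert before calling.

The scikit-learn-style :class:`PolynomialKneeRegressor` is the primary
surface; :func:`fit_model`, :func:`predict` and :func:`predict_trial` are
thin functional wrappers around it and the model container.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .datamodel import JointParameterVector, KinematicTrial
from .model import PolynomialKneeModel, basis_terms
from .params import ALL_PARAMETERS, PRIMARY_INPUT, TF_PARAMETERS, validate_parameter_names


class RankDeficientDesignError(ValueError):
    """Design matrix does not have full column rank (e.g. constant flexion)."""


def design_matrix(
    observations: pd.DataFrame | Mapping[str, np.ndarray],
    input_names: Sequence[str],
    order: int,
) -> np.ndarray:
    """Polynomial basis values for each observation.

    Columns are ordered ``[1, x1, x2, ..., x1^2, x2^2, ...]`` up to
    ``order`` — the constant first, then degree-major powers of each input,
    with no cross terms.
    """
    input_names = validate_parameter_names(input_names, subset_of=TF_PARAMETERS)
    if PRIMARY_INPUT not in input_names:
        raise ValueError(f"input_names must contain {PRIMARY_INPUT!r}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    cols = []
    for name in input_names:
        if name not in observations:
            raise ValueError(f"input parameter {name!r} not present in observations")
        cols.append(np.asarray(observations[name], dtype=float))
    x = np.column_stack(cols) if cols else np.empty((0, 0))
    n = x.shape[0]
    blocks = [np.ones((n, 1))]
    for k in range(1, order + 1):
        blocks.append(x**k)
    return np.hstack(blocks)


def _solve_ols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares solve with an explicit rank check (SVD-based)."""
    n, m = X.shape
    if n < m:
        raise RankDeficientDesignError(
            f"need at least {m} observations for {m} basis columns, got {n}"
        )
    s = linalg.svdvals(X)
    tol = max(X.shape) * np.finfo(float).eps * s[0]
    rank = int((s > tol).sum())
    if rank < m:
        raise RankDeficientDesignError(
            f"design matrix is rank deficient (rank {rank} < {m} columns); "
            "check for constant or collinear input channels"
        )
    coef, *_ = linalg.lstsq(X, Y)
    return coef


def fit_model(
    observations: pd.DataFrame,
    input_names: Sequence[str] = (PRIMARY_INPUT,),
    order: int = 2,
    *,
    provenance: str = "fitted",
) -> PolynomialKneeModel:
    """Fit per-output polynomials by ordinary least squares.

    ``observations`` must contain the 12 canonical parameter columns (a
    pooled table from :func:`kneekin.datamodel.pool_observations` works
    directly).  Every non-input parameter becomes an output with its own
    coefficient row; all outputs share the same design matrix.
    """
    reg = PolynomialKneeRegressor(inputs=tuple(input_names), order=order)
    reg.fit(observations)
    model = reg.model_
    model.provenance = provenance
    return model


def predict(model: PolynomialKneeModel, inputs: Mapping[str, float]) -> JointParameterVector:
    """Predict all 12 parameters from input values at one time point.

    Input parameters pass through into the returned vector unchanged.
    """
    for name in model.input_names:
        if name not in inputs:
            raise ValueError(f"missing input value for {name!r}")
        if not np.isfinite(inputs[name]):
            raise ValueError(f"non-finite input value for {name!r}")
    frame = predict_table(model, {k: [float(inputs[k])] for k in model.input_names})
    return JointParameterVector(*frame.iloc[0].to_numpy())


def predict_table(
    model: PolynomialKneeModel, inputs: pd.DataFrame | Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Predict a full 12-column trajectory table from input trajectories."""
    series = {}
    lengths = set()
    for name in model.input_names:
        if name not in inputs:
            raise ValueError(f"missing input trajectory for {name!r}")
        arr = np.asarray(inputs[name], dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"input trajectory {name!r} must be 1-D")
        series[name] = arr
        lengths.add(arr.shape[0])
    if len(lengths) != 1:
        raise ValueError(f"input trajectories have mismatched lengths {sorted(lengths)}")
    X = design_matrix(series, model.input_names, model.order)
    Yhat = X @ model.coefficient_matrix().T
    out = pd.DataFrame(index=range(X.shape[0]), columns=list(ALL_PARAMETERS), dtype=float)
    for j, name in enumerate(model.output_names):
        out[name] = Yhat[:, j]
    for name in model.input_names:
        out[name] = series[name]
    return out


def predict_trial(
    model: PolynomialKneeModel,
    inputs: pd.DataFrame | Mapping[str, Sequence[float]],
    *,
    participant_id: str = "predicted",
    activity: str = "level_walk",
    bicondylar_width: float = 81.7,
) -> KinematicTrial:
    """Predict a full trial from measured input trajectories.

    The input channels of the returned trial are identical to the supplied
    trajectories, so a model's error on its own inputs is exactly zero.
    """
    table = predict_table(model, inputs)
    return KinematicTrial(
        participant_id=participant_id,
        activity=activity,
        samples=table,
        bicondylar_width=bicondylar_width,
        sample_rate=None,
    )


class PolynomialKneeRegressor:
    """Scikit-learn-style estimator for the polynomial coupling model.

    Parameters
    ----------
    inputs : tuple of str
        Input TF parameter names; must contain ``"tf_flexion"``.
    order : int
        Polynomial order of the shared cross-term-free basis.

    Attributes (after :meth:`fit`)
    ------------------------------
    model_ : PolynomialKneeModel
        Fitted coefficient container.
    coef_ : ndarray of shape (n_outputs, n_coefficients)
        Coefficient rows, outputs in canonical order.
    n_observations_ : int
        Number of pooled observations used.
    design_ : ndarray
        The design matrix of the fit (kept for residual diagnostics).

    Examples
    --------
    >>> reg = PolynomialKneeRegressor(inputs=("tf_flexion",), order=2)
    >>> reg.fit(observations)            # doctest: +SKIP
    >>> reg.predict({"tf_flexion": [0.0, 30.0, 60.0]})  # doctest: +SKIP
    """

    def __init__(self, inputs: tuple[str, ...] = (PRIMARY_INPUT,), order: int = 2):
        self.inputs = tuple(inputs)
        self.order = order

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"inputs": self.inputs, "order": self.order}

    def set_params(self, **params) -> "PolynomialKneeRegressor":
        for k, v in params.items():
            if k not in ("inputs", "order"):
                raise ValueError(f"invalid parameter {k!r} for PolynomialKneeRegressor")
            setattr(self, k, tuple(v) if k == "inputs" else v)
        return self

    def __repr__(self) -> str:
        return f"PolynomialKneeRegressor(inputs={self.inputs!r}, order={self.order})"

    # -- estimator API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "PolynomialKneeRegressor":
        """Fit on a pooled observation table with the 12 canonical columns."""
        missing = [c for c in ALL_PARAMETERS if c not in X.columns]
        if missing:
            raise ValueError(f"observation table missing column(s): {missing}")
        inputs = validate_parameter_names(self.inputs, subset_of=TF_PARAMETERS)
        if PRIMARY_INPUT not in inputs:
            raise ValueError(f"inputs must contain {PRIMARY_INPUT!r}")
        outputs = tuple(n for n in ALL_PARAMETERS if n not in inputs)
        D = design_matrix(X, inputs, self.order)
        Y = X.loc[:, list(outputs)].to_numpy(dtype=float)
        coef = _solve_ols(D, Y)  # (n_coefficients, n_outputs)
        self.model_ = PolynomialKneeModel(
            input_names=inputs,
            order=self.order,
            coefficients={name: coef[:, j].copy() for j, name in enumerate(outputs)},
            provenance="fitted",
        )
        self.coef_ = coef.T
        self.n_observations_ = D.shape[0]
        self.n_features_in_ = len(inputs)
        self.design_ = D
        return self

    def predict(self, X: pd.DataFrame | Mapping[str, Sequence[float]]) -> pd.DataFrame:
        """Predict the full 12-parameter table from input trajectories."""
        self._check_fitted()
        return predict_table(self.model_, X)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("PolynomialKneeRegressor is not fitted yet; call fit()")

    @property
    def basis_terms_(self) -> tuple[str, ...]:
        self._check_fitted()
        return basis_terms(self.model_.input_names, self.model_.order)
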