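"""Residual metrics, cross-validation and model-selection sweeps.

Error conventions
-----------------
Rotations of 1 degree and translations of 1 mm are weighted equally, so
pooled residuals carry a combined deg|mm unit.  The tibiofemoral (TF)
pooled residual averages squared residuals over the (6 - n) predicted TF
parameters of an n-input model; the patellofemoral (PF) pooled residual
always averages over all 6 PF parameters (model inputs are TF-side only):

    RMSR_TF = sqrt( 1 / ((6 - n) p) * sum_i sum_j (y_ij - y'_ij)^2 )
    RMSR_PF = sqrt( 1 / (6 p)      * sum_i sum_j (y_ij - y'_ij)^2 )

with p observations.  Cross-validation leaves out one participant at a
time: the model is refitted on everyone else's pooled observations and
used to predict the left-out participant's trials from their measured
input channels.  The report has the shape of a per-participant error
table: one column per left-out participant plus an arithmetic ``Mean``
column, one row per parameter plus a pooled ``All`` row that excludes the
input parameters (whose error is zero by construction).
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CVReport, KinematicTrial, ModelSelectionResult, ResidualReport, pool_observations
from .model import PolynomialKneeModel
from .params import ALL_PARAMETERS, PF_PARAMETERS, PRIMARY_INPUT, TF_PARAMETERS
from .polymodel import RankDeficientDesignError, fit_model, predict_table


def _as_matrix(values, n_cols_expected: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[1] != n_cols_expected:
        raise ValueError(
            f"{what}: expected a (p, {n_cols_expected}) array of parameter values, "
            f"got shape {arr.shape}"
        )
    if arr.shape[0] == 0:
        raise ValueError(f"{what}: no observations (p = 0)")
    return arr


def rmsr_tf(fitted, measured, n_inputs: int) -> float:
    """Pooled RMS residual over the (6 - n) predicted TF parameters."""
    if not 1 <= n_inputs <= 5:
        raise ValueError(f"n_inputs must be in 1..5, got {n_inputs}")
    k = 6 - n_inputs
    f = _as_matrix(fitted, k, "fitted")
    m = _as_matrix(measured, k, "measured")
    if f.shape != m.shape:
        raise ValueError(f"fitted {f.shape} and measured {m.shape} shapes differ")
    return float(np.sqrt(np.mean((f - m) ** 2)))


def rmsr_pf(fitted, measured) -> float:
    """Pooled RMS residual over all 6 PF parameters."""
    f = _as_matrix(fitted, 6, "fitted")
    m = _as_matrix(measured, 6, "measured")
    if f.shape != m.shape:
        raise ValueError(f"fitted {f.shape} and measured {m.shape} shapes differ")
    return float(np.sqrt(np.mean((f - m) ** 2)))


def pooled_rmse(per_parameter_rmse: Mapping[str, float], exclude: Iterable[str] = ()) -> float:
    """RMS of per-parameter RMSE values over predicted parameters.

    With equal observation counts behind each per-parameter value this
    equals pooling the raw squared errors.  ``exclude`` names the input
    parameters to drop (their error is zero by construction and would
    deflate the pooled value).
    """
    exclude = set(exclude)
    values = [v for k, v in per_parameter_rmse.items() if k not in exclude]
    if not values:
        raise ValueError("no parameters left after exclusion")
    return float(np.sqrt(np.mean(np.square(values))))


def residual_report(model: PolynomialKneeModel, observations: pd.DataFrame) -> ResidualReport:
    """Training/evaluation residuals of a model on an observation table."""
    fitted = predict_table(model, observations.loc[:, list(model.input_names)])
    measured = observations.loc[:, list(ALL_PARAMETERS)].reset_index(drop=True)
    err = fitted.to_numpy() - measured.to_numpy()
    per_param = {
        name: float(np.sqrt(np.mean(err[:, i] ** 2)))
        for i, name in enumerate(ALL_PARAMETERS)
    }
    for name in model.input_names:
        per_param[name] = 0.0
    tf_out = list(model.tf_output_names)
    return ResidualReport(
        per_parameter_rmse=per_param,
        rmsr_tfj=rmsr_tf(
            fitted.loc[:, tf_out], measured.loc[:, tf_out], n_inputs=model.n_inputs
        ),
        rmsr_pfj=rmsr_pf(fitted.loc[:, list(PF_PARAMETERS)], measured.loc[:, list(PF_PARAMETERS)]),
        n_inputs=model.n_inputs,
        n_observations=len(measured),
    )


def _participants(trials: Sequence[KinematicTrial]) -> list[str]:
    seen: list[str] = []
    for t in trials:
        if t.participant_id not in seen:
            seen.append(t.participant_id)
    return seen


def loocv(
    trials: Sequence[KinematicTrial],
    input_names: Sequence[str] = (PRIMARY_INPUT,),
    order: int = 2,
) -> CVReport:
    """Leave-one-participant-out cross-validation.

    For each participant: fit on all other participants' pooled
    observations, predict the left-out participant's trials from their
    measured input channels, and pool squared errors over all of that
    participant's trials and time points.  A fold whose training design is
    rank deficient is recorded in ``fold_errors`` (its column is NaN)
    rather than silently propagated.
    """
    trials = list(trials)
    participants = _participants(trials)
    if len(participants) < 2:
        raise ValueError("leave-one-out cross-validation needs >= 2 participants")
    input_names = tuple(input_names)

    per_param: dict[str, dict[str, float]] = {p: {} for p in participants}
    fold_errors: dict[str, str] = {}
    for left_out in participants:
        train = [t for t in trials if t.participant_id != left_out]
        test = [t for t in trials if t.participant_id == left_out]
        try:
            model = fit_model(pool_observations(train), input_names, order)
        except RankDeficientDesignError as exc:
            fold_errors[left_out] = str(exc)
            per_param[left_out] = {name: np.nan for name in ALL_PARAMETERS}
            continue
        sq_sum = np.zeros(len(ALL_PARAMETERS))
        count = 0
        for trial in test:
            fitted = predict_table(model, trial.samples.loc[:, list(input_names)])
            err = fitted.to_numpy() - trial.samples.to_numpy()
            sq_sum += (err**2).sum(axis=0)
            count += trial.n_samples
        rmse = np.sqrt(sq_sum / count)
        per_param[left_out] = dict(zip(ALL_PARAMETERS, rmse))
        for name in input_names:
            per_param[left_out][name] = 0.0

    def panel(panel_params: tuple[str, ...]) -> pd.DataFrame:
        predicted = [n for n in panel_params if n not in input_names]
        rows = list(panel_params) + ["All"]
        table = pd.DataFrame(index=rows, columns=participants, dtype=float)
        for p in participants:
            for name in panel_params:
                table.loc[name, p] = per_param[p][name]
            vals = {n: per_param[p][n] for n in predicted}
            table.loc["All", p] = (
                np.nan if p in fold_errors else pooled_rmse(vals)
            )
        table["Mean"] = table[participants].mean(axis=1)
        return table

    return CVReport(
        tf_table=panel(TF_PARAMETERS),
        pf_table=panel(PF_PARAMETERS),
        input_names=input_names,
        order=order,
        fold_errors=fold_errors,
    )


def input_set_candidates(max_dof: int) -> list[tuple[str, ...]]:
    """All input subsets of the six TF parameters containing flexion.

    Candidates have size 1..max_dof; e.g. max_dof = 2 gives 6 candidates
    and max_dof = 5 gives 31.
    """
    if not 1 <= max_dof <= 6:
        raise ValueError(f"max_dof must be in 1..6, got {max_dof}")
    others = [n for n in TF_PARAMETERS if n != PRIMARY_INPUT]
    out: list[tuple[str, ...]] = []
    for size in range(1, max_dof + 1):
        for combo in itertools.combinations(others, size - 1):
            # keep canonical ordering within the candidate
            names = tuple(n for n in TF_PARAMETERS if n == PRIMARY_INPUT or n in combo)
            out.append(names)
    return out


def enumerate_input_sets(
    observations: pd.DataFrame, max_dof: int, order: int = 2
) -> ModelSelectionResult:
    """Fit and score every candidate input set up to ``max_dof`` inputs.

    Each candidate is fitted on the pooled observations and scored by the
    TF and PF pooled residuals; the result table is ranked by the TF
    residual (the input parameters themselves carry no residual, so the
    TF value is the discriminating one).
    """
    rows = []
    for names in input_set_candidates(max_dof):
        model = fit_model(observations, names, order)
        rep = residual_report(model, observations)
        rows.append(
            {
                "inputs": ",".join(names),
                "n_inputs": len(names),
                "order": order,
                "rmsr_tfj": rep.rmsr_tfj,
                "rmsr_pfj": rep.rmsr_pfj,
            }
        )
    table = pd.DataFrame(rows).sort_values("rmsr_tfj", kind="stable").reset_index(drop=True)
    return ModelSelectionResult(table=table)


def order_sweep(
    observations: pd.DataFrame,
    input_names: Sequence[str],
    orders: Sequence[int],
) -> pd.DataFrame:
    """Training residuals of one input set across polynomial orders.

    Returns a DataFrame indexed by order with ``rmsr_tfj`` / ``rmsr_pfj``
    columns.  On a fixed training set the residual is non-increasing in
    order (nested bases).
    """
    if len(orders) == 0 or min(orders) < 1:
        raise ValueError("orders must be a non-empty sequence of integers >= 1")
    rows = {}
    for order in orders:
        model = fit_model(observations, input_names, int(order))
        rep = residual_report(model, observations)
        rows[int(order)] = {"rmsr_tfj": rep.rmsr_tfj, "rmsr_pfj": rep.rmsr_pfj}
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "order"
    return out
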