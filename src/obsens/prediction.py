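"""Ensemble trajectory prediction, percentile envelopes and NRMSE scoring.

The ensemble prediction is the pointwise median of the member trajectories
(states and outputs); uncertainty is summarized by pointwise percentile
envelopes.  A "P% confidence percentile" band spans the (50 - P/2)th to
(50 + P/2)th percentiles, so the conventional 40%/80% bands correspond to the
30-70 and 10-90 percentile pairs, and 95% to 2.5-97.5.

Prediction quality is scored by the normalized root-mean-square error

    NRMSE = RMSE(prediction, reference) / (max(reference) - min(reference)),

computed per variable and averaged across variables, which makes errors
comparable between quantities of different magnitude.  The same score applies
to outputs against data, states against true (nominal-parameter) trajectories,
and parameter vectors against nominal values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble
from .models import ODEModel, SimulationError, simulate

__all__ = ["EnsemblePrediction", "ensemble_predict", "nrmse"]


@dataclass(frozen=True)
class EnsemblePrediction:
    """Stacked member trajectories with median and percentile envelopes."""

    times: np.ndarray
    variable_names: tuple[str, ...]  # states then outputs
    stack: np.ndarray  # (m, n_t, n_x + n_y)
    median: np.ndarray  # (n_t, n_x + n_y)
    envelopes: dict  # level (e.g. 80) -> (lower, upper) matrices
    failed_members: tuple[int, ...]

    @property
    def n_members(self) -> int:
        return self.stack.shape[0]

    def variable(self, name: str) -> int:
        return self.variable_names.index(name)

    def to_frame(self):
        import pandas as pd

        cols = {"time": self.times}
        for j, name in enumerate(self.variable_names):
            cols[f"{name}_median"] = self.median[:, j]
            for lvl, (lo, hi) in sorted(self.envelopes.items()):
                cols[f"{name}_p{lvl}_lo"] = lo[:, j]
                cols[f"{name}_p{lvl}_hi"] = hi[:, j]
        return pd.DataFrame(cols)


def ensemble_predict(
    problem_or_model,
    ensemble: Ensemble,
    times: np.ndarray,
    percentiles: tuple = (40, 80),
    max_failure_fraction: float = 0.2,
) -> EnsemblePrediction:
    """Simulate every ensemble member and aggregate median and envelopes.

    ``problem_or_model`` is either an :class:`EstimationProblem` (whose
    decision-vector layout unpacks each member into parameters, initial
    conditions and input functions) or a bare :class:`ODEModel` when members
    are plain parameter vectors.  Members whose simulation fails are excluded
    and reported; more than ``max_failure_fraction`` failures aborts.
    """
    times = np.asarray(times, dtype=float)
    if ensemble.size == 0:
        raise ValueError("empty ensemble")
    if isinstance(problem_or_model, ODEModel):
        model = problem_or_model

        def run(v):
            return simulate(model, theta=v, times=times)
    else:
        problem = problem_or_model
        model = problem.model

        def run(v):
            theta, x0, w_funcs, _ = problem.split(v)
            return simulate(
                model, theta=theta, x0=x0, times=times,
                inputs=problem.known_inputs, w=w_funcs,
            )

    names = tuple(str(s) for s in model.states) + tuple(
        f"y{j + 1}" for j in range(model.n_outputs)
    )
    rows = []
    failed = []
    for i in range(ensemble.size):
        try:
            tr = run(ensemble.vectors[i])
            rows.append(np.hstack([tr.states, tr.outputs]))
        except SimulationError:
            failed.append(i)
    if len(failed) > max_failure_fraction * ensemble.size:
        raise SimulationError(
            f"{len(failed)} of {ensemble.size} ensemble member simulations failed"
        )
    stack = np.array(rows)
    median = np.percentile(stack, 50.0, axis=0)
    envelopes = {}
    for p in percentiles:
        if not 0 < p <= 100:
            raise ValueError(f"invalid envelope level {p}")
        lo = np.percentile(stack, 50.0 - p / 2.0, axis=0)
        hi = np.percentile(stack, 50.0 + p / 2.0, axis=0)
        envelopes[p] = (lo, hi)
    return EnsemblePrediction(
        times=times,
        variable_names=names,
        stack=stack,
        median=median,
        envelopes=envelopes,
        failed_members=tuple(failed),
    )


def plot_prediction(
    pred: EnsemblePrediction,
    variable: str,
    truth: np.ndarray | None = None,
    data: tuple | None = None,
    ax=None,
):
    """Median trajectory with shaded percentile envelopes for one variable.

    ``truth`` is an optional reference trajectory on ``pred.times``; ``data``
    an optional (times, values) pair of measurements.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    j = pred.variable(variable)
    for lvl, (lo, hi) in sorted(pred.envelopes.items(), reverse=True):
        ax.fill_between(pred.times, lo[:, j], hi[:, j], alpha=0.25,
                        label=f"{lvl}% envelope")
    ax.plot(pred.times, pred.median[:, j], "k-", label="ensemble median")
    if truth is not None:
        ax.plot(pred.times, truth, "r-", lw=1.2, label="true trajectory")
    if data is not None:
        ax.plot(data[0], data[1], "o", ms=3, color="tab:gray", label="data")
    ax.set_xlabel("time")
    ax.set_ylabel(variable)
    ax.legend(fontsize=8)
    return ax


def nrmse(prediction: np.ndarray, reference: np.ndarray) -> float:
    """Range-normalized RMSE; per-variable for 2-D input, then averaged.

    The reference must not be constant (its range normalizes the error).
    """
    pred = np.asarray(prediction, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference must have the same shape")
    if pred.ndim == 1:
        if pred.size < 2:
            raise ValueError("need at least two points")
        rng = np.max(ref) - np.min(ref)
        if rng == 0:
            raise ValueError("constant reference: NRMSE undefined")
        return float(np.sqrt(np.mean((pred - ref) ** 2)) / rng)
    if pred.ndim == 2:
        return float(np.mean([nrmse(pred[:, j], ref[:, j]) for j in range(pred.shape[1])]))
    raise ValueError("prediction must be 1-D or 2-D")
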