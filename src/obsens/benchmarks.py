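"""Bundled benchmark case studies.

Four kinetic models of increasing size: a glucose-regulation circuit (``big``),
a cell-division-cycle oscillator (``celldiv``), a circadian gene oscillator
(``circad``) and a JAK-STAT signalling model (``jakstat``).  Each case carries
the original model, the reparameterization that restores full observability
(where one exists; none is known for ``celldiv``), study metadata (dimensions,
number of data points, noise levels) and the data-generation protocol
(measurement horizon and true input functions) used by the synthetic studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import sympy as sp

from .models import ODEModel, Reparameterization, apply_reparameterization, load_model

__all__ = ["BenchmarkCase", "load_benchmark", "bundled_transformations", "BENCHMARK_IDS"]

BENCHMARK_IDS = ("big", "celldiv", "circad", "jakstat")

_ALIASES = {
    "big": "big",
    "βig": "big",
    "betaig": "big",
    "celldiv": "celldiv",
    "circad": "circad",
    "jakstat": "jakstat",
}


@dataclass(frozen=True)
class BenchmarkMetadata:
    n_params: int
    n_states: int
    n_observed: int
    n_datapoints: int
    sigma_abs: float | None  # fraction of the per-output trajectory maximum
    sigma_rel: float | None


@dataclass(frozen=True)
class BenchmarkCase:
    id: str
    original: ODEModel
    transformation: Reparameterization | None
    metadata: BenchmarkMetadata
    t_end: float
    known_input_truth: Mapping[str, Callable] | None
    unknown_input_truth: Mapping[str, Callable] | None
    source: str

    @property
    def reparameterized(self) -> ODEModel | None:
        if self.transformation is None:
            return None
        return apply_reparameterization(self.original, self.transformation)

    def measurement_times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.metadata.n_datapoints)


def _pulse(peak: float, t_peak: float, delay: float = 0.0) -> Callable:
    """Smooth single-bump time course peaking at ``t_peak`` with height ``peak``."""

    def f(t):
        if isinstance(t, (float, int)):
            s = (t - delay) / t_peak
            return peak * s * math.exp(1.0 - s) if s > 0 else 0.0
        s = np.maximum(np.asarray(t, dtype=float) - delay, 0.0) / t_peak
        return peak * s * np.exp(1.0 - s)

    return f


def bundled_transformations() -> dict[str, Reparameterization]:
    """The reparameterizations that make each transformable benchmark FISPO.

    * ``jakstat``: the unobservable STAT variable is multiplied by the
      unidentifiable unit-conversion parameter, x1* = x1*p2; the recycling and
      output-scale parameters merge into q5 = p2*p5 and q6 = p6/p2.
    * ``circad``: the two unobservable mRNAs are rescaled by the transcription
      rates, x5* = x5/aAp and x7* = x7/aRp, merging cA = aA/aAp, bAs = bA*aAp
      (and the repressor-side analogues); one parameter per mRNA is removed.
    * ``big``: the beta-cell mass is rescaled by the secretion capacity,
      x3* = x3*p, and the insulin-clearance term is absorbed into the unknown
      input, w* = w - x1*x2*(si - 1), so insulin itself becomes observable
      without being transformed.
    """
    x1, x2, x3, x5, x7 = sp.symbols("x1 x2 x3 x5 x7")
    p, si, w = sp.symbols("p si w")
    p2, p5, p6 = sp.symbols("p2 p5 p6")
    aA, aAp, aR, aRp, bA, bR = sp.symbols("aA aAp aR aRp bA bR")
    return {
        "big": Reparameterization(
            name="obs",
            new_states={x3: (sp.Symbol("x3s"), x3 * p)},
            new_inputs={w: (sp.Symbol("ws"), w - x1 * x2 * (si - 1))},
            removed_params=(p, si),
        ),
        "jakstat": Reparameterization(
            name="obs",
            new_states={x1: (sp.Symbol("x1s"), x1 * p2)},
            new_params={sp.Symbol("q5"): p2 * p5, sp.Symbol("q6"): p6 / p2},
            removed_params=(p2,),
        ),
        "circad": Reparameterization(
            name="obs",
            new_states={
                x5: (sp.Symbol("x5s"), x5 / aAp),
                x7: (sp.Symbol("x7s"), x7 / aRp),
            },
            new_params={
                sp.Symbol("cA"): aA / aAp,
                sp.Symbol("bAs"): bA * aAp,
                sp.Symbol("cR"): aR / aRp,
                sp.Symbol("bRs"): bR * aRp,
            },
            removed_params=(aAp, aRp),
        ),
    }


_METADATA = {
    "big": BenchmarkMetadata(5, 3, 1, 200, 0.02, 0.02),
    "celldiv": BenchmarkMetadata(8, 6, 2, 20, 0.02, 0.10),
    "circad": BenchmarkMetadata(15, 9, 3, 30, 0.02, 0.10),
    # measured with real data in the original study; synthetic replacement here
    "jakstat": BenchmarkMetadata(6, 4, 2, 16, 0.02, 0.10),
}

_HORIZONS = {"big": 120.0, "celldiv": 100.0, "circad": 100.0, "jakstat": 60.0}

_SOURCES = {
    "big": "glucose-regulation circuit with dynamical compensation (3-state beta-cell/insulin/glucose model)",
    "celldiv": "cdc2-cyclin cell-division-cycle oscillator (6-state)",
    "circad": "activator-repressor circadian gene oscillator (9-state)",
    "jakstat": "JAK-STAT signalling cycle (4-state, scaled STAT units)",
}


def load_benchmark(case_id: str) -> BenchmarkCase:
    """Load one bundled case study by id (big | celldiv | circad | jakstat)."""
    key = _ALIASES.get(str(case_id).lower())
    if key is None:
        raise KeyError(f"unknown benchmark id {case_id!r}; choose from {BENCHMARK_IDS}")
    with resources.files("obsens.fixtures").joinpath(f"{key}.yaml").open() as fh:
        model = load_model(fh)
    meta = _METADATA[key]
    assert model.n_params == meta.n_params and model.n_states == meta.n_states
    assert model.n_outputs == meta.n_observed
    transformation = bundled_transformations().get(key)
    known_truth = {"u": _pulse(2.0, 5.0)} if key == "jakstat" else None
    # meal glucose appearance: slow absorption bump peaking at ~25 min, so the
    # default 10-knot input grid resolves it to below the measurement noise
    unknown_truth = {"w": _pulse(0.3, 25.0)} if key == "big" else None
    return BenchmarkCase(
        id=key,
        original=model,
        transformation=transformation,
        metadata=meta,
        t_end=_HORIZONS[key],
        known_input_truth=known_truth,
        unknown_input_truth=unknown_truth,
        source=_SOURCES[key],
    )
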