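import numpy as np
import pytest
import sympy as sp

from obsens.models import ODEModel


@pytest.fixture(scope="session")
def decay_model():
    """1-state exponential decay: dx/dt = -theta*x, y = x."""
    x, th = sp.symbols("x theta")
    return ODEModel(
        "decay", states=(x,), params=(th,), rhs=(-th * x,), outputs=(x,),
        x0={x: 1.0}, nominal={th: 1.0},
    )


class FunctionProblem:
    """Adapter exposing a plain test function through the estimation-problem
    surface used by the optimizer (bounds, nll, dim)."""

    def __init__(self, fun, bounds, log_scale=None):
        self.fun = fun
        self.bounds = np.asarray(bounds, dtype=float)
        self.log_mask = np.zeros(self.bounds.shape[0], dtype=bool)
        self.estimate_noise = True  # polish via Nelder-Mead on the objective
        self.decision_names = [f"x{i}" for i in range(self.bounds.shape[0])]

    @property
    def dim(self):
        return self.bounds.shape[0]

    def nll(self, v):
        return float(self.fun(np.asarray(v, dtype=float)))


@pytest.fixture
def function_problem():
    return FunctionProblem
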