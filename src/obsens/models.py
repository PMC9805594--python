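"""Symbolic definition and numerical simulation of kinetic ODE models.

A model is a deterministic ODE system

    dx/dt = f(x, theta, u(t), w(t)),    y = g(x, theta, u(t), w(t)),

where ``f`` and ``g`` are rational functions of the states ``x``, the constant
parameters ``theta``, known (measured) inputs ``u`` and unknown (unmeasured)
inputs ``w``.  Outputs ``y`` are the measurable quantities.

This module provides the :class:`ODEModel` container, numerical simulation via
stiff-capable variable-step integrators, symbolic reparameterization (state /
parameter / input substitutions that remove redundant parameters), and the
state augmentation used by observability analysis (states + parameters +
unknown-input derivatives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "TIME",
    "ODEModel",
    "Trajectory",
    "Reparameterization",
    "PiecewiseLinearInput",
    "ModelValidationError",
    "SimulationError",
    "simulate",
    "apply_reparameterization",
    "augment_for_fispo",
    "load_model",
    "save_model",
]

#: The independent (time) variable shared by every model.
TIME = sp.Symbol("t")

# Default integrator settings; oscillatory and stiff benchmark regimes need a
# stiff-capable variable-step method and tight tolerances.
DEFAULT_METHOD = "LSODA"
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class ModelValidationError(ValueError):
    """A model definition violates the model-class contract."""


class SimulationError(RuntimeError):
    """Numerical integration failed (stiffness, blow-up, bad inputs)."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


def _as_symbols(names: Sequence[str | sp.Symbol]) -> tuple[sp.Symbol, ...]:
    return tuple(sp.Symbol(n) if isinstance(n, str) else n for n in names)


@dataclass(frozen=True)
class ODEModel:
    """Symbolic ODE model with rational right-hand sides and outputs.

    Parameters
    ----------
    name:
        Identifier for reports and file names.
    states, params, known_inputs, unknown_inputs:
        Ordered, pairwise-disjoint symbol tuples.
    rhs:
        One rational expression per state, in the declared symbols and time.
    outputs:
        Rational output expressions (the observation map ``g``).
    x0:
        Initial condition per state: a number, or ``None`` when the initial
        condition is unknown and must be estimated.
    nominal:
        Optional ground-truth parameter values (used by synthetic studies).
    """

    name: str
    states: tuple[sp.Symbol, ...]
    params: tuple[sp.Symbol, ...]
    rhs: tuple[sp.Expr, ...]
    outputs: tuple[sp.Expr, ...]
    known_inputs: tuple[sp.Symbol, ...] = ()
    unknown_inputs: tuple[sp.Symbol, ...] = ()
    x0: Mapping[sp.Symbol, float | None] = field(default_factory=dict)
    nominal: Mapping[sp.Symbol, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "states", _as_symbols(self.states))
        object.__setattr__(self, "params", _as_symbols(self.params))
        object.__setattr__(self, "known_inputs", _as_symbols(self.known_inputs))
        object.__setattr__(self, "unknown_inputs", _as_symbols(self.unknown_inputs))
        object.__setattr__(self, "rhs", tuple(sp.sympify(e) for e in self.rhs))
        object.__setattr__(self, "outputs", tuple(sp.sympify(e) for e in self.outputs))
        object.__setattr__(
            self, "x0", {sp.Symbol(k) if isinstance(k, str) else k: v for k, v in dict(self.x0).items()}
        )
        object.__setattr__(
            self, "nominal", {sp.Symbol(k) if isinstance(k, str) else k: v for k, v in dict(self.nominal).items()}
        )
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        groups = [self.states, self.params, self.known_inputs, self.unknown_inputs]
        flat = [s for g in groups for s in g]
        if len(set(flat)) != len(flat):
            raise ModelValidationError(
                f"{self.name}: state/parameter/input symbol sets must be pairwise disjoint"
            )
        if len(self.rhs) != len(self.states):
            raise ModelValidationError(
                f"{self.name}: {len(self.rhs)} equations for {len(self.states)} states"
            )
        declared = set(flat) | {TIME}
        for label, exprs in (("rhs", self.rhs), ("output", self.outputs)):
            for e in exprs:
                undeclared = e.free_symbols - declared
                if undeclared:
                    raise ModelValidationError(
                        f"{self.name}: undeclared symbols {sorted(map(str, undeclared))} in {label} {e}"
                    )
                syms = list(e.free_symbols - {TIME})
                if syms and not e.is_rational_function(*syms):
                    raise ModelValidationError(
                        f"{self.name}: {label} expression {e} is not rational in the model symbols"
                    )

    # -- conveniences -------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    @property
    def n_known_inputs(self) -> int:
        return len(self.known_inputs)

    @property
    def n_unknown_inputs(self) -> int:
        return len(self.unknown_inputs)

    def nominal_theta(self) -> np.ndarray:
        try:
            return np.array([float(self.nominal[p]) for p in self.params])
        except KeyError as err:
            raise ModelValidationError(f"{self.name}: no nominal value for {err.args[0]}") from None

    def nominal_x0(self) -> np.ndarray:
        vals = []
        for s in self.states:
            v = self.x0.get(s)
            if v is None:
                v = self.nominal.get(s)
            if v is None:
                raise ModelValidationError(f"{self.name}: no numeric initial condition for {s}")
            vals.append(float(sp.sympify(v).subs(self.nominal)) if isinstance(v, sp.Expr) else float(v))
        return np.array(vals)

    def unknown_x0_states(self) -> tuple[sp.Symbol, ...]:
        """States whose initial condition is not fixed numerically."""
        return tuple(s for s in self.states if self.x0.get(s) is None)

    def with_(self, **changes) -> "ODEModel":
        return replace(self, **changes)

    def __repr__(self) -> str:  # compact; the dataclass default is unwieldy
        return (
            f"ODEModel({self.name!r}, n_x={self.n_states}, n_theta={self.n_params}, "
            f"n_u={self.n_known_inputs}, n_w={self.n_unknown_inputs}, n_y={self.n_outputs})"
        )


@dataclass(frozen=True)
class Trajectory:
    """Simulated states and outputs on a time grid."""

    times: np.ndarray
    states: np.ndarray  # (n_t, n_x)
    outputs: np.ndarray  # (n_t, n_y)

    def to_frame(self, model: ODEModel):
        import pandas as pd

        cols = {"time": self.times}
        for i, s in enumerate(model.states):
            cols[str(s)] = self.states[:, i]
        for j in range(self.outputs.shape[1]):
            cols[f"y{j + 1}"] = self.outputs[:, j]
        return pd.DataFrame(cols)


class PiecewiseLinearInput:
    """Piecewise-linear time function defined by knot times and values.

    Used both for known inputs and for parameterizing an unknown input during
    estimation (the knot values then enter the decision vector).
    """

    def __init__(self, knot_times: Sequence[float], knot_values: Sequence[float]):
        self.knot_times = np.asarray(knot_times, dtype=float)
        self.knot_values = np.asarray(knot_values, dtype=float)
        if self.knot_times.ndim != 1 or self.knot_times.shape != self.knot_values.shape:
            raise ValueError("knot times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.knot_times) <= 0):
            raise ValueError("knot times must be strictly increasing")

    def __call__(self, t):
        return np.interp(t, self.knot_times, self.knot_values)


def _input_callables(symbols, supplied, kind: str):
    funcs = []
    supplied = dict(supplied or {})
    supplied = {(sp.Symbol(k) if isinstance(k, str) else k): v for k, v in supplied.items()}
    for s in symbols:
        if s not in supplied:
            raise SimulationError(f"missing {kind} input function for {s}")
        v = supplied[s]
        funcs.append((lambda c: (lambda t: c))(float(v)) if np.isscalar(v) else v)
    return funcs


def _compiled(model: ODEModel):
    """Lambdified (f, g) cached on the model instance itself (the dataclass is
    frozen, so the cache cannot go stale)."""
    cache = getattr(model, "_compiled_cache", None)
    if cache is None:
        args = (TIME, model.states, model.params, model.known_inputs, model.unknown_inputs)
        f = sp.lambdify(args, model.rhs, modules="numpy")
        g = sp.lambdify(args, model.outputs, modules="numpy")
        cache = (f, g)
        object.__setattr__(model, "_compiled_cache", cache)
    return cache


def simulate(
    model: ODEModel,
    theta: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    times: np.ndarray | None = None,
    inputs: Mapping | None = None,
    w: Mapping | None = None,
    method: str = DEFAULT_METHOD,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the model and return states and outputs on ``times``.

    ``theta``/``x0`` default to the model's nominal values.  ``inputs`` and
    ``w`` map input symbols to callables of time (or constants).  The result is
    deterministic for fixed inputs and tolerances.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    theta = model.nominal_theta() if theta is None else np.asarray(theta, dtype=float)
    x0 = model.nominal_x0() if x0 is None else np.asarray(x0, dtype=float)
    if theta.shape != (model.n_params,):
        raise ValueError(f"theta has shape {theta.shape}, expected ({model.n_params},)")
    if x0.shape != (model.n_states,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({model.n_states},)")

    u_funcs = _input_callables(model.known_inputs, inputs, "known")
    w_funcs = _input_callables(model.unknown_inputs, w, "unknown")
    f, g = _compiled(model)

    def odefun(t, x):
        # finite-time blow-up: feed NaN so the solver fails fast instead of
        # grinding with ever-smaller steps
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e50:
            return np.full(x.shape, np.nan)
        uv = [fn(t) for fn in u_funcs]
        wv = [fn(t) for fn in w_funcs]
        return f(t, x, theta, uv, wv)

    t0, tf = float(times[0]), float(times[-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LSODA chatter on hard problems
        sol = solve_ivp(
            odefun, (t0, tf), x0, method=method, t_eval=times, rtol=rtol, atol=atol
        )
    if not sol.success or sol.y.shape[1] != times.size:
        t_fail = float(sol.t[-1]) if sol.t.size else t0
        raise SimulationError(
            f"{model.name}: integration failed near t={t_fail:.6g}: {sol.message}", time=t_fail
        )
    X = sol.y.T
    if not np.all(np.isfinite(X)):
        raise SimulationError(f"{model.name}: non-finite states in solution")
    Y = np.empty((times.size, model.n_outputs))
    for i, t in enumerate(times):
        uv = [fn(t) for fn in u_funcs]
        wv = [fn(t) for fn in w_funcs]
        Y[i] = g(t, X[i], theta, uv, wv)
    if not np.all(np.isfinite(Y)):
        raise SimulationError(f"{model.name}: non-finite outputs in solution")
    return Trajectory(times=times, states=X, outputs=Y)


# ---------------------------------------------------------------------------
# Reparameterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reparameterization:
    """Invertible state/parameter/input substitutions that remove parameters.

    ``new_states`` maps an old state symbol to ``(new_symbol, expr)`` where
    ``expr`` defines the new state in terms of old states and parameters
    (e.g. ``x3 -> (x3s, x3*p)``).  ``new_params`` maps a new (merged) parameter
    symbol to its definition in old parameters (e.g. ``q5 -> p2*p5``).
    ``new_inputs`` similarly redefines unknown inputs in terms of the old input,
    states, and parameters.  ``removed_params`` must disappear entirely from the
    transformed equations; a substitution leaving one behind is rejected.
    """

    name: str = ""
    new_states: Mapping[sp.Symbol, tuple[sp.Symbol, sp.Expr]] = field(default_factory=dict)
    new_params: Mapping[sp.Symbol, sp.Expr] = field(default_factory=dict)
    new_inputs: Mapping[sp.Symbol, tuple[sp.Symbol, sp.Expr]] = field(default_factory=dict)
    removed_params: tuple[sp.Symbol, ...] = ()


def apply_reparameterization(model: ODEModel, repar: Reparameterization) -> ODEModel:
    """Return the transformed model; outputs are preserved by construction.

    The new state variables are ``z_i = phi_i(x, theta)``; their dynamics are
    obtained by the chain rule and rewritten in the new variables, with merged
    parameters substituted and removed parameters required to cancel.
    """
    new_states: list[sp.Symbol] = []
    forward: dict[sp.Symbol, sp.Expr] = {}  # new symbol -> definition in old vars
    for s in model.states:
        if s in repar.new_states:
            z, expr = repar.new_states[s]
            new_states.append(z)
            forward[z] = sp.sympify(expr)
        else:
            new_states.append(s)
            forward[s] = s

    # Invert the state map: old states in terms of new symbols (+ old params).
    eqs = [sp.Eq(z, expr) for z, expr in forward.items() if z is not expr]
    transformed_old = list(repar.new_states.keys())
    if eqs:
        sol = sp.solve(eqs, transformed_old, dict=True)
        if not sol:
            raise ModelValidationError(f"{repar.name}: state substitutions are not invertible")
        old_in_new = sol[0]
    else:
        old_in_new = {}

    # Invert the parameter map: solve definitions of merged parameters for the
    # surviving old parameters (removed ones are expected to cancel later).
    kept_old = [p for p in model.params if p not in repar.removed_params]
    param_sub: dict[sp.Symbol, sp.Expr] = {}
    if repar.new_params:
        peqs = [sp.Eq(q, sp.sympify(e)) for q, e in repar.new_params.items()]
        targets = [p for p in kept_old if any(p in sp.sympify(e).free_symbols for e in repar.new_params.values())]
        psol = sp.solve(peqs, targets, dict=True)
        if not psol:
            raise ModelValidationError(f"{repar.name}: parameter substitutions are not invertible")
        param_sub = psol[0]

    # Unknown-input redefinition: w_old in terms of w_new, states, parameters.
    input_sub: dict[sp.Symbol, sp.Expr] = {}
    new_inputs: list[sp.Symbol] = []
    for wsym in model.unknown_inputs:
        if wsym in repar.new_inputs:
            wz, expr = repar.new_inputs[wsym]
            isol = sp.solve(sp.Eq(wz, sp.sympify(expr)), wsym)
            if not isol:
                raise ModelValidationError(f"{repar.name}: input substitution not invertible")
            input_sub[wsym] = isol[0]
            new_inputs.append(wz)
        else:
            new_inputs.append(wsym)

    def rewrite(expr: sp.Expr) -> sp.Expr:
        e = expr.subs(input_sub).subs(old_in_new).subs(param_sub)
        return sp.cancel(sp.together(e))

    new_rhs = []
    for z in new_states:
        phi = forward[z]
        zdot = sum(sp.diff(phi, xs) * f for xs, f in zip(model.states, model.rhs))
        new_rhs.append(rewrite(zdot))
    new_outputs = [rewrite(g) for g in model.outputs]

    new_param_syms = tuple(p for p in kept_old if p not in param_sub) + tuple(
        repar.new_params.keys()
    )
    leftover = set()
    for e in list(new_rhs) + list(new_outputs):
        leftover |= e.free_symbols & set(repar.removed_params)
        leftover |= e.free_symbols & (set(model.params) - set(kept_old) - set(repar.removed_params))
    # also reject surviving old parameters that were merged away
    merged_away = {p for p in kept_old if p in param_sub}
    for e in list(new_rhs) + list(new_outputs):
        leftover |= e.free_symbols & merged_away
    if leftover:
        raise ModelValidationError(
            f"{repar.name}: removed/merged parameters {sorted(map(str, leftover))} "
            "remain in the transformed equations"
        )

    # Transform initial conditions and nominal values consistently.
    nominal_full = {**model.nominal}
    new_x0: dict[sp.Symbol, float | None] = {}
    for old, z in zip(model.states, new_states):
        v_old = model.x0.get(old)
        if z is old:
            new_x0[z] = v_old
            continue
        if v_old is None:
            new_x0[z] = None
        else:
            expr0 = forward[z].subs({s: model.x0.get(s) for s in model.states if model.x0.get(s) is not None})
            expr0 = sp.sympify(expr0).subs(nominal_full)
            new_x0[z] = float(expr0) if not expr0.free_symbols else None
    new_nominal: dict[sp.Symbol, float] = {}
    for p in kept_old:
        if p not in param_sub and p in nominal_full:
            new_nominal[p] = nominal_full[p]
    for q, e in repar.new_params.items():
        val = sp.sympify(e).subs(nominal_full)
        if not val.free_symbols:
            new_nominal[q] = float(val)

    return ODEModel(
        name=f"{model.name}_repar" if not repar.name else f"{model.name}_{repar.name}",
        states=tuple(new_states),
        params=new_param_syms,
        rhs=tuple(new_rhs),
        outputs=tuple(new_outputs),
        known_inputs=model.known_inputs,
        unknown_inputs=tuple(new_inputs),
        x0=new_x0,
        nominal=new_nominal,
    )


# ---------------------------------------------------------------------------
# Augmentation for observability analysis
# ---------------------------------------------------------------------------


def augment_for_fispo(model: ODEModel, w_derivative_order: int = 1) -> ODEModel:
    """Append parameters and unknown-input derivatives to the state vector.

    The augmented state is ``(x, theta, w, w', ..., w^(order))`` with
    ``theta' = 0`` and the derivative of the highest unknown-input derivative
    set to zero (finite truncation).  The augmented model has no parameters;
    known inputs are retained.
    """
    if w_derivative_order < 0:
        raise ValueError("w_derivative_order must be non-negative")
    aug_states = list(model.states) + list(model.params)
    aug_rhs = list(model.rhs) + [sp.Integer(0)] * model.n_params
    for wsym in model.unknown_inputs:
        chain = [wsym] + [sp.Symbol(f"{wsym}_d{k}") for k in range(1, w_derivative_order + 1)]
        aug_states.extend(chain)
        aug_rhs.extend(chain[1:] + [sp.Integer(0)])
    return ODEModel(
        name=f"{model.name}_aug",
        states=tuple(aug_states),
        params=(),
        rhs=tuple(aug_rhs),
        outputs=model.outputs,
        known_inputs=model.known_inputs,
        unknown_inputs=(),
        x0={s: None for s in aug_states},
        nominal={},
    )


# ---------------------------------------------------------------------------
# Declarative model files
# ---------------------------------------------------------------------------


def _parse_expr(text, local: dict) -> sp.Expr:
    return sp.sympify(text, locals=local, rational=True)


def load_model(source) -> ODEModel:
    """Read a model from a declarative YAML file (path, stream, or dict)."""
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    names = {
        "states": doc.get("states", []),
        "parameters": doc.get("parameters", []),
        "known_inputs": doc.get("known_inputs", []),
        "unknown_inputs": doc.get("unknown_inputs", []),
    }
    local = {n: sp.Symbol(n) for grp in names.values() for n in grp}
    local["t"] = TIME
    rhs = tuple(_parse_expr(doc["rhs"][s], local) for s in names["states"])
    outputs = tuple(_parse_expr(e, local) for e in doc["outputs"])
    x0 = {sp.Symbol(k): (None if v is None else float(v)) for k, v in (doc.get("x0") or {}).items()}
    nominal = {sp.Symbol(k): float(v) for k, v in (doc.get("nominal") or {}).items()}
    return ODEModel(
        name=doc.get("name", "model"),
        states=_as_symbols(names["states"]),
        params=_as_symbols(names["parameters"]),
        known_inputs=_as_symbols(names["known_inputs"]),
        unknown_inputs=_as_symbols(names["unknown_inputs"]),
        rhs=rhs,
        outputs=outputs,
        x0=x0,
        nominal=nominal,
    )


def save_model(model: ODEModel, path) -> None:
    doc = {
        "name": model.name,
        "states": [str(s) for s in model.states],
        "parameters": [str(p) for p in model.params],
        "known_inputs": [str(u) for u in model.known_inputs],
        "unknown_inputs": [str(w) for w in model.unknown_inputs],
        "rhs": {str(s): str(e) for s, e in zip(model.states, model.rhs)},
        "outputs": [str(e) for e in model.outputs],
        "x0": {str(s): (None if v is None else float(v)) for s, v in model.x0.items()},
        "nominal": {str(s): float(v) for s, v in model.nominal.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
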