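"""Objective function and archiving hybrid global optimization.

The calibration objective is the exact negative log-likelihood for independent
Gaussian measurement noise,

    -log L = sum_ij [ log(sigma_ij * sqrt(2*pi)) + (y~_ij - y_ij)^2 / (2 sigma_ij^2) ],

evaluated by simulating the model (single shooting).  The decision vector is,
in order: model parameters, unknown initial conditions, unknown-input knot
values (piecewise-linear parameterization), and optionally the noise terms
(sigma_abs, sigma_rel).

The optimizer is an enhanced-scatter-search-style metaheuristic: Latin
hypercube diversification, a small reference set recombined by hyper-rectangle
sampling between member pairs, a go-beyond intensification rule, and periodic
derivative-free local polish.  Every objective evaluation is archived with its
decision vector; the archive — not just the best fit — is the raw material for
ensemble selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .data import Dataset, SIGMA_FLOOR
from .models import ODEModel, PiecewiseLinearInput, SimulationError, simulate

__all__ = [
    "EstimationProblem",
    "ParameterArchive",
    "ESSResult",
    "negative_log_likelihood",
    "ess_optimize",
]

PENALTY = 1e10  # archived value for failed simulations; excluded from ensembles

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ParameterArchive:
    """Every decision vector evaluated during optimization, with its value."""

    vectors: list = field(default_factory=list)
    values: list = field(default_factory=list)
    failed: list = field(default_factory=list)

    def record(self, x: np.ndarray, value: float, failed: bool = False) -> None:
        self.vectors.append(np.array(x, dtype=float))
        self.values.append(float(value))
        self.failed.append(bool(failed))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.values))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.array(self.vectors, dtype=float),
            np.array(self.values, dtype=float),
            np.array(self.failed, dtype=bool),
        )

    def to_frame(self, names: Sequence[str]):
        import pandas as pd

        X, v, bad = self.as_arrays()
        df = pd.DataFrame(X, columns=list(names))
        df.insert(0, "value", v)
        df["failed"] = bad
        return df


class EstimationProblem:
    """Bundles a model, a dataset and the decision-vector layout.

    Parameters
    ----------
    model, dataset:
        The model to calibrate and the measurements (with per-point sigma).
    bounds:
        Mapping name -> (lo, hi) for any decision component; parameters without
        explicit bounds default to nominal * [1e-2, 1e2].
    estimate_x0:
        State symbols/names whose initial condition joins the decision vector.
    n_w_knots:
        Number of knots of the piecewise-linear unknown-input parameterization
        (per unknown input); knots are uniform over the measurement horizon.
    estimate_noise:
        When true, sigma_abs and sigma_rel are appended to the decision vector
        and sigma_ij = sigma_abs + sigma_rel*y_ij is rebuilt from the model
        output; otherwise the dataset sigma is used directly.
    log_scale:
        Names searched in log10 space (default: all model parameters).
    """

    def __init__(
        self,
        model: ODEModel,
        dataset: Dataset,
        bounds: Mapping | None = None,
        estimate_x0: Sequence = (),
        n_w_knots: int = 10,
        estimate_noise: bool = False,
        known_inputs: Mapping | None = None,
        log_scale: Sequence[str] | None = None,
        x0_defaults: np.ndarray | None = None,
        sim_rtol: float = 1e-8,
        sim_atol: float = 1e-10,
    ):
        self.model = model
        self.dataset = dataset
        self.sim_rtol = float(sim_rtol)
        self.sim_atol = float(sim_atol)
        self.estimate_noise = bool(estimate_noise)
        self.known_inputs = known_inputs
        self.n_w_knots = int(n_w_knots)
        self._x0_base = model.nominal_x0() if x0_defaults is None else np.asarray(x0_defaults, float)

        self.param_names = [str(p) for p in model.params]
        self.x0_names = [str(s) for s in estimate_x0]
        self._x0_idx = [
            [str(s) for s in model.states].index(n) for n in self.x0_names
        ]
        self.w_names: list[str] = []
        t0, tf = float(dataset.times[0]), float(dataset.times[-1])
        self.w_knot_times = np.linspace(t0, tf, self.n_w_knots) if model.unknown_inputs else None
        for wsym in model.unknown_inputs:
            self.w_names += [f"{wsym}_k{k}" for k in range(self.n_w_knots)]
        self.noise_names = ["sigma_abs", "sigma_rel"] if estimate_noise else []
        self.decision_names = self.param_names + self.x0_names + self.w_names + self.noise_names

        bounds = {str(k): v for k, v in (bounds or {}).items()}
        self.bounds = np.empty((len(self.decision_names), 2))
        nominal = {str(p): v for p, v in model.nominal.items()}
        for i, name in enumerate(self.decision_names):
            if name in bounds:
                self.bounds[i] = bounds[name]
            elif name in nominal and nominal[name] > 0:
                self.bounds[i] = (nominal[name] * 1e-2, nominal[name] * 1e2)
            elif name in self.x0_names:
                base = self._x0_base[self._x0_idx[self.x0_names.index(name)]]
                self.bounds[i] = (base * 0.1, base * 10.0) if base > 0 else (0.0, 1.0)
            elif name in self.w_names:
                self.bounds[i] = (0.0, 10.0)
            elif name in self.noise_names:
                self.bounds[i] = (1e-6, 1.0)
            else:
                raise ValueError(f"no bounds for decision component {name!r}")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("bounds must satisfy lo < hi")

        if log_scale is None:
            log_scale = [n for n in self.param_names if self.bounds[self.decision_names.index(n), 0] > 0]
        self.log_mask = np.array([n in set(log_scale) for n in self.decision_names])
        if np.any(self.log_mask & (self.bounds[:, 0] <= 0)):
            raise ValueError("log-scale components need strictly positive lower bounds")

    # -- layout -------------------------------------------------------------
    @property
    def dim(self) -> int:
        return len(self.decision_names)

    def split(self, v: np.ndarray):
        n_p, n_i, n_w = len(self.param_names), len(self.x0_names), len(self.w_names)
        theta = v[:n_p]
        x0 = self._x0_base.copy()
        x0[self._x0_idx] = v[n_p : n_p + n_i]
        w_funcs = None
        if self.model.unknown_inputs:
            w_funcs = {}
            vals = v[n_p + n_i : n_p + n_i + n_w].reshape(len(self.model.unknown_inputs), -1)
            for wsym, kv in zip(self.model.unknown_inputs, vals):
                w_funcs[wsym] = PiecewiseLinearInput(self.w_knot_times, kv)
        noise = v[n_p + n_i + n_w :] if self.estimate_noise else None
        return theta, x0, w_funcs, noise

    # -- objective ----------------------------------------------------------
    def simulate_decision(self, v: np.ndarray):
        theta, x0, w_funcs, _ = self.split(np.asarray(v, dtype=float))
        return simulate(
            self.model, theta=theta, x0=x0, times=self.dataset.times,
            inputs=self.known_inputs, w=w_funcs,
            rtol=self.sim_rtol, atol=self.sim_atol,
        )

    def _sigma(self, v, y_model):
        if not self.estimate_noise:
            return self.dataset.sigma
        sabs, srel = v[-2], v[-1]
        return np.maximum(sabs + srel * y_model, SIGMA_FLOOR)

    def nll(self, v: np.ndarray) -> float:
        v = np.asarray(v, dtype=float)
        traj = self.simulate_decision(v)
        sigma = self._sigma(v, traj.outputs)
        if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
            raise ValueError("non-finite or non-positive sigma in likelihood")
        r = (self.dataset.y - traj.outputs) / sigma
        return float(np.sum(np.log(sigma * math.sqrt(2.0 * math.pi))) + 0.5 * np.sum(r * r))

    def residuals(self, v: np.ndarray) -> np.ndarray:
        """Weighted residual vector; the NLL is const + 0.5*||r||^2 when the
        noise model is fixed."""
        traj = self.simulate_decision(v)
        return ((self.dataset.y - traj.outputs) / self.dataset.sigma).ravel()


def negative_log_likelihood(decision: np.ndarray, problem: EstimationProblem) -> float:
    """Exact Gaussian NLL of a decision vector; penalty on simulation failure."""
    if np.asarray(decision, dtype=float).shape != (problem.dim,):
        raise ValueError(f"decision vector must have length {problem.dim}")
    try:
        return problem.nll(decision)
    except SimulationError:
        return PENALTY


@dataclass
class ESSResult:
    best_x: np.ndarray
    best_f: float
    archive: ParameterArchive
    n_evaluations: int


def ess_optimize(
    problem: EstimationProblem,
    budget: int,
    seed: int = 0,
    local_search: bool = True,
    refset_size: int = 10,
    n_diverse: int | None = None,
    local_every: int = 4,
    combination_spread: float = 0.3,
) -> ESSResult:
    """Enhanced-scatter-search-style global optimization with a full archive.

    Deterministic for a fixed seed and budget.  Out-of-bounds candidates are
    clipped to the feasible box before simulation, so the archive stays inside
    the bounds the ensemble-selection interval logic assumes.  Failed
    simulations are archived with a large finite penalty and flagged.
    """
    d = problem.dim
    lo, hi = problem.bounds[:, 0].copy(), problem.bounds[:, 1].copy()
    lmask = problem.log_mask
    zlo, zhi = lo.copy(), hi.copy()
    zlo[lmask], zhi[lmask] = np.log10(lo[lmask]), np.log10(hi[lmask])

    def to_nat(z):
        x = z.copy()
        x[lmask] = 10.0 ** x[lmask]
        return x

    rng = np.random.default_rng(seed)
    archive = ParameterArchive()
    state = {"best_f": np.inf, "best_z": None}

    def evaluate(z) -> float:
        z = np.clip(z, zlo, zhi)
        x = to_nat(z)
        try:
            f = problem.nll(x)
            ok = np.isfinite(f)
        except (SimulationError, FloatingPointError, ValueError):
            f, ok = PENALTY, False
        if not ok:
            f = PENALTY
        archive.record(x, f, failed=not ok)
        if f < state["best_f"]:
            state["best_f"], state["best_z"] = f, z.copy()
        return f

    def remaining() -> int:
        return budget - len(archive)

    # --- diversification: Latin hypercube over the (scaled) box -------------
    n_div = int(n_diverse) if n_diverse is not None else max(10 * d, refset_size * 2)
    n_div = min(n_div, max(budget - refset_size, refset_size * 2))
    sampler = qmc.LatinHypercube(d=d, seed=int(rng.integers(2**31 - 1)))
    Z = zlo + sampler.random(n_div) * (zhi - zlo)
    fvals = np.array([evaluate(z) for z in Z])
    if np.all(fvals >= PENALTY):
        raise SimulationError("all initial simulations failed; check bounds and inputs")

    # --- reference set: half best, half maximally diverse --------------------
    order = np.argsort(fvals)
    n_best = refset_size // 2
    ref_idx = list(order[:n_best])
    span = zhi - zlo
    for _ in range(refset_size - n_best):
        cand = [i for i in range(n_div) if i not in ref_idx]
        dmin = [
            min(np.linalg.norm((Z[i] - Z[j]) / span) for j in ref_idx) for i in cand
        ]
        ref_idx.append(cand[int(np.argmax(dmin))])
    ref_z = [Z[i].copy() for i in ref_idx]
    ref_f = [float(fvals[i]) for i in ref_idx]

    def try_replace(z, f):
        worst = int(np.argmax(ref_f))
        if f >= ref_f[worst]:
            return False
        # keep the reference set spread out: a candidate close to an existing
        # member may only replace that member (if better), never a distant one
        dists = [np.linalg.norm((z - other) / span) for other in ref_z]
        nearest = int(np.argmin(dists))
        if dists[nearest] < 1e-3:
            if f < ref_f[nearest]:
                ref_z[nearest], ref_f[nearest] = z.copy(), float(f)
            return False  # no diversity gained; don't reset stagnation
        ref_z[worst], ref_f[worst] = z.copy(), float(f)
        return True

    def polish_key(z) -> tuple:
        return tuple(np.round((z - zlo) / span, 2))

    sweeps = 0
    stagnation = 0
    polished: set[tuple] = set()
    while remaining() > 0:
        sweeps += 1
        improved = False
        pairs = [(i, j) for i in range(len(ref_z)) for j in range(i + 1, len(ref_z))]
        for i, j in pairs:
            if remaining() <= 0:
                break
            zi, zj = ref_z[i], ref_z[j]
            u = rng.uniform(-combination_spread, 1.0 + combination_spread, size=d)
            child = np.clip(zi + (zj - zi) * u, zlo, zhi)
            f_child = evaluate(child)
            parent_f = min(ref_f[i], ref_f[j])
            if f_child < parent_f:
                # go-beyond: keep stepping while the direction pays off
                step = child - (zi if ref_f[i] <= ref_f[j] else zj)
                cur, cur_f = child, f_child
                for _ in range(2):
                    if remaining() <= 0:
                        break
                    nxt = np.clip(cur + step, zlo, zhi)
                    f_nxt = evaluate(nxt)
                    if f_nxt >= cur_f:
                        break
                    cur, cur_f = nxt, f_nxt
                    step *= 2.0
                if try_replace(cur, cur_f):
                    improved = True
            elif try_replace(child, f_child):
                improved = True

        # sustained diversification: a few fresh uniform points per sweep keep
        # the archive sampling regions away from the current basins
        for _ in range(max(2, d // 4)):
            if remaining() <= 0:
                break
            evaluate(zlo + rng.uniform(0.0, 1.0, size=d) * span)
        stagnation = 0 if improved else stagnation + 1

        if local_search and sweeps % local_every == 0 and remaining() > (d + 2):
            # polish the best not-yet-polished reference member, so local
            # refinement spreads over basins instead of re-grinding the incumbent
            order = np.argsort(ref_f)
            start = None
            for k in order:
                if polish_key(ref_z[k]) not in polished:
                    start = ref_z[k].copy()
                    polished.add(polish_key(start))
                    break
            if start is not None:
                z_best, f_best = _local_polish(
                    problem, archive, state, zlo, zhi, to_nat, remaining, evaluate, start
                )
                if z_best is not None:
                    polished.add(polish_key(z_best))  # don't re-polish the result
                    try_replace(z_best, f_best)
        if stagnation >= 3 and remaining() > refset_size:
            # diversification restart of the worst half
            sampler = qmc.LatinHypercube(d=d, seed=int(rng.integers(2**31 - 1)))
            fresh = zlo + sampler.random(refset_size // 2) * (zhi - zlo)
            worst_half = list(np.argsort(ref_f)[-(refset_size // 2):])
            for k, z in zip(worst_half, fresh):
                if remaining() <= 0:
                    break
                ref_z[k], ref_f[k] = z.copy(), evaluate(z)
            stagnation = 0

    best_idx = archive.best_index
    return ESSResult(
        best_x=np.array(archive.vectors[best_idx]),
        best_f=float(archive.values[best_idx]),
        archive=archive,
        n_evaluations=len(archive),
    )


def _local_polish(problem, archive, state, zlo, zhi, to_nat, remaining, evaluate, z0):
    """Derivative-free local refinement from ``z0``, every evaluation archived.

    Least-squares on weighted residuals when the noise model is fixed (the NLL
    is then const + 0.5*||r||^2); Nelder-Mead on the NLL when noise parameters
    are part of the decision vector.  Returns the best point found (in scaled
    coordinates) and its objective value.
    """
    d = len(z0)
    if remaining() < 3 * (d + 2):
        return None, np.inf
    local = {"f": np.inf, "z": None}
    if not problem.estimate_noise:
        const = float(np.sum(np.log(problem.dataset.sigma * math.sqrt(2.0 * math.pi))))

        def res(z):
            z = np.clip(z, zlo, zhi)
            x = to_nat(z)
            try:
                r = problem.residuals(x)
                f = const + 0.5 * float(np.dot(r, r))
                archive.record(x, f, failed=False)
                if f < state["best_f"]:
                    state["best_f"], state["best_z"] = f, z.copy()
                if f < local["f"]:
                    local["f"], local["z"] = f, z.copy()
                return r
            except (SimulationError, ValueError):
                archive.record(x, PENALTY, failed=True)
                return np.full(problem.dataset.y.size, 1e3)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            least_squares(
                res, z0, bounds=(zlo, zhi), method="trf", diff_step=1e-3,
                max_nfev=max(3, min(remaining() // (d + 2), 40)),
            )
    else:
        cap = remaining() - 2

        def fun(z):
            f = evaluate(z)
            if f < local["f"]:
                local["f"], local["z"] = f, np.clip(z, zlo, zhi)
            return f

        minimize(
            fun, z0, method="Nelder-Mead",
            options={"maxfev": cap, "xatol": 1e-8, "fatol": 1e-10},
        )
    return local["z"], local["f"]
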