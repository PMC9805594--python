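"""Structural identifiability and observability (FISPO) analysis.

The analysis asks whether parameters, states and unknown inputs of an ODE
model can in principle be inferred from its outputs.  The test is a generic
rank condition: stack time derivatives of the outputs along the vector field
(Lie derivatives), take the Jacobian with respect to the augmented state
(states + parameters + unknown-input derivatives), and compare its generic
rank with the augmented dimension.  Full rank means the model is FISPO
(Fully Input-State-Parameter Observable); rank deficiency localizes to the
variables whose columns can be deleted without decreasing the rank.

Two evaluation routes compute the same rank:

* a symbolic route (:func:`output_lie_derivatives`, :func:`oic_matrix`,
  :func:`generic_rank`) that builds the matrix explicitly — transparent and
  convenient for small models and for tests;
* an exact arithmetic route used by :func:`classify` that evaluates the
  matrix at random points over a prime field via a Taylor/variational
  recursion, avoiding symbolic expression growth on larger models.  Entries of
  the matrix at a point are ``d^k y_j/dt^k`` differentiated with respect to the
  initial augmented state, obtained from Taylor coefficients of the flow and of
  the variational (tangent) system.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np
import sympy as sp

from .models import TIME, ODEModel, augment_for_fispo

__all__ = [
    "FISPOReport",
    "InconclusiveAnalysis",
    "ExpressionBudgetExceeded",
    "output_lie_derivatives",
    "oic_matrix",
    "generic_rank",
    "classify",
    "verify_fispo",
]

_PRIME = (1 << 31) - 1  # Mersenne prime; field for exact generic-rank tests
_LOW, _HIGH = 2, 997  # random rational numerators/denominators drawn here


class InconclusiveAnalysis(RuntimeError):
    """Rank did not stabilize within the derivative budget."""


class ExpressionBudgetExceeded(RuntimeError):
    """Symbolic Lie derivatives grew past the configured node budget."""


@dataclass(frozen=True)
class FISPOReport:
    """Classification of every model variable by the generic rank test."""

    model: str
    rank: int
    n_aug: int
    observable_states: frozenset
    unobservable_states: frozenset
    identifiable_params: frozenset
    unidentifiable_params: frozenset
    observable_inputs: frozenset
    unobservable_inputs: frozenset
    is_fispo: bool
    n_lie_derivatives_used: int

    def summary(self) -> str:
        lines = [
            f"model: {self.model}",
            f"rank {self.rank} of {self.n_aug} "
            + ("(FISPO)" if self.is_fispo else "(not FISPO)"),
            f"Lie derivatives used: {self.n_lie_derivatives_used}",
            f"unidentifiable parameters ({len(self.unidentifiable_params)}): "
            + ", ".join(sorted(map(str, self.unidentifiable_params))),
            f"unobservable states ({len(self.unobservable_states)}): "
            + ", ".join(sorted(map(str, self.unobservable_states))),
        ]
        if self.unobservable_inputs:
            lines.append(
                "unobservable inputs: " + ", ".join(sorted(map(str, self.unobservable_inputs)))
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "rank": self.rank,
            "n_aug": self.n_aug,
            "is_fispo": self.is_fispo,
            "n_lie_derivatives_used": self.n_lie_derivatives_used,
            "observable_states": sorted(map(str, self.observable_states)),
            "unobservable_states": sorted(map(str, self.unobservable_states)),
            "identifiable_params": sorted(map(str, self.identifiable_params)),
            "unidentifiable_params": sorted(map(str, self.unidentifiable_params)),
            "observable_inputs": sorted(map(str, self.observable_inputs)),
            "unobservable_inputs": sorted(map(str, self.unobservable_inputs)),
        }


# ---------------------------------------------------------------------------
# Symbolic route
# ---------------------------------------------------------------------------


def _input_chain(model: ODEModel, order: int) -> dict[sp.Symbol, sp.Symbol]:
    """Derivative symbols for known inputs, treated as differentially
    independent: u, u_d1, ..., with d(u_dk)/dt = u_d(k+1)."""
    chain = {}
    for u in model.known_inputs:
        prev = u
        for k in range(1, order + 1):
            nxt = sp.Symbol(f"{u}_d{k}")
            chain[prev] = nxt
            prev = nxt
        chain[prev] = sp.Integer(0)
    return chain


def output_lie_derivatives(
    model: ODEModel, max_order: int, node_budget: int = 2_000_000
) -> list[list[sp.Expr]]:
    """Successive total time derivatives of the outputs along the dynamics.

    ``model`` must be augmented (parameter-free state).  Element ``k`` of the
    result is the vector of k-th Lie derivatives; element 0 is ``g`` itself.
    """
    if model.params:
        raise ValueError("output_lie_derivatives expects an augmented (parameter-free) model")
    chain = _input_chain(model, max_order + 1)
    levels = [list(model.outputs)]
    for _ in range(max_order):
        nxt = []
        for e in levels[-1]:
            d = sum(sp.diff(e, s) * f for s, f in zip(model.states, model.rhs))
            d += sum(sp.diff(e, u) * du for u, du in chain.items() if u in e.free_symbols)
            d = sp.together(d)
            if sp.count_ops(d) > node_budget:
                raise ExpressionBudgetExceeded(
                    f"Lie derivative exceeded {node_budget} nodes; "
                    "use classify() which evaluates the matrix numerically"
                )
            nxt.append(d)
        levels.append(nxt)
    return levels


def oic_matrix(model: ODEModel, n_derivatives: int, node_budget: int = 2_000_000) -> sp.Matrix:
    """Observability–identifiability matrix: Jacobian of stacked Lie
    derivatives of the outputs with respect to the augmented state.

    Shape is ``((n_derivatives + 1) * n_y, n_aug)``.
    """
    levels = output_lie_derivatives(model, n_derivatives, node_budget=node_budget)
    stacked = sp.Matrix([e for level in levels for e in level])
    return stacked.jacobian(sp.Matrix(list(model.states)))


def generic_rank(matrix: sp.Matrix, seed: int = 0, draws: int = 2, max_retries: int = 10) -> int:
    """Generic (symbolic) rank via exact evaluation at random rational points.

    All free symbols are replaced by independent random rationals with
    numerators and denominators in [2, 997]; the exact rank of the resulting
    rational matrix is computed.  Two independent draws are taken and the
    maximum kept; a draw that hits a pole is retried.
    """
    syms = sorted(matrix.free_symbols, key=str)
    rng = random.Random(seed)
    best = 0
    done = 0
    attempts = 0
    while done < draws:
        attempts += 1
        if attempts > draws + max_retries:
            raise InconclusiveAnalysis("generic_rank: repeated pole hits during substitution")
        subs = {
            s: sp.Rational(rng.randint(_LOW, _HIGH), rng.randint(_LOW, _HIGH)) for s in syms
        }
        try:
            M = matrix.subs(subs)
            if any(not e.is_finite for e in M):
                continue
            best = max(best, M.rank())
        except ZeroDivisionError:
            continue
        done += 1
    return best


# ---------------------------------------------------------------------------
# Exact point-evaluation route (prime-field Taylor/variational recursion)
# ---------------------------------------------------------------------------


def _compile_expr(expr: sp.Expr, index: dict[sp.Symbol, int]):
    """Compile a rational sympy expression to a closure evaluating it over
    GF(p) power series.  ``index`` maps symbols to positions in the value
    environment (a list of series)."""
    p = _PRIME

    def build(e):
        if e.is_Symbol:
            i = index[e]
            return lambda env: env[i]
        if e.is_Integer:
            c = int(e) % p
            return lambda env, c=c: c
        if e.is_Rational:
            c = (int(e.p) % p) * pow(int(e.q) % p, p - 2, p) % p
            return lambda env, c=c: c
        if e.is_Float:
            from fractions import Fraction

            fr = Fraction(str(e))
            c = (fr.numerator % p) * pow(fr.denominator % p, p - 2, p) % p
            return lambda env, c=c: c
        if e.is_Add:
            parts = [build(a) for a in e.args]
            return lambda env: _s_sum([f(env) for f in parts])
        if e.is_Mul:
            parts = [build(a) for a in e.args]

            def mul(env):
                out = 1
                for f in parts:
                    out = _s_mul(out, f(env))
                return out

            return mul
        if e.is_Pow:
            base = build(e.base)
            if not e.exp.is_Integer:
                raise ValueError(f"non-integer exponent in rational expression: {e}")
            k = int(e.exp)

            def power(env, k=k):
                b = base(env)
                if k >= 0:
                    return _s_ipow(b, k)
                return _s_div(1, _s_ipow(b, -k))

            return power
        raise ValueError(f"unsupported operation in rational expression: {e}")

    return build(sp.together(expr))


# -- GF(p) truncated power-series helpers.  A series is a list of ints
# (coefficients mod p); plain ints are scalars (order-0 constants).

def _s_sum(vals):
    series = [v for v in vals if isinstance(v, list)]
    const = sum(v for v in vals if not isinstance(v, list)) % _PRIME
    if not series:
        return const
    n = max(len(s) for s in series)
    out = [0] * n
    out[0] = const
    for s in series:
        for i, c in enumerate(s):
            out[i] = (out[i] + c) % _PRIME
    return out


def _s_mul(a, b):
    p = _PRIME
    if not isinstance(a, list) and not isinstance(b, list):
        return (a * b) % p
    if not isinstance(a, list):
        return [(a * c) % p for c in b]
    if not isinstance(b, list):
        return [(b * c) % p for c in a]
    n = max(len(a), len(b))
    out = [0] * n
    for i, ca in enumerate(a):
        if ca:
            for j in range(min(len(b), n - i)):
                cb = b[j]
                if cb:
                    out[i + j] = (out[i + j] + ca * cb) % p
    return out


def _s_ipow(a, k):
    if k == 0:
        return 1
    out = a
    for _ in range(k - 1):
        out = _s_mul(out, a)
    return out


def _s_div(a, b):
    p = _PRIME
    if not isinstance(b, list):
        if b % p == 0:
            raise ZeroDivisionError
        inv = pow(b % p, p - 2, p)
        return _s_mul(a, inv)
    if b[0] % p == 0:
        raise ZeroDivisionError  # pole at the evaluation point
    n = len(b)
    if not isinstance(a, list):
        a = [a % p] + [0] * (n - 1)
    n = max(len(a), len(b))
    a = a + [0] * (n - len(a))
    b = b + [0] * (n - len(b))
    inv0 = pow(b[0], p - 2, p)
    q = [0] * n
    for m in range(n):
        acc = a[m]
        for i in range(m):
            acc -= q[i] * b[m - i]
        q[m] = (acc % p) * inv0 % p
    return q


def _as_series(v, n):
    if isinstance(v, list):
        return v + [0] * (n - len(v))
    return [v % _PRIME] + [0] * (n - 1)


class _PointEvaluator:
    """Evaluates observability-matrix rows at one random point over GF(p).

    Given the augmented model, computes Taylor coefficients of the flow and of
    the full variational system, from which the rows ``d/dx0 (d^k y/dt^k)``
    follow exactly (mod p).
    """

    def __init__(self, aug: ODEModel, max_order: int, rng: random.Random):
        self.aug = aug
        self.n = len(aug.states)
        self.K = max_order
        p = _PRIME
        index = {s: i for i, s in enumerate(aug.states)}
        # known inputs enter as free time functions: random derivative chains
        self.u_series = {}
        for u in aug.known_inputs:
            vals = [self._rand(rng) for _ in range(self.K + 2)]
            # series of u(t): sum u^(k) t^k / k!
            ser = [vals[k] * pow(math.factorial(k) % p, p - 2, p) % p for k in range(self.K + 2)]
            index[u] = self.n + len(self.u_series)
            self.u_series[u] = ser
        self.index = index
        J = sp.Matrix(list(aug.rhs)).jacobian(sp.Matrix(list(aug.states)))
        G = sp.Matrix(list(aug.outputs)).jacobian(sp.Matrix(list(aug.states)))
        self.f_fns = [_compile_expr(e, index) for e in aug.rhs]
        self.J_fns = [[_compile_expr(J[i, j], index) for j in range(self.n)] for i in range(self.n)]
        self.G_fns = [[_compile_expr(G[i, j], index) for j in range(self.n)] for i in range(aug.n_outputs)]
        self.x0 = [self._rand(rng) for _ in range(self.n)]

    @staticmethod
    def _rand(rng):
        p = _PRIME
        num = rng.randint(_LOW, _HIGH)
        den = rng.randint(_LOW, _HIGH)
        return num * pow(den, p - 2, p) % p

    def rows(self) -> list[list[int]]:
        """All matrix rows up to derivative order K, ordered by (order, output)."""
        p, n, K = _PRIME, self.n, self.K
        L = K + 2  # series length

        # 1) Taylor series of the flow x(t).
        x = [[c % p] for c in self.x0]
        for m in range(L - 1):
            env = [xi + [0] * (L - len(xi)) for xi in x]
            for u, ser in self.u_series.items():
                env.append(ser)
            fvals = [fn(env) for fn in self.f_fns]
            for i in range(n):
                fi = _as_series(fvals[i], L)
                nxt = fi[m] * pow(m + 1, p - 2, p) % p
                x[i].append(nxt)
        env = [xi[:L] for xi in x]
        for u, ser in self.u_series.items():
            env.append(ser)

        # 2) Variational system Xi' = J(x(t)) Xi, Xi(0) = I, solved
        #    coefficient-by-coefficient.
        Jser = [[_as_series(fn(env), L) for fn in row] for row in self.J_fns]
        Xi = [[[1 if i == j else 0] for j in range(n)] for i in range(n)]
        for m in range(L - 1):
            inv = pow(m + 1, p - 2, p)
            new = [[0] * n for _ in range(n)]
            for i in range(n):
                for j in range(n):
                    acc = 0
                    Ji = Jser[i]
                    for s in range(n):
                        Jis = Ji[s]
                        Xs = Xi[s][j]
                        for q in range(min(m + 1, len(Xs))):
                            c = Xs[q]
                            if c:
                                acc += Jis[m - q] * c
                    new[i][j] = acc % p * inv % p
            for i in range(n):
                for j in range(n):
                    Xi[i][j].append(new[i][j])

        # 3) Rows: k! * [t^k] ( grad g_j (x(t)) . Xi[:, i] ).
        Gser = [[_as_series(fn(env), L) for fn in row] for row in self.G_fns]
        rows = []
        for k in range(K + 1):
            fact = math.factorial(k) % p
            for j in range(len(self.G_fns)):
                row = []
                for i in range(n):
                    acc = 0
                    for s in range(n):
                        gs = Gser[j][s]
                        Xs = Xi[s][i]
                        for q in range(min(k + 1, len(Xs))):
                            c = Xs[q]
                            if c:
                                acc += gs[k - q] * c
                    row.append(acc % p * fact % p)
                rows.append(row)
        return rows


def _rank_mod(rows: list[list[int]], ncols: int, skip_col: int | None = None) -> int:
    """Gaussian elimination over GF(p); optionally ignore one column."""
    p = _PRIME
    cols = [c for c in range(ncols) if c != skip_col]
    mat = [[r[c] % p for c in cols] for r in rows]
    rank = 0
    ncol = len(cols)
    row = 0
    for col in range(ncol):
        piv = None
        for r in range(row, len(mat)):
            if mat[r][col]:
                piv = r
                break
        if piv is None:
            continue
        mat[row], mat[piv] = mat[piv], mat[row]
        inv = pow(mat[row][col], p - 2, p)
        prow = mat[row]
        for r in range(row + 1, len(mat)):
            factor = mat[r][col]
            if factor:
                f = factor * inv % p
                rr = mat[r]
                for c in range(col, ncol):
                    rr[c] = (rr[c] - f * prow[c]) % p
        row += 1
        rank += 1
        if row == len(mat):
            break
    return rank


def classify(
    model: ODEModel,
    w_derivative_order: int = 1,
    seed: int = 0,
    max_derivatives: int | None = None,
    draws: int = 2,
    max_retries: int = 8,
) -> FISPOReport:
    """Full input-state-parameter observability classification.

    The model is augmented (states + parameters + unknown-input derivatives,
    finite truncation of order ``w_derivative_order``); the rank of the
    observability–identifiability matrix is evaluated at random rational
    points with exact arithmetic, adding Lie-derivative orders until two
    consecutive orders give the same rank (or full rank is reached).  A
    variable is classified observable/identifiable iff deleting its column
    strictly decreases the generic rank.
    """
    aug = augment_for_fispo(model, w_derivative_order)
    n_aug = aug.n_states
    cap = max_derivatives if max_derivatives is not None else n_aug + 1
    rng = random.Random(seed)

    all_rows = []  # one list of row-blocks per draw
    attempts = 0
    while len(all_rows) < draws:
        attempts += 1
        if attempts > draws + max_retries:
            raise InconclusiveAnalysis(f"{model.name}: repeated pole hits in rank evaluation")
        try:
            ev = _PointEvaluator(aug, cap, rng)
            all_rows.append(ev.rows())
        except ZeroDivisionError:
            continue

    n_y = aug.n_outputs

    def rank_at(order: int, skip: int | None = None) -> int:
        return max(
            _rank_mod(rows[: (order + 1) * n_y], n_aug, skip_col=skip) for rows in all_rows
        )

    rank_prev = rank_at(0)
    order = 0
    used = 0
    rank = rank_prev
    for order in range(1, cap + 1):
        rank = rank_at(order)
        used = order
        if rank == n_aug or rank == rank_prev:
            break
        rank_prev = rank
    else:
        raise InconclusiveAnalysis(
            f"{model.name}: rank did not stabilize within {cap} Lie derivatives"
        )
    if rank < n_aug and rank != rank_prev:
        raise InconclusiveAnalysis(
            f"{model.name}: rank did not stabilize within {cap} Lie derivatives"
        )

    # Per-variable classification by column deletion at the stabilized order.
    observable = []
    for i in range(n_aug):
        observable.append(rank_at(used, skip=i) < rank)

    states_obs, states_unobs, params_id, params_unid = set(), set(), set(), set()
    inputs_obs, inputs_unobs = set(), set()
    for i, s in enumerate(aug.states):
        if i < model.n_states:
            (states_obs if observable[i] else states_unobs).add(s)
        elif i < model.n_states + model.n_params:
            (params_id if observable[i] else params_unid).add(s)
        else:
            # unknown-input chain: attribute the base symbol's own column
            if s in model.unknown_inputs:
                (inputs_obs if observable[i] else inputs_unobs).add(s)

    return FISPOReport(
        model=model.name,
        rank=rank,
        n_aug=n_aug,
        observable_states=frozenset(states_obs),
        unobservable_states=frozenset(states_unobs),
        identifiable_params=frozenset(params_id),
        unidentifiable_params=frozenset(params_unid),
        observable_inputs=frozenset(inputs_obs),
        unobservable_inputs=frozenset(inputs_unobs),
        is_fispo=(rank == n_aug),
        n_lie_derivatives_used=used,
    )


def verify_fispo(model: ODEModel, repar, w_derivative_order: int = 1, seed: int = 0) -> FISPOReport:
    """Apply a reparameterization and classify the transformed model."""
    from .models import apply_reparameterization

    transformed = apply_reparameterization(model, repar)
    return classify(transformed, w_derivative_order=w_derivative_order, seed=seed)
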