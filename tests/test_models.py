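"""Model container, simulation, reparameterization and augmentation."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

from obsens.benchmarks import bundled_transformations, load_benchmark
from obsens.models import (
    ODEModel,
    ModelValidationError,
    PiecewiseLinearInput,
    apply_reparameterization,
    augment_for_fispo,
    load_model,
    save_model,
    simulate,
)


class TestValidation:
    def test_dimension_mismatch_rejected(self):
        x, th = sp.symbols("x theta")
        with pytest.raises(ModelValidationError, match="equations"):
            ODEModel("bad", states=(x,), params=(th,), rhs=(-x, -x), outputs=(x,))

    def test_undeclared_symbol_rejected(self):
        x, th = sp.symbols("x theta")
        with pytest.raises(ModelValidationError, match="undeclared"):
            ODEModel("bad", states=(x,), params=(), rhs=(-th * x,), outputs=(x,))

    def test_non_rational_rhs_rejected(self):
        x = sp.Symbol("x")
        with pytest.raises(ModelValidationError, match="rational"):
            ODEModel("bad", states=(x,), params=(), rhs=(sp.sin(x),), outputs=(x,))

    def test_overlapping_names_rejected(self):
        x = sp.Symbol("x")
        with pytest.raises(ModelValidationError, match="disjoint"):
            ODEModel("bad", states=(x,), params=(x,), rhs=(-x,), outputs=(x,))


class TestSimulate:
    def test_exponential_decay_closed_form(self, decay_model):
        t = np.linspace(0.0, 1.0, 5)
        tr = simulate(decay_model, theta=[1.0], x0=[1.0], times=t)
        assert tr.states[-1, 0] == pytest.approx(np.exp(-1.0), rel=1e-6)
        np.testing.assert_allclose(tr.outputs[:, 0], np.exp(-t), rtol=1e-6)

    def test_zero_dynamics_constant_trajectory(self, decay_model):
        t = np.linspace(0.0, 5.0, 11)
        tr = simulate(decay_model, theta=[0.0], x0=[2.5], times=t)
        np.testing.assert_allclose(tr.states[:, 0], 2.5, rtol=1e-12)

    def test_grid_invariance(self, decay_model):
        coarse = np.linspace(0.0, 2.0, 5)
        fine = np.linspace(0.0, 2.0, 17)  # contains the coarse points
        tr_c = simulate(decay_model, times=coarse)
        tr_f = simulate(decay_model, times=fine)
        idx = [np.argmin(np.abs(fine - t)) for t in coarse]
        np.testing.assert_allclose(tr_f.states[idx, 0], tr_c.states[:, 0], rtol=1e-6)

    def test_dimension_mismatch_rejected_before_integration(self, decay_model):
        with pytest.raises(ValueError, match="shape"):
            simulate(decay_model, theta=[1.0, 2.0], times=np.linspace(0, 1, 3))

    def test_circad_matches_fixed_step_rk4(self):
        """Independent oracle: classic RK4 at a 10x finer fixed step."""
        case = load_benchmark("circad")
        model = case.original
        t = np.linspace(0.0, 2.0, 21)
        tr = simulate(model, times=t)

        theta = model.nominal_theta()
        x0 = model.nominal_x0()
        import sympy

        f = sympy.lambdify(
            (model.states, model.params), list(model.rhs), modules="numpy"
        )

        def rhs(x):
            return np.asarray(f(x, theta))

        # fixed step far below the fastest relaxation time (~1/1500 h)
        n_sub = 2000
        h = (t[1] - t[0]) / n_sub
        x = x0.copy()
        out = [x0.copy()]
        for k in range(len(t) - 1):
            for _ in range(n_sub):
                k1 = rhs(x)
                k2 = rhs(x + 0.5 * h * k1)
                k3 = rhs(x + 0.5 * h * k2)
                k4 = rhs(x + h * k3)
                x = x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            out.append(x.copy())
        ref = np.array(out)
        scale = np.max(np.abs(ref), axis=0)
        assert np.max(np.abs(tr.states - ref) / scale) < 1e-4

    def test_oscillatory_circad(self):
        case = load_benchmark("circad")
        t = np.linspace(0.0, 100.0, 400)
        tr = simulate(case.original, times=t)
        s = tr.outputs[:, 0] - tr.outputs[:, 0].mean()
        assert np.sum(np.diff(np.sign(s)) != 0) >= 4  # several full periods


class TestReparameterization:
    @pytest.mark.parametrize("case_id", ["jakstat", "circad"])
    def test_output_equivalence_direct(self, case_id):
        """Transformed model simulated from transformed initial conditions
        reproduces the original outputs."""
        case = load_benchmark(case_id)
        new = apply_reparameterization(case.original, case.transformation)
        t = np.linspace(0.0, case.t_end / 2, 50)
        kw = dict(inputs=case.known_input_truth, rtol=1e-10, atol=1e-12)
        tr_old = simulate(case.original, times=t, **kw)
        tr_new = simulate(new, times=t, **kw)
        scale = np.maximum(np.max(np.abs(tr_old.outputs), axis=0), 1e-12)
        assert np.max(np.abs(tr_old.outputs - tr_new.outputs) / scale) < 1e-8

    def test_output_equivalence_big_with_input_redefinition(self):
        """For the glucose model the transformed unknown input depends on the
        original states, so the two systems are co-integrated jointly."""
        case = load_benchmark("big")
        new = apply_reparameterization(case.original, case.transformation)
        old = case.original
        theta = old.nominal_theta()
        w_true = case.unknown_input_truth["w"]

        f_old = sp.lambdify((old.states, old.params, old.unknown_inputs), list(old.rhs))
        f_new = sp.lambdify((new.states, new.unknown_inputs), [
            e.subs(new.nominal) for e in new.rhs
        ])
        si = float(old.nominal[sp.Symbol("si")])

        def joint(t, z):
            xo, xn = z[:3], z[3:]
            w = w_true(t)
            ws = w - xo[0] * xo[1] * (si - 1.0)
            return np.hstack([f_old(xo, theta, [w]), f_new(xn, [ws])])

        x0_old = old.nominal_x0()
        x0_new = new.nominal_x0()
        t = np.linspace(0.0, 60.0, 61)
        sol = solve_ivp(joint, (0, 60.0), np.hstack([x0_old, x0_new]),
                        t_eval=t, rtol=1e-10, atol=1e-12, method="LSODA")
        assert sol.success
        y_old = sol.y[0]  # glucose of the original
        y_new = sol.y[3]  # glucose of the transformed
        assert np.max(np.abs(y_old - y_new) / np.max(np.abs(y_old))) < 1e-8

    def test_identity_substitution_preserves_model(self, decay_model):
        rep = apply_reparameterization(
            decay_model,
            __import__("obsens").Reparameterization(name="id"),
        )
        assert rep.params == decay_model.params
        assert rep.rhs == decay_model.rhs

    def test_jakstat_transformation_removes_p2(self):
        case = load_benchmark("jakstat")
        new = apply_reparameterization(case.original, case.transformation)
        assert sp.Symbol("p2") not in new.params
        assert all(sp.Symbol("p2") not in e.free_symbols for e in new.rhs + new.outputs)

    def test_leftover_removed_parameter_rejected(self, decay_model):
        from obsens.models import Reparameterization

        x, th = sp.symbols("x theta")
        bad = Reparameterization(name="bad", removed_params=(th,))
        with pytest.raises(ModelValidationError, match="remain"):
            apply_reparameterization(decay_model, bad)

    def test_big_leaves_insulin_untransformed(self):
        repar = bundled_transformations()["big"]
        assert sp.Symbol("x2") not in {s for s, _ in repar.new_states.values()}
        new = apply_reparameterization(load_benchmark("big").original, repar)
        assert sp.Symbol("x2") in new.states


class TestAugmentation:
    def test_dimension_counting(self):
        x1, x2, x3 = sp.symbols("x1 x2 x3")
        ps = sp.symbols("a b c d e")
        m = ODEModel("m", states=(x1, x2, x3), params=ps,
                     rhs=(-ps[0] * x1, -ps[1] * x2, -ps[2] * x3),
                     outputs=(x1,))
        aug = augment_for_fispo(m, 0)
        assert aug.n_states == 8
        assert aug.n_params == 0

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_dimension_formula_with_unknown_input(self, order):
        case = load_benchmark("big")
        m = case.original
        aug = augment_for_fispo(m, order)
        assert aug.n_states == m.n_states + m.n_params + m.n_unknown_inputs * (order + 1)

    def test_decay_augmentation_by_definition(self, decay_model):
        aug = augment_for_fispo(decay_model, 0)
        x, th = sp.symbols("x theta")
        assert aug.states == (x, th)
        assert aug.rhs == (-th * x, sp.Integer(0))


class TestModelIO:
    def test_roundtrip(self, tmp_path, decay_model):
        path = tmp_path / "decay.yaml"
        save_model(decay_model, path)
        back = load_model(path)
        assert back.states == decay_model.states
        assert back.rhs == decay_model.rhs
        assert back.nominal == decay_model.nominal

    def test_piecewise_linear_input(self):
        f = PiecewiseLinearInput([0.0, 1.0, 2.0], [0.0, 2.0, 0.0])
        assert f(0.5) == pytest.approx(1.0)
        assert f(1.5) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            PiecewiseLinearInput([0.0, 0.0], [1.0, 2.0])
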