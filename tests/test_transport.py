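"""Forward-solver tests: oracles, conservation, stability, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wetlandch4 as w
from wetlandch4.transport import affine_propagator

from conftest import constant_diffusivity


def uniform_profile(grid, value=100.0, time=0.0):
    return w.ConcentrationProfile(grid, np.full(grid.n_layers, value), time)


def explicit_ftcs(c0, d, r, dt, n_steps, dz):
    """Independent fine-step explicit (FTCS) oracle with closed boundaries."""
    c = c0.copy()
    d_face = 2.0 * d[:-1] * d[1:] / (d[:-1] + d[1:])
    for _ in range(n_steps):
        flux = d_face * (c[1:] - c[:-1]) / dz  # diffusive flux between cells
        div = np.zeros_like(c)
        div[:-1] += flux / dz
        div[1:] -= flux / dz
        c = c + dt * (div + r)
    return c


class TestDiffusivityProfile:
    def test_constant_polynomial_returns_reference(self, grid):
        model = w.DiffusivityModel(reference_diffusivity=1.5, temperature_coefficients=[1.0])
        temp = w.TemperatureField.constant(grid, 15.0)
        d = w.diffusivity_profile(model, temp, 0.0)
        np.testing.assert_allclose(d, 1.5)

    def test_fixed_override_ignores_temperature(self, grid):
        override = np.linspace(0.5, 2.0, grid.n_layers)
        model = w.DiffusivityModel(fixed_profile=override)
        temp = w.TemperatureField.constant(grid, -3.0)
        np.testing.assert_array_equal(w.diffusivity_profile(model, temp, 0.0), override)

    def test_linear_in_temperature_midpoint(self, grid):
        # T ramps 10 -> 20 degC over 10 d uniformly; query at day 5 -> 15 degC.
        coeffs = [0.5, 0.04]  # oracle: direct polynomial evaluation
        model = w.DiffusivityModel(reference_diffusivity=2.0, temperature_coefficients=coeffs)
        temp = w.TemperatureField(
            np.array([0.0, 10.0]), grid,
            np.vstack([np.full(grid.n_layers, 10.0), np.full(grid.n_layers, 20.0)]),
        )
        d = w.diffusivity_profile(model, temp, 5.0)
        np.testing.assert_allclose(d, 2.0 * (0.5 + 0.04 * 15.0))

    def test_negative_diffusivity_names_layer(self, grid):
        model = w.DiffusivityModel(reference_diffusivity=1.0)
        model.temperature_coefficients = [1.0, -0.5]  # corrupt after validation
        temp = w.TemperatureField.constant(grid, 30.0)
        with pytest.raises(ValueError, match="layer"):
            w.diffusivity_profile(model, temp, 0.0)


class TestStepImplicit:
    def test_uniform_no_sources_is_identity(self, grid):
        c = uniform_profile(grid)
        out = w.step_implicit(c, np.ones(grid.n_layers), w.SourceProfile.zeros(grid), 0.0, 1.0)
        np.testing.assert_allclose(out.values, c.values, rtol=1e-14)

    def test_pure_source_integration(self, grid):
        c = uniform_profile(grid, 10.0)
        r = w.SourceProfile(grid, np.full(grid.n_layers, 2.0))
        out = w.step_implicit(c, np.full(grid.n_layers, 1e-12), r, 0.0, 5.0)
        np.testing.assert_allclose(out.values, 20.0, rtol=1e-9)

    def test_gaussian_pulse_matches_explicit_oracle(self, grid):
        z = grid.layer_centers
        c0 = 100.0 * np.exp(-(((z - 28.0) / 6.0) ** 2))
        d = np.ones(grid.n_layers)
        dt, n_steps = 0.5, 100
        prof = w.ConcentrationProfile(grid, c0)
        r = w.SourceProfile.zeros(grid)
        for _ in range(n_steps):
            prof = w.step_implicit(prof, d, r, 0.0, dt)
        oracle = explicit_ftcs(c0, d, np.zeros(grid.n_layers), dt / 200, n_steps * 200,
                               grid.layer_thickness)
        rms = np.sqrt(np.mean((prof.values - oracle) ** 2))
        assert rms / np.sqrt(np.mean(oracle**2)) < 0.01


class TestSolveForward:
    def test_closed_column_conserves_mass(self, grid):
        z = grid.layer_centers
        c0 = w.ConcentrationProfile(grid, 50.0 + 4.0 * z + 30.0 * np.sin(z / 8.0))
        sol = w.solve_forward(
            c0, constant_diffusivity(grid), w.TemperatureField.constant(grid, 15.0),
            w.SourceProfile.zeros(grid), w.BoundaryFluxSeries.constant(0.0),
            t_end=30.0, dt=0.1,
        )
        mass = sol.mass()
        assert abs(mass[-1] - mass[0]) / mass[0] < 1e-8

    def test_steady_state_matches_parabola(self, grid):
        # Analytic steady state of d/dz(D dC/dz) + r = 0 with no-flux bottom
        # and top emission balancing the column production.
        d_const, r_const = 1.0, 0.5
        length = grid.depth
        c0 = uniform_profile(grid, 500.0)
        r = w.SourceProfile(grid, np.full(grid.n_layers, r_const))
        sol = w.solve_forward(
            c0, constant_diffusivity(grid, d_const),
            w.TemperatureField.constant(grid, 15.0), r,
            w.BoundaryFluxSeries.constant(r_const * length),
            t_end=8000.0, dt=10.0,
        )
        z = grid.layer_centers
        shape = -(r_const / (2 * d_const)) * (length - z) ** 2
        exact = shape - shape.mean() + 500.0  # mass is conserved -> mean fixed
        err = np.sqrt(np.mean((sol.final.values - exact) ** 2))
        assert err / (exact.max() - exact.min()) < 0.005

    def test_single_step_equals_step_implicit(self, grid):
        z = grid.layer_centers
        c0 = w.ConcentrationProfile(grid, 100.0 + 3.0 * z)
        r = w.SourceProfile(grid, 0.5 * np.sin(z / 10.0))
        dmodel = constant_diffusivity(grid, 0.8)
        temp = w.TemperatureField.constant(grid, 15.0)
        boundary = w.BoundaryFluxSeries.constant(5.0)
        sol = w.solve_forward(c0, dmodel, temp, r, boundary, t_end=7.0, dt=7.0)
        direct = w.step_implicit(c0, np.full(grid.n_layers, 0.8), r, 5.0, 7.0)
        np.testing.assert_allclose(sol.final.values, direct.values, rtol=1e-13)


class TestColumnMassBalance:
    def test_solver_output_closes(self, grid):
        z = grid.layer_centers
        c0 = w.ConcentrationProfile(grid, 80.0 + 5.0 * z)
        r = w.SourceProfile(grid, 2.0 * np.exp(-z / 10.0) - 0.5)
        boundary = w.BoundaryFluxSeries(np.array([0.0, 30.0]), np.array([5.0, 15.0]))
        sol = w.solve_forward(
            c0, constant_diffusivity(grid), w.TemperatureField.constant(grid, 15.0),
            r, boundary, t_end=30.0, dt=0.1,
        )
        residual = w.column_mass_balance(sol, r, boundary)
        delta_m = sol.mass()[-1] - sol.mass()[0]
        assert abs(residual) / max(abs(delta_m), 1.0) < 1e-6

    def test_two_layer_single_step_hand_arithmetic(self):
        # Pencil-and-paper: 2 layers, dz=1, D=1, dt=1, r=(1,0), flux=0.5.
        grid = w.DepthGrid(n_layers=2, layer_thickness=1.0)
        c0 = w.ConcentrationProfile(grid, np.array([4.0, 2.0]))
        r = w.SourceProfile(grid, np.array([1.0, 0.0]))
        boundary = w.BoundaryFluxSeries.constant(0.5)
        sol = w.solve_forward(
            c0, constant_diffusivity(grid), w.TemperatureField.constant(grid, 15.0),
            r, boundary, t_end=1.0, dt=1.0,
        )
        # Mass: dM = dt*(sum r dz) - dt*flux = 1*1 - 0.5 = 0.5 exactly.
        assert abs((sol.mass()[-1] - sol.mass()[0]) - 0.5) < 1e-12
        assert abs(w.column_mass_balance(sol, r, boundary)) < 1e-12

    def test_zero_everything_residual_zero(self, grid):
        c0 = uniform_profile(grid, 0.0)
        r = w.SourceProfile.zeros(grid)
        boundary = w.BoundaryFluxSeries.constant(0.0)
        sol = w.solve_forward(
            c0, constant_diffusivity(grid), w.TemperatureField.constant(grid, 15.0),
            r, boundary, t_end=10.0, dt=1.0,
        )
        assert w.column_mass_balance(sol, r, boundary) == 0.0


class TestIgnorantGuess:
    def test_static_profiles_give_zero(self, grid):
        c = uniform_profile(grid, 120.0)
        guess = w.ignorant_guess(
            c, uniform_profile(grid, 120.0), constant_diffusivity(grid),
            w.TemperatureField.constant(grid, 15.0),
            w.BoundaryFluxSeries.constant(0.0), 30.0,
        )
        np.testing.assert_allclose(guess.values, 0.0, atol=1e-12)

    def test_no_transport_is_finite_difference(self, grid):
        rng = np.random.default_rng(4)
        a = 50.0 + rng.random(grid.n_layers) * 50
        b = 50.0 + rng.random(grid.n_layers) * 50
        guess = w.ignorant_guess(
            w.ConcentrationProfile(grid, a), w.ConcentrationProfile(grid, b),
            constant_diffusivity(grid, 1e-12), w.TemperatureField.constant(grid, 15.0),
            w.BoundaryFluxSeries.constant(0.0), 30.0,
        )
        np.testing.assert_allclose(guess.values, (b - a) / 30.0, atol=1e-10)

    def test_recovers_constant_truth_within_25_percent(self, grid):
        # Forward-simulate a month at fine dt under constant R, after a
        # spin-up so the column carries the surface flux smoothly; the
        # coarse one-step guess is then good to well under 25% per layer.
        r_true = 1.6
        dmodel = constant_diffusivity(grid, 0.8)
        temp = w.TemperatureField.constant(grid, 15.0)
        boundary = w.BoundaryFluxSeries.constant(0.9 * r_true * grid.depth)
        r = w.SourceProfile(grid, np.full(grid.n_layers, r_true))
        c0 = w.ConcentrationProfile(grid, 300.0 + 4.0 * grid.layer_centers)
        spin = w.solve_forward(c0, dmodel, temp, r, boundary, t_end=120.0, dt=0.1)
        sol = w.solve_forward(spin.final, dmodel, temp, r, boundary,
                              t_end=150.0, dt=0.1, t_start=120.0)
        guess = w.ignorant_guess(spin.final, sol.final, dmodel, temp, boundary, 30.0)
        assert np.all(np.abs(guess.values - r_true) / r_true < 0.25)


class TestAffinePropagator:
    def test_matches_stepped_solver_exactly(self, surface_scenario):
        sc = surface_scenario
        profs = sc.true_peeper_profiles("open")
        ctx = sc.forward_context("open", 1)
        r = w.SourceProfile(sc.grid, sc.true_r["open"][1])
        sol = w.solve_forward(
            profs[1], sc.dmodel, sc.temperature, r, ctx.boundary,
            t_end=ctx.t_end, dt=0.1, t_start=ctx.t_start,
        )
        v0, m = affine_propagator(profs[1], ctx, dt=0.1)
        np.testing.assert_allclose(v0 + m @ r.values, sol.final.values, atol=1e-9)


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        dt=st.floats(0.01, 30.0),
        d_scale=st.floats(0.1, 5.0),
        seed=st.integers(0, 10_000),
    )
    def test_unconditional_stability_and_maximum_principle(self, dt, d_scale, seed):
        grid = w.DepthGrid()
        rng = np.random.default_rng(seed)
        c0 = w.ConcentrationProfile(grid, rng.random(grid.n_layers) * 400.0)
        out = w.step_implicit(
            c0, np.full(grid.n_layers, d_scale), w.SourceProfile.zeros(grid), 0.0, dt
        )
        assert np.isfinite(out.values).all()
        assert out.values.min() >= c0.values.min() - 1e-9
        assert out.values.max() <= c0.values.max() + 1e-9

    def test_per_step_conservation_tight(self, grid):
        rng = np.random.default_rng(11)
        c = w.ConcentrationProfile(grid, rng.random(grid.n_layers) * 300.0)
        mass0 = c.mass
        for _ in range(10):
            c = w.step_implicit(c, np.ones(grid.n_layers), w.SourceProfile.zeros(grid),
                                0.0, 3.0)
            assert abs(c.mass - mass0) / mass0 < 1e-10
            mass0 = c.mass

    def test_first_order_convergence_to_explicit_oracle(self, grid):
        z = grid.layer_centers
        c0 = 100.0 * np.exp(-(((z - 20.0) / 5.0) ** 2))
        d = np.ones(grid.n_layers)
        oracle = explicit_ftcs(c0, d, np.zeros(grid.n_layers), 0.002, 10_000,
                               grid.layer_thickness)
        errs = []
        for dt in (1.0, 0.5, 0.25):
            prof = w.ConcentrationProfile(grid, c0)
            for _ in range(int(20.0 / dt)):
                prof = w.step_implicit(prof, d, w.SourceProfile.zeros(grid), 0.0, dt)
            errs.append(np.sqrt(np.mean((prof.values - oracle) ** 2)))
        # halving dt should at least halve the error (observed order >= 1)
        assert errs[1] < 0.62 * errs[0]
        assert errs[2] < 0.62 * errs[1]
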