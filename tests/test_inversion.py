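"""Source-term inversion tests: misfit, chain behavior, selection, recovery."""

import numpy as np
import pytest

import wetlandch4 as w
from wetlandch4.inversion import Chain

from conftest import constant_diffusivity


def make_context(grid, flux=0.0, d=1.0, t0=0.0, t1=30.0):
    return w.ForwardContext(
        grid, constant_diffusivity(grid, d), w.TemperatureField.constant(grid, 15.0),
        w.BoundaryFluxSeries.constant(flux), t0, t1,
    )


class TestErrorMetric:
    def test_identical_profiles_zero(self, grid):
        c = w.ConcentrationProfile(grid, np.full(grid.n_layers, 50.0))
        assert w.error_metric(c, c) == 0.0

    def test_constant_offset_sums_squares(self, grid):
        a = w.ConcentrationProfile(grid, np.full(grid.n_layers, 10.0))
        b = w.ConcentrationProfile(grid, np.full(grid.n_layers, 12.0))
        assert w.error_metric(a, b) == pytest.approx(grid.n_layers * 4.0)

    def test_masked_layer_excluded(self, grid):
        a = w.ConcentrationProfile(grid, np.full(grid.n_layers, 10.0))
        vals = np.full(grid.n_layers, 10.0)
        vals[7] = np.nan  # missing peeper window; modeled value differs there
        b = w.ConcentrationProfile(grid, vals)
        a2 = w.ConcentrationProfile(grid, np.where(np.arange(grid.n_layers) == 7, 15.0, 10.0))
        assert w.error_metric(a2, b) == 0.0

    def test_all_missing_raises(self, grid):
        a = w.ConcentrationProfile(grid, np.full(grid.n_layers, 10.0))
        b = w.ConcentrationProfile(grid, np.full(grid.n_layers, np.nan))
        with pytest.raises(ValueError, match="missing"):
            w.error_metric(a, b)


class TestMHChain:
    def test_flat_target_accepts_everything(self, grid):
        c0 = w.ConcentrationProfile(grid, np.full(grid.n_layers, 100.0))
        cfg = w.InversionConfig(n_iterations=2000, error_scale=1e9, rng_seed=1)
        chain = w.mh_chain(c0, c0, make_context(grid), w.SourceProfile.zeros(grid), cfg)
        assert chain.acceptance_rate > 0.999

    def test_running_minimum_improves_on_initial_guess(self, surface_scenario):
        sc = surface_scenario
        profs = sc.true_peeper_profiles("open")  # noiseless data, known truth
        ctx = sc.forward_context("open", 0)
        model = w.SourceInversion(profs[0], profs[1], ctx, w.InversionConfig(rng_seed=2))
        r0 = model.initial_guess()
        chain = w.mh_chain(profs[0], profs[1], ctx, r0, model.config)
        assert chain.errors.min() < chain.errors[0]
        assert chain.errors.min() < 0.5 * chain.errors[0]

    def test_same_seed_bit_identical(self, grid):
        rng = np.random.default_rng(0)
        c0 = w.ConcentrationProfile(grid, 100.0 + rng.random(grid.n_layers) * 50)
        c1 = w.ConcentrationProfile(grid, 100.0 + rng.random(grid.n_layers) * 50)
        cfg = w.InversionConfig(n_iterations=500, rng_seed=42)
        ctx = make_context(grid)
        r0 = w.SourceProfile.zeros(grid)
        a = w.mh_chain(c0, c1, ctx, r0, cfg)
        b = w.mh_chain(c0, c1, ctx, r0, cfg)
        np.testing.assert_array_equal(a.errors, b.errors)
        np.testing.assert_array_equal(a.rs, b.rs)


class TestSummarizeChain:
    def test_default_selection_is_4000_states(self, grid):
        cfg = w.InversionConfig()  # 40,000 iterations, top 10%
        assert cfg.n_selected == 4000
        rng = np.random.default_rng(3)
        chain = Chain(grid, rng.random((cfg.n_iterations, grid.n_layers)),
                      rng.random(cfg.n_iterations), n_accepted=1)
        result = w.summarize_chain(chain, cfg)
        assert result.n_selected == 4000

    def test_identical_states_zero_spread(self, grid):
        cfg = w.InversionConfig(n_iterations=100, top_fraction=0.5)
        rs = np.tile(np.linspace(-1, 1, grid.n_layers), (100, 1))
        chain = Chain(grid, rs, np.full(100, 7.0), n_accepted=0)
        result = w.summarize_chain(chain, cfg)
        np.testing.assert_allclose(result.sd_r, 0.0, atol=1e-12)
        np.testing.assert_allclose(result.mean_r.values, rs[0], atol=1e-12)

    def test_hand_built_selection_and_moments(self):
        grid = w.DepthGrid(n_layers=2, layer_thickness=1.0)
        cfg = w.InversionConfig()
        cfg.n_iterations, cfg.top_fraction = 10, 0.3  # miniature pencil-and-paper case
        errors = np.array([5.0, 1.0, 3.0, 9.0, 2.0, 8.0, 7.0, 6.0, 4.0, 10.0])
        rs = np.column_stack([np.arange(10.0), np.arange(10.0) * 2])
        chain = Chain(grid, rs, errors, n_accepted=0)
        result = w.summarize_chain(chain, cfg)
        # top 3 errors: 1.0 (i=1), 2.0 (i=4), 3.0 (i=2) -> r1 = (1+4+2)/3
        assert result.n_selected == 3
        np.testing.assert_allclose(result.mean_r.values, [7.0 / 3.0, 14.0 / 3.0])
        np.testing.assert_allclose(result.sd_r, [np.std([1.0, 4.0, 2.0]),
                                                 np.std([2.0, 8.0, 4.0])])

    def test_selection_boundary_ties_keep_earlier(self, grid):
        cfg = w.InversionConfig()
        cfg.n_iterations, cfg.top_fraction = 4, 0.5
        errors = np.array([2.0, 1.0, 1.0, 1.0])  # three-way tie, keep i=1, i=2
        rs = np.tile(np.arange(4.0)[:, None], (1, grid.n_layers))
        result = w.summarize_chain(Chain(grid, rs, errors, 0), cfg)
        np.testing.assert_allclose(result.mean_r.values, 1.5)

    def test_selection_invariant(self, grid):
        rng = np.random.default_rng(9)
        cfg = w.InversionConfig(n_iterations=1000, top_fraction=0.1)
        errors = rng.random(1000)
        chain = Chain(grid, rng.random((1000, grid.n_layers)), errors, 0)
        w.summarize_chain(chain, cfg)
        cutoff = np.sort(errors)[cfg.n_selected - 1]
        assert (np.sort(errors)[: cfg.n_selected] <= cutoff).all()


class TestInvertSeries:
    def test_interval_count(self, grid):
        c = [w.ConcentrationProfile(grid, np.full(grid.n_layers, 100.0), t)
             for t in (0.0, 30.0, 60.0, 90.0)]
        ctxs = [make_context(grid, t0=t, t1=t + 30.0) for t in (0.0, 30.0, 60.0)]
        cfg = w.InversionConfig(n_iterations=200, rng_seed=0)
        results = w.invert_series(c, ctxs, cfg)
        assert len(results) == 3
        assert [r.t_start for r in results] == [0.0, 30.0, 60.0]

    def test_missing_interval_skipped(self, grid):
        c = [w.ConcentrationProfile(grid, np.full(grid.n_layers, 100.0), t)
             for t in (0.0, 30.0, 60.0)]
        ctxs = [make_context(grid), None]
        cfg = w.InversionConfig(n_iterations=200, rng_seed=0)
        assert len(w.invert_series(c, ctxs, cfg)) == 1

    def test_null_scenario_recovery(self, grid):
        # Static profiles, no flux: inferred activity consistent with zero.
        sc = w.make_scenario("null", seed=0)
        profs = sc.true_peeper_profiles("open")
        ctxs = [sc.forward_context("open", k) for k in range(3)]
        cfg = w.InversionConfig(n_iterations=5000, rng_seed=0)
        results = w.invert_series(profs, ctxs, cfg)
        for res in results:
            frac = np.mean(np.abs(res.mean_r.values) < 2 * res.sd_r)
            assert frac >= 0.95

    def test_two_layer_source_recovery(self, grid):
        # Production at 0-10 cm, consumption at 25-35 cm, noiseless data.
        z = grid.layer_centers
        r_true = np.where(z < 10, 2.0, np.where((z > 25) & (z < 35), -1.0, 0.0))
        dmodel = constant_diffusivity(grid, 0.8)
        temp = w.TemperatureField.constant(grid, 15.0)
        boundary = w.BoundaryFluxSeries.constant(0.8 * r_true.sum() * grid.layer_thickness)
        c0 = w.ConcentrationProfile(grid, 200.0 + 3.0 * z)
        profs = [c0]
        for k in range(2):
            sol = w.solve_forward(profs[-1], dmodel, temp, w.SourceProfile(grid, r_true),
                                  boundary, t_end=30.0 * (k + 1), dt=0.1,
                                  t_start=30.0 * k)
            profs.append(sol.final)
        ctxs = [make_context(grid, flux=boundary.flux[0], d=0.8, t0=30.0 * k,
                             t1=30.0 * (k + 1)) for k in range(2)]
        cfg = w.InversionConfig(rng_seed=5)
        results = w.invert_series(profs, ctxs, cfg)
        for res in results:
            within = np.abs(res.mean_r.values - r_true) <= 2 * res.sd_r
            assert within.mean() >= 0.8


class TestCalibration:
    def test_null_shrinks_with_proposal_scale(self, grid):
        # On noiseless static data the sampled activity collapses toward 0
        # as the random-walk step shrinks.
        c = w.ConcentrationProfile(grid, np.full(grid.n_layers, 150.0))
        ctx = make_context(grid)
        sizes = []
        for scale in (0.1, 0.025, 0.00625):
            cfg = w.InversionConfig(n_iterations=4000, proposal_scale=scale, rng_seed=3)
            res = w.SourceInversion(c, c, ctx, cfg).fit()
            sizes.append(np.abs(res.mean_r.values).mean())
        assert sizes[2] < sizes[1] < sizes[0]

    def test_bias_decreases_with_noise(self, grid):
        # Recovery error grows monotonically over three peeper noise levels.
        errs = []
        for sigma in (0.0, 4.0, 16.0):
            sc = w.make_scenario("surface_source", seed=7,
                                 overrides={"noise": {"peeper_sigma": sigma}})
            truth = sc.true_r["open"][0]
            profs = sc.true_peeper_profiles("open")
            rng = np.random.default_rng(17)
            noisy_end = w.ConcentrationProfile(
                sc.grid, np.maximum(profs[1].values + rng.normal(0, sigma, sc.grid.n_layers), 0.0),
                profs[1].time,
            )
            cfg = w.InversionConfig(n_iterations=10_000, rng_seed=11,
                                    error_scale=max(sigma, 1.0))
            res = w.SourceInversion(profs[0], noisy_end, sc.forward_context("open", 0), cfg).fit()
            errs.append(np.abs(res.mean_r.values - truth).mean())
        assert errs[0] < errs[1] < errs[2]


def test_summary_is_readable(pipeline_report):
    text = pipeline_report.inversions["open"][0].summary()
    assert "mean R" in text and "acceptance rate" in text
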