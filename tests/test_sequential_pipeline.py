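"""Sequential prior propagation, model-based IC updating and full-run wiring."""

import dataclasses

import numpy as np
import pytest

from chemograd.cli_io import Dataset, normalize_intensities
from chemograd.condition_extraction import interpolate_initial
from chemograd.inference_core import (
    PARAM_NAMES,
    ParameterSummary,
    PosteriorSamples,
    PosteriorSummary,
    fit_gamma_moments,
)
from chemograd.sequential_pipeline import (
    PipelineConfig,
    StepRecord,
    make_priors,
    propagate_initial_condition,
    run_pipeline,
    run_step,
)
from chemograd.synthetic_data import generate, reference_scenarios, scaled_scenario
from chemograd.transport_model import (
    BoundaryFn,
    ConcentrationProfile,
    SpatialGrid,
    constant_boundary,
)


def stub_record(n, d_draws, u_draws, sigma_draws=None):
    """A StepRecord carrying given posterior draws (everything else minimal)."""
    draws = {
        "D": np.asarray(d_draws, float),
        "u": np.asarray(u_draws, float),
        "sigma": np.asarray(
            sigma_draws if sigma_draws is not None else np.full_like(d_draws, 0.01),
            float,
        ),
    }
    summary = PosteriorSummary(
        parameters={
            k: ParameterSummary(
                float(np.mean(v)), float(np.median(v)), float(np.std(v)),
                float(np.min(v)), float(np.max(v)),
            )
            for k, v in draws.items()
        }
    )
    return StepRecord(
        n=n, t_start=0.0, t_end=30.0,
        priors={}, diagnostics=None, ic=lambda x: np.zeros_like(x),
        samples=PosteriorSamples(draws, 0.3, 0, len(d_draws), 0, 1),
        summary=summary,
    )


class TestMakePriors:
    def test_first_step_vague_priors(self):
        priors = make_priors(1, None, PipelineConfig())
        assert priors["D"].family == "uniform" and priors["D"].params == (0.0, 1.0)
        assert priors["u"].family == "uniform" and priors["u"].params == (0.0, 1.0)
        assert priors["sigma"].family == "half_normal"
        assert priors["sigma"].params == (1.0,)

    def test_diffusivity_prior_is_gamma_moment_fit_of_previous_posterior(self):
        # draws {1e-5, 3e-5}: mean 2e-5, variance 1e-10 -> Gamma(4, 2e5)
        prev = stub_record(2, [1e-5, 3e-5], [0.1, 0.2])
        priors = make_priors(3, prev, PipelineConfig())
        assert priors["D"].family == "gamma"
        assert priors["D"].params[0] == pytest.approx(4.0)
        assert priors["D"].params[1] == pytest.approx(2e5)
        assert priors["u"].family == "uniform"

    def test_dextranI_variant_propagates_u_only_through_window(self):
        cfg = dataclasses.replace(PipelineConfig(), variant="dextranI")
        for n in range(2, 7):
            prev = stub_record(n - 1, [1e-5, 3e-5], [1e-4, 3e-4])
            priors = make_priors(n, prev, cfg)
            assert priors["u"].family == "gamma", f"step {n}"
            fit = fit_gamma_moments(2e-4, 1e-8)
            assert priors["u"].params == pytest.approx((fit.shape, fit.rate))
        prev = stub_record(6, [1e-5, 3e-5], [1e-4, 3e-4])
        assert make_priors(7, prev, cfg)["u"].family == "uniform"

    def test_variant_flag_changes_only_u_priors_in_window(self):
        std = PipelineConfig()
        dex = dataclasses.replace(PipelineConfig(), variant="dextranI")
        for n in range(2, 9):
            prev_a = stub_record(n - 1, [1e-5, 3e-5], [1e-4, 3e-4])
            prev_b = stub_record(n - 1, [1e-5, 3e-5], [1e-4, 3e-4])
            pa = make_priors(n, prev_a, std)
            pb = make_priors(n, prev_b, dex)
            assert pa["D"] == pb["D"]
            assert pa["sigma"] == pb["sigma"]
            if 2 <= n <= 6:
                assert pa["u"] != pb["u"]
            else:
                assert pa["u"] == pb["u"]

    def test_sigma_prior_identical_at_every_step(self):
        cfg = PipelineConfig()
        p1 = make_priors(1, None, cfg)
        pn = make_priors(5, stub_record(4, [1e-5, 3e-5], [0.1, 0.2]), cfg)
        assert p1["sigma"] == pn["sigma"]

    def test_previous_record_required_iff_n_at_least_two(self):
        cfg = PipelineConfig()
        with pytest.raises(ValueError):
            make_priors(2, None, cfg)
        with pytest.raises(ValueError):
            make_priors(1, stub_record(1, [1e-5, 2e-5], [0.1, 0.2]), cfg)

    def test_degenerate_posterior_variance_floored(self, caplog):
        prev = stub_record(1, np.full(50, 2e-5), np.linspace(0.1, 0.2, 50))
        with caplog.at_level("WARNING"):
            priors = make_priors(2, prev, PipelineConfig())
        fit = fit_gamma_moments(2e-5, (1e-3 * 2e-5) ** 2)
        assert priors["D"].params == pytest.approx((fit.shape, fit.rate))


class TestPropagateInitialCondition:
    def test_collapsed_posterior_reproduces_generator_trajectory(self, tiny_synthetic):
        """With the posterior collapsed onto the true parameters, the
        model-based IC equals the generator's clean profile at t_{n-1}."""
        sc = tiny_synthetic.scenario
        clean = tiny_synthetic.clean_profiles
        truth_d = np.full(20, sc.params.diffusivity)
        truth_u = np.full(20, sc.params.advection)
        rec = stub_record(1, truth_d, truth_u)
        rec.t_start, rec.t_end = clean[0].time, clean[1].time
        rec.ic = interpolate_initial(clean[0])
        grid = SpatialGrid(sc.width, 101)
        ic_next = propagate_initial_condition(
            rec, BoundaryFn(sc.source), BoundaryFn(sc.buffer), grid, 60
        )
        predicted = ic_next(clean[1].positions)
        assert np.max(np.abs(predicted - clean[1].values)) < 0.005 * sc.source.amplitude
        assert rec.model_profile is not None
        assert rec.model_profile.time == clean[1].time


class TestRunStep:
    def test_zero_information_leaves_diffusivity_prior_unchanged(self):
        """A spatially constant profile with equal boundaries carries no
        information on D, so its posterior matches the U(0,1) prior."""
        grid = SpatialGrid(0.5, 21)
        level = 0.4
        noise = np.random.default_rng(17).normal(0, 0.01, 21)
        data = ConcentrationProfile(30.0, grid.x, np.full(21, level) + noise)
        cfg = PipelineConfig(n_iter=6000, burn_in=1500, n_nodes=21, substeps=5)
        priors = make_priors(1, None, cfg)
        from chemograd.inference_core import ParameterPoint

        rec = run_step(
            data, lambda x: np.full_like(x, level),
            constant_boundary(level), constant_boundary(level),
            priors, grid, 0.0, cfg, seed=4,
            init_point=ParameterPoint(0.5, 0.5, 0.1),
            init_scales=np.array([0.2, 0.2, 0.05]),
        )
        d = rec.samples.draws["D"]
        assert d.mean() == pytest.approx(0.5, abs=0.08)
        assert d.std() == pytest.approx(1 / np.sqrt(12), abs=0.05)

    def test_posterior_concentrates_on_generating_parameters(self, tiny_synthetic):
        """Single-step recovery: the truth lands inside (or near) the bulk
        of the posterior when the data are generated by the model itself."""
        sc = tiny_synthetic.scenario
        ds, scale = normalize_intensities(tiny_synthetic.dataset)
        cfg = PipelineConfig(n_iter=4000, burn_in=1500, n_nodes=51, substeps=20)
        grid = SpatialGrid(sc.width, cfg.n_nodes)
        priors = make_priors(1, None, cfg)
        src = BoundaryFn(lambda t: sc.source(t) / scale)
        buf = BoundaryFn(lambda t: sc.buffer(t) / scale)
        rec = run_step(
            ds.profiles[1], interpolate_initial(ds.profiles[0]),
            src, buf, priors, grid, ds.profiles[0].time, cfg, seed=9,
        )
        s = rec.summary["D"]
        width = s.hpd_high - s.hpd_low
        assert s.hpd_low - width <= sc.params.diffusivity <= s.hpd_high + width


@pytest.fixture(scope="module")
def small_run(tiny_dataset):
    cfg = PipelineConfig(
        n_iter=1500, burn_in=500, n_nodes=31, substeps=10, seed=21
    )
    return run_pipeline(tiny_dataset, cfg), cfg


class TestRunPipeline:
    def test_one_record_per_observation_time(self, small_run, tiny_dataset):
        result, _ = small_run
        assert [r.t_end for r in result.records] == list(tiny_dataset.times[1:])
        assert [r.n for r in result.records] == [1, 2, 3, 4]

    def test_prior_wiring_matches_stored_gamma_fits(self, small_run):
        result, _ = small_run
        for prev, cur in zip(result.records, result.records[1:]):
            d = prev.samples.draws["D"]
            fit = fit_gamma_moments(float(np.mean(d)), float(np.var(d)))
            assert cur.priors["D"].params == (fit.shape, fit.rate)
            assert prev.gamma_fits["D"].shape == fit.shape
            assert cur.priors["sigma"].family == "half_normal"
            assert cur.priors["sigma"].params == (1.0,)
            assert cur.priors["u"].params == (0.0, 1.0)

    def test_windows_chain_through_observation_times(self, small_run):
        result, _ = small_run
        for prev, cur in zip(result.records, result.records[1:]):
            assert cur.t_start == prev.t_end

    def test_reproducible_under_fixed_seed(self, tiny_dataset, small_run):
        result, cfg = small_run
        again = run_pipeline(tiny_dataset, dataclasses.replace(cfg))
        for a, b in zip(result.records, again.records):
            np.testing.assert_array_equal(a.samples.draws["D"], b.samples.draws["D"])

    def test_single_step_pipeline_equals_run_step(self, tiny_dataset):
        cfg = PipelineConfig(
            n_iter=800, burn_in=200, n_nodes=31, substeps=10, seed=5, max_steps=1
        )
        result = run_pipeline(tiny_dataset, cfg)
        assert len(result.records) == 1
        from chemograd.sequential_pipeline import _resolve_bc

        grid = SpatialGrid(tiny_dataset.width_mm, cfg.n_nodes)
        bc_l, bc_r = _resolve_bc(tiny_dataset, cfg)
        seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0])
        direct = run_step(
            tiny_dataset.profiles[1],
            interpolate_initial(tiny_dataset.profiles[0]),
            bc_l, bc_r, make_priors(1, None, cfg), grid,
            tiny_dataset.t0_s, cfg, seed,
        )
        np.testing.assert_array_equal(
            result.records[0].samples.draws["D"], direct.samples.draws["D"]
        )

    def test_summary_frame_layout(self, small_run):
        result, _ = small_run
        df = result.summary_frame()
        assert list(df.columns) == [
            "time_s", "parameter", "mean", "median", "sd",
            "hpd95_low", "hpd95_high",
        ]
        assert len(df) == 3 * len(result.records)

    def test_boundary_coverage_gap_fails_before_sampling(self, tiny_synthetic):
        ds = tiny_synthetic.dataset
        short = {
            side: dataclasses.replace(
                s, times=s.times[s.times <= 60.0], values=s.values[s.times <= 60.0]
            )
            for side, s in ds.boundaries.items()
        }
        clipped = Dataset(
            name=ds.name, width_mm=ds.width_mm, t0_s=ds.t0_s,
            profiles=ds.profiles, boundaries=short,
        )
        with pytest.raises(ValueError, match="covers"):
            run_pipeline(clipped, PipelineConfig(n_iter=100, burn_in=10))

    def test_single_profile_dataset_rejected(self, tiny_dataset):
        ds = Dataset(
            name="one", width_mm=tiny_dataset.width_mm, t0_s=tiny_dataset.t0_s,
            profiles=tiny_dataset.profiles[:1], boundaries=tiny_dataset.boundaries,
        )
        with pytest.raises(ValueError, match="observation"):
            run_pipeline(ds, PipelineConfig())
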