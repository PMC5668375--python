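"""Tests of weighted least squares, the UNDX/MGG genetic algorithm, and
the simulation-based fitting stages."""

import numpy as np
import pytest

from bcrsurv.fitting import (
    FitResult,
    GAConfig,
    consensus,
    fit_binding_constants,
    fit_decay_rate,
    fit_tonic_stage,
    ga_optimize,
    weighted_objective,
)
from bcrsurv.model import ModelParameters, bcr_level_at
from bcrsurv.synth import (
    ObservationSet,
    default_cohort,
    generate_mfi_decay_observations,
    generate_occupancy_observations,
    generate_viability_observations,
)

TABLE = ModelParameters.published()


class TestWeightedObjective:
    def test_perfect_fit_is_zero(self):
        obs = ObservationSet(x=[1, 2], y=[0.5, 0.3], sd=[0.1, 0.2], kind="mfi_decay")
        assert weighted_objective(obs, [0.5, 0.3]) == 0.0

    def test_single_point_arithmetic(self):
        obs = ObservationSet(x=[1], y=[1.0], sd=[0.5], kind="mfi_decay")
        assert weighted_objective(obs, [0.0]) == pytest.approx(4.0)

    def test_scaling_law(self):
        obs1 = ObservationSet(x=[1, 2, 3], y=[1, 2, 3], sd=[0.1, 0.2, 0.3], kind="viability")
        obs2 = ObservationSet(x=[1, 2, 3], y=[1, 2, 3], sd=[0.2, 0.4, 0.6], kind="viability")
        pred = [0.5, 1.5, 2.5]
        assert weighted_objective(obs1, pred) == pytest.approx(4 * weighted_objective(obs2, pred))

    def test_order_invariance(self):
        x, y, sd = np.array([1.0, 2, 3]), np.array([0.9, 0.5, 0.2]), np.array([0.1, 0.2, 0.3])
        pred = np.array([0.8, 0.6, 0.3])
        perm = [2, 0, 1]
        a = weighted_objective(ObservationSet(x=x, y=y, sd=sd, kind="viability"), pred)
        b = weighted_objective(
            ObservationSet(x=x[perm], y=y[perm], sd=sd[perm], kind="viability"), pred[perm]
        )
        assert a == pytest.approx(b)

    def test_zero_sd_rejected(self):
        obs = ObservationSet(x=[1], y=[1.0], sd=[0.0], kind="mfi_decay")
        with pytest.raises(ValueError):
            weighted_objective(obs, [1.0])


class TestFitDecayRate:
    def test_noiseless_self_consistency(self):
        obs = generate_mfi_decay_observations(d1=0.01435, noise_sd=0.0)
        d1 = fit_decay_rate(obs)
        assert d1 == pytest.approx(0.01435, abs=1e-6)
        # independent oracle: dense grid search over d1
        grid = np.linspace(0.01, 0.02, 10001)
        sse = [np.sum((obs.y - bcr_level_at(obs.x, 1.0, g)) ** 2) for g in grid]
        assert d1 == pytest.approx(grid[int(np.argmin(sse))], abs=1e-6)

    def test_constant_observations_give_zero_rate(self):
        obs = ObservationSet(x=[0, 18, 48, 72], y=[1, 1, 1, 1], sd=[1, 1, 1, 1], kind="mfi_decay")
        assert fit_decay_rate(obs) == 0.0

    def test_weighting_changes_noisy_fit(self):
        rng = np.random.Generator(np.random.MT19937(4))
        t = np.array([0.0, 18, 48, 72])
        y = np.clip(bcr_level_at(t, 1.0, 0.0143) + rng.normal(0, 0.05, 4), 0.01, 1)
        flat = ObservationSet(x=t, y=y, sd=np.full(4, 0.05), kind="mfi_decay")
        tilted = ObservationSet(x=t, y=y, sd=np.array([0.01, 0.3, 0.3, 0.01]), kind="mfi_decay")
        assert fit_decay_rate(flat) != pytest.approx(fit_decay_rate(tilted), abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_decay_rate(ObservationSet(x=[0], y=[1], sd=[1], kind="mfi_decay"))
        with pytest.raises(ValueError):
            fit_decay_rate(ObservationSet(x=[0, 1], y=[0, 0], sd=[1, 1], kind="mfi_decay"))


@pytest.fixture(scope="module")
def datasets():
    titration = generate_occupancy_observations(
        2.779, 3.145, "titration", [0.1, 0.3, 1, 3, 10, 30], noise_sd=0.0
    )
    time_course = generate_occupancy_observations(
        2.779, 3.145, "time_course",
        [1 / 12, 1 / 6, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0], noise_sd=0.0, anti_igm=1.0,
    )
    return titration, time_course


class TestFitBindingConstants:
    def test_noiseless_recovery_within_one_percent(self, datasets):
        k2, k3 = fit_binding_constants(*datasets)
        assert k2 == pytest.approx(2.779, rel=0.01)
        assert k3 == pytest.approx(3.145, rel=0.01)

    def test_recovered_ratio_matches_published(self, datasets):
        k2, k3 = fit_binding_constants(*datasets)
        assert round(k3 / k2, 3) == 1.132

    def test_oracle_grid_search_agrees(self, datasets):
        """2-D grid search over (k2, k3) finds the same optimum basin."""
        titration, time_course = datasets
        k2s = np.linspace(2.0, 3.5, 61)
        k3s = np.linspace(2.5, 4.0, 61)
        from bcrsurv.model import occupancy_closed_form

        best = min(
            ((np.sum((time_course.y - occupancy_closed_form(1.0, time_course.x, a, b)) ** 2)
              + np.sum((titration.y - (titration.x / (titration.x + b / a))
                        / (30.0 / (30.0 + b / a))) ** 2), a, b)
             for a in k2s for b in k3s)
        )
        k2, k3 = fit_binding_constants(titration, time_course)
        assert k2 == pytest.approx(best[1], abs=0.05)
        assert k3 == pytest.approx(best[2], abs=0.05)

    def test_time_rescaling_degeneracy(self):
        """Halving (k2, k3) and doubling time gives the identical curve —
        the time course pins the scale only through its time axis."""
        t = np.linspace(0.05, 2.0, 8)
        a = generate_occupancy_observations(2.779, 3.145, "time_course", t, noise_sd=0.0)
        b = generate_occupancy_observations(2.779 / 2, 3.145 / 2, "time_course", 2 * t, noise_sd=0.0)
        assert np.allclose(a.y, b.y)

    def test_too_few_points_rejected(self):
        short = ObservationSet(x=[1, 2], y=[0.3, 0.4], sd=[1, 1], kind="occupancy_titration")
        with pytest.raises(ValueError):
            fit_binding_constants(short, short)


class TestGAConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            GAConfig(init_ranges=((0, 1),), population_size=2)
        with pytest.raises(ValueError):
            GAConfig(init_ranges=((1, 1),))
        with pytest.raises(ValueError):
            GAConfig(init_ranges=((0, 1),), convergence_tol=0)

    def test_sigma_eta_default_scales_with_dimension(self):
        assert GAConfig(init_ranges=((0, 1),) * 4).sigma_eta == pytest.approx(0.35 / 2)


class TestGaOptimize:
    def test_sphere_benchmark(self):
        """Convex 3-D benchmark: optimum found to <=1e-3 within 500 generations."""
        cfg = GAConfig(init_ranges=((0.0, 0.2),) * 3, max_generations=500)
        res = ga_optimize(lambda x: float(np.sum((x - 0.1) ** 2)), cfg, seed=0)
        assert res.objective <= 1e-3
        assert res.generations <= 500

    def test_best_objective_monotone_non_increasing(self):
        """Elitism: the returned optimum is the best value ever evaluated."""
        cfg = GAConfig(init_ranges=((0.0, 1.0),) * 2, max_generations=120,
                       children_per_generation=10)
        seen = []

        def objective(x):
            v = float(np.sum(x ** 2))
            seen.append(v)
            return v

        res = ga_optimize(objective, cfg, seed=3)
        assert res.objective == pytest.approx(np.min(seen))

    def test_candidates_stay_in_box(self):
        lo, hi = 0.05, 0.2

        def objective(x):
            assert np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12)
            return float(np.sum(x ** 2))

        cfg = GAConfig(init_ranges=((lo, hi),) * 3, max_generations=60,
                       children_per_generation=20)
        res = ga_optimize(objective, cfg, seed=1)
        assert all(lo <= v <= hi for v in res.params.values())

    def test_non_finite_objective_ranked_worst_not_dropped(self):
        calls = {"n": 0}

        def objective(x):
            calls["n"] += 1
            if x[0] > 0.15:
                return np.nan
            return float(x[0])

        cfg = GAConfig(init_ranges=((0.0, 0.2),), population_size=10,
                       children_per_generation=5, max_generations=50)
        res = ga_optimize(objective, cfg, seed=2)
        assert np.isfinite(res.objective)
        assert res.params["x0"] <= 0.15

    def test_seeded_reproducibility(self):
        cfg = GAConfig(init_ranges=((0.0, 1.0),) * 2, max_generations=40,
                       children_per_generation=10)
        f = lambda x: float((x[0] - 0.3) ** 2 + (x[1] - 0.7) ** 2)
        a = ga_optimize(f, cfg, seed=9)
        b = ga_optimize(f, cfg, seed=9)
        assert a.params == b.params and a.objective == b.objective


TONIC = ModelParameters.tonic_fit()


@pytest.fixture(scope="module")
def tonic_setup():
    # 50-cell quantile cohort: small enough for full GA convergence
    from bcrsurv.simulate import Cohort

    cohort = Cohort(default_cohort(seed=0).initial_bcr_levels[::4])
    obs = generate_viability_observations(
        TONIC, cohort, doses=[0.0], noise_sd=0.0, seed=0
    )
    return cohort, obs


class TestTonicStage:

    def test_fit_quality_beats_truth_objective(self, tonic_setup):
        """On noiseless data the optimizer matches the truth's (zero)
        objective and stays inside the search box."""
        cohort, obs = tonic_setup
        cfg = GAConfig(init_ranges=((0.0, 0.2),) * 3, max_generations=400)
        res = fit_tonic_stage(obs, cohort, d1=TONIC.d1, config=cfg, seed=0)
        from bcrsurv.simulate import simulate_cohort

        truth_pred = simulate_cohort(cohort, 0.0, TONIC, obs[0].x)
        truth_obj = float(np.sum((obs[0].y - truth_pred) ** 2))
        assert res.objective <= truth_obj + 1e-12
        assert all(0.0 <= v <= 0.2 for v in res.params.values())

    def test_requires_dose_zero_observations(self, tonic_setup):
        cohort, _ = tonic_setup
        stim_only = generate_viability_observations(
            TONIC, cohort, doses=[3.0], noise_sd=0.0, seed=0
        )
        with pytest.raises(ValueError):
            fit_tonic_stage(stim_only, cohort, d1=TONIC.d1)


class TestK4Identifiability:
    def test_high_dose_rows_pin_k4(self):
        """Without the near-saturating dose the objective profile along
        k4 flattens severely: only occupancy well above the activation
        threshold exercises the crosslinked-signal rate."""
        cohort = default_cohort(seed=0)
        obs = generate_viability_observations(
            TABLE, cohort, doses=[0.0, 0.3, 3.0, 10.0], noise_sd=0.0, seed=0
        )
        from bcrsurv.simulate import simulate_cohort

        def profile(subset, k4s):
            out = []
            for k4 in k4s:
                p = TABLE.replace(k4=k4)
                out.append(sum(
                    float(np.sum((o.y - simulate_cohort(cohort, o.dose, p, o.x)) ** 2))
                    for o in subset
                ))
            return np.array(out)

        k4s = np.linspace(0.0, 0.2, 9)
        full = profile(obs, k4s)
        no_high = profile([o for o in obs if o.dose < 10.0], k4s)
        assert full.min() <= 1e-3 and no_high.min() <= 1e-3  # truth fits both
        assert (full.max() - full.min()) > 4 * (no_high.max() - no_high.min())


class TestConsensus:
    def test_identical_results_zero_sd(self):
        r = FitResult(params={"k1": 0.03}, objective=1.0, seed=0)
        cons = consensus([r, FitResult(params={"k1": 0.03}, objective=2.0, seed=1)])
        assert cons.params["k1"] == pytest.approx(0.03)
        assert cons.percent_sd["k1"] == pytest.approx(0.0)

    def test_two_point_sample_sd_convention(self):
        a = FitResult(params={"p": 0.1}, objective=0.0, seed=0)
        b = FitResult(params={"p": 0.3}, objective=0.0, seed=1)
        cons = consensus([a, b])
        assert cons.params["p"] == pytest.approx(0.2)
        # sample SD of {0.1, 0.3} is 0.1*sqrt(2); as percent of mean: 50*sqrt(2)
        assert cons.percent_sd["p"] == pytest.approx(50 * np.sqrt(2))

    def test_multi_seed_convex_consensus_is_tight(self):
        cfg = GAConfig(init_ranges=((0.0, 0.2),) * 3, max_generations=300)
        results = [
            ga_optimize(lambda x: float(np.sum((x - 0.1) ** 2)), cfg, seed=s,
                        param_names=("a", "b", "c"))
            for s in range(10)
        ]
        cons = consensus(results)
        assert all(v < 5.0 for v in cons.percent_sd.values())

    def test_needs_two_results(self):
        with pytest.raises(ValueError):
            consensus([FitResult(params={"p": 1.0}, objective=0.0)])
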