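"""One-way DSA, tornado aggregation, PSA sampling, CEAC construction."""

import numpy as np
import pytest

from markovcea import (
    DSAScenario,
    ModelSpec,
    apply_scenario,
    compute_ceac,
    compute_icer,
    evaluate_strategy,
    run_dsa,
    run_psa,
    sample_psa_draw,
    standard_dsa_scenarios,
    tornado_table,
    validate_model_spec,
)


@pytest.fixture(scope="module")
def dsa_run(bph_spec):
    scenarios = standard_dsa_scenarios(bph_spec)
    baseline, results = run_dsa(bph_spec, scenarios)
    return scenarios, baseline, results


class TestScenarioSet:
    def test_contains_the_standard_scenarios(self, dsa_run):
        scenarios, _, _ = dsa_run
        values = {
            s.scenario_value for s in scenarios if s.group == "discount_rate"
        }
        assert values == {0.01, 0.02, 0.03, 0.04, 0.05, 0.06}
        assert any(s.group == "horizon" and s.scenario_value == 15 for s in scenarios)
        assert any(s.group == "horizon" and s.scenario_value == 5 for s in scenarios)
        assert any(s.group == "cohort_size" and s.scenario_value == 570_000 for s in scenarios)
        assert any(
            s.group == "entry_state" and s.scenario_value == {"moderate": 1.0}
            for s in scenarios
        )

    def test_moderate_utility_band_values(self, dsa_run):
        scenarios, _, _ = dsa_run
        vals = sorted(
            s.scenario_value for s in scenarios if s.group == "utility[moderate]"
        )
        assert vals == [pytest.approx(0.787 * 0.8), pytest.approx(0.787 * 1.2)]
        assert vals[0] == pytest.approx(0.6296)
        assert vals[1] == pytest.approx(0.9444)

    def test_utility_scenarios_capped_at_one(self, dsa_run):
        scenarios, _, _ = dsa_run
        healthy = [s for s in scenarios if s.group == "utility[healthy]"]
        assert all(s.scenario_value <= 1.0 for s in healthy)

    def test_every_scenario_yields_valid_spec(self, bph_spec, dsa_run):
        scenarios, _, _ = dsa_run
        for scenario in scenarios:
            assert validate_model_spec(apply_scenario(bph_spec, scenario)).ok


class TestDSA:
    def test_null_scenario_zero_deviation(self, bph_spec):
        null = DSAScenario(
            label="null",
            group="null",
            parameter_path="discount.annual_rate",
            baseline_value=0.06,
            scenario_value=0.06,
        )
        _, results = run_dsa(bph_spec, [null])
        assert results[0].deviation == 0.0

    def test_deterministic(self, bph_spec, dsa_run):
        scenarios, baseline, results = dsa_run
        baseline2, results2 = run_dsa(bph_spec, scenarios)
        assert baseline2 == baseline
        assert [r.icer for r in results2] == [r.icer for r in results]

    def test_longer_horizon_lowers_icer(self, dsa_run):
        _, baseline, results = dsa_run
        fifteen = next(
            r for r in results
            if r.scenario.group == "horizon" and r.scenario.scenario_value == 15
        )
        assert fifteen.icer < baseline

    def test_icer_monotone_over_discount_grid(self, dsa_run):
        # regression: on the bundled model the ICER increases with the rate
        _, _, results = dsa_run
        grid = sorted(
            (r.scenario.scenario_value, r.icer)
            for r in results
            if r.scenario.group == "discount_rate"
        )
        icers = [i for _, i in grid]
        assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_cohort_size_scenario_leaves_icer_unchanged(self, dsa_run):
        _, _, results = dsa_run
        r = next(r for r in results if r.scenario.group == "cohort_size")
        assert r.deviation == pytest.approx(0.0, abs=1e-6)

    def test_invalid_scenario_recorded_and_run_continues(self, bph_spec):
        bad = DSAScenario(
            label="bad",
            group="bad",
            parameter_path="states[mild].utility",
            baseline_value=0.883,
            scenario_value=1.5,
        )
        ok = DSAScenario(
            label="ok",
            group="ok",
            parameter_path="discount.annual_rate",
            baseline_value=0.06,
            scenario_value=0.03,
        )
        _, results = run_dsa(bph_spec, [bad, ok])
        assert not results[0].ok
        assert "utility" in results[0].error
        assert results[1].ok


class TestTornado:
    def test_baseline_entry_present_with_zero_spread(self, dsa_run):
        _, baseline, results = dsa_run
        entries = tornado_table(baseline, results)
        base = next(e for e in entries if e.group == "baseline")
        assert base.icer_low == base.icer_high == baseline
        assert base.max_abs_deviation == 0.0

    def test_sorted_by_descending_spread(self, dsa_run):
        _, baseline, results = dsa_run
        entries = tornado_table(baseline, results)
        devs = [e.max_abs_deviation for e in entries]
        assert devs == sorted(devs, reverse=True)

    def test_groups_span_their_scenarios(self, dsa_run):
        _, baseline, results = dsa_run
        entries = {e.group: e for e in tornado_table(baseline, results)}
        disc = [r.icer for r in results if r.scenario.group == "discount_rate"]
        assert entries["discount_rate"].icer_low == min(disc)
        assert entries["discount_rate"].icer_high == max(disc)


class TestPSASampling:
    def test_zero_sd_reproduces_baseline(self, bph_spec):
        rng = np.random.default_rng(0)
        assert sample_psa_draw(bph_spec, rng, sd_fraction=0.0) == bph_spec

    def test_drawn_probabilities_in_unit_interval_and_valid(self, bph_spec):
        rng = np.random.default_rng(42)
        for _ in range(300):
            drawn = sample_psa_draw(bph_spec, rng)
            for t in drawn.transitions:
                assert 0.0 <= t.annual_probability <= 1.0
            assert validate_model_spec(drawn).ok

    def test_cost_draws_moment_matched(self, bph_spec):
        rng = np.random.default_rng(7)
        draws = np.array(
            [sample_psa_draw(bph_spec, rng).state("turp").event_cost for _ in range(10_000)]
        )
        assert draws.mean() == pytest.approx(484.97, rel=0.01)
        assert draws.std() == pytest.approx(0.2 * 484.97, rel=0.1)

    def test_shared_parameters_get_common_draws(self, bph_spec):
        # background mortality is identical across strategies, so each draw
        # must assign both strategies the same perturbed value
        rng = np.random.default_rng(3)
        drawn = sample_psa_draw(bph_spec, rng)
        for state in ("healthy", "mild", "moderate", "severe"):
            assert drawn.transition("DM", state, "death") == drawn.transition(
                "FDCT", state, "death"
            )

    def test_degenerate_utilities_held_fixed(self, bph_spec):
        rng = np.random.default_rng(5)
        drawn = sample_psa_draw(bph_spec, rng)
        assert drawn.state("healthy").utility == 1.0
        assert drawn.state("death").utility == 0.0


class TestPSARun:
    def test_single_draw_zero_sd_equals_deterministic(self, bph_spec, bph_outcomes):
        psa = run_psa(bph_spec, n=1, seed=0, sd_fraction=0.0)
        det = compute_icer(bph_outcomes["FDCT"], bph_outcomes["DM"])
        assert psa.draws[0, 0] == pytest.approx(det.delta_cost)
        assert psa.draws[0, 1] == pytest.approx(det.delta_effect)

    def test_seed_reproducibility(self, bph_spec):
        a = run_psa(bph_spec, n=20, seed=123)
        b = run_psa(bph_spec, n=20, seed=123)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.quadrants == b.quadrants

    def test_different_seeds_differ(self, bph_spec):
        a = run_psa(bph_spec, n=5, seed=1)
        b = run_psa(bph_spec, n=5, seed=2)
        assert not np.array_equal(a.draws, b.draws)

    def test_rejects_nonpositive_n(self, bph_spec):
        with pytest.raises(ValueError):
            run_psa(bph_spec, n=0, seed=0)


class TestCEAC:
    def test_single_tradeoff_draw(self, bph_spec):
        psa = run_psa(bph_spec, n=1, seed=0, sd_fraction=0.0)
        psa = psa.__class__(
            intervention="i", comparator="c", n_draws=1, seed=0,
            draws=np.array([[1.0, 1.0]]), quadrants=["NE"],
        )
        (point,) = compute_ceac(psa, [2.0])
        assert point.probability_cost_effective == 1.0

    def test_enumerated_half_acceptance(self):
        from markovcea.sensitivity import PSAResult

        psa = PSAResult(
            intervention="i", comparator="c", n_draws=2, seed=0,
            draws=np.array([[10.0, 1.0], [10.0, -1.0]]), quadrants=["NE", "NW"],
        )
        (point,) = compute_ceac(psa, [20.0])
        assert point.probability_cost_effective == 0.5

    def test_zero_wtp_with_positive_costs(self):
        from markovcea.sensitivity import PSAResult

        psa = PSAResult(
            intervention="i", comparator="c", n_draws=3, seed=0,
            draws=np.array([[1.0, 1.0], [2.0, -1.0], [0.5, 0.0]]),
            quadrants=["NE", "NW", "cost-axis"],
        )
        (point,) = compute_ceac(psa, [0.0])
        assert point.probability_cost_effective == 0.0

    def test_zero_sd_curve_steps_at_deterministic_icer(self, bph_spec, bph_outcomes):
        det = compute_icer(bph_outcomes["FDCT"], bph_outcomes["DM"])
        psa = run_psa(bph_spec, n=1, seed=0, sd_fraction=0.0)
        below, above = det.icer * 0.9, det.icer * 1.1
        points = compute_ceac(psa, [below, above])
        assert points[0].probability_cost_effective == 0.0
        assert points[1].probability_cost_effective == 1.0

    def test_probabilities_match_brute_force_nmb_enumeration(self, bph_spec):
        from markovcea.cea import compute_nmb

        psa = run_psa(bph_spec, n=50, seed=9)
        grid = [0.0, 200.0, 489.95, 1000.0, 2450.0, 10_000.0]
        for point in compute_ceac(psa, grid):
            count = sum(
                1
                for dc, de in psa.draws
                if compute_nmb((dc, de), point.wtp) > 0  # wtp·ΔE − ΔC > 0
            )
            assert point.probability_cost_effective == pytest.approx(count / psa.n_draws)

    def test_empty_grid_rejected(self, bph_spec):
        psa = run_psa(bph_spec, n=2, seed=0)
        with pytest.raises(ValueError):
            compute_ceac(psa, [])
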