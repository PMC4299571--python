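"""Scale-up projection and affordability arithmetic."""

import numpy as np
import pytest

from clustercea.costs import InterventionCostSummary
from clustercea.outcomes import OutcomeDraws
from clustercea.scaleup import (
    MALAWI_2010,
    NationalContext,
    ScaleUpScenario,
    affordability_table,
    annualize_trial_quantities,
    budget_share,
    discounted_stream,
    evaluate_scenario,
    mnh_budget,
    national_annual_cost,
    population_ratio,
    scenario_grid,
    scenario_table,
)

CI = InterventionCostSummary("CI", 362_083, 2_068_997, 27_250, 120_067)
FI = InterventionCostSummary("FI", 362_860, 2_026_811, 25_328, 272_017)
FICI2 = InterventionCostSummary("FICI", 724_943, 4_095_808, 52_578, 392_084)


def _outcomes(label, mean, sd, n=2000, seed=0):
    rng = np.random.default_rng(seed)
    dalys = rng.normal(mean, sd, n)
    return OutcomeDraws(label, np.zeros(n), np.zeros(n), dalys)


def test_annualisation_divides_effects_by_trial_period():
    out = _outcomes("CI", 67_361, 0.0, n=5)
    start_up, annual, annual_draws = annualize_trial_quantities(CI, out, 2.25)
    assert start_up == 362_083
    assert annual == pytest.approx(2_216_314)
    assert annual_draws[0] == pytest.approx(29_938.2, abs=0.05)


@pytest.mark.parametrize(
    "annual,rate,horizon,expected",
    [(100, 0.0, 10, 1000.0), (100, 0.03, 10, 878.61), (100, 0.07, 1, 100.0)],
)
def test_discounted_stream_examples(annual, rate, horizon, expected):
    assert discounted_stream(annual, rate, horizon) == pytest.approx(expected, abs=0.005)


def test_discounting_decreases_with_rate_and_grows_with_horizon():
    rates = [0.0, 0.02, 0.05, 0.10]
    values = [discounted_stream(100, r, 10) for r in rates]
    assert values == sorted(values, reverse=True)
    horizons = [1, 2, 5, 20]
    values = [discounted_stream(100, 0.03, h) for h in horizons]
    assert values == sorted(values)


def test_discounted_stream_vectorises_over_draws():
    draws = np.array([100.0, 200.0])
    np.testing.assert_allclose(
        discounted_stream(draws, 0.03, 10), draws * discounted_stream(1.0, 0.03, 10)
    )


def test_population_ratio_matches_printed_value():
    assert population_ratio() == pytest.approx(12.5114, abs=0.0001)


@pytest.mark.parametrize(
    "summary,printed",
    [(CI, 27_729_225), (FI, 29_078_474), (FICI2, 56_807_699)],
)
def test_national_annual_costs(summary, printed):
    annual = summary.annual_implementation + summary.annual_maintenance + summary.annual_external
    assert national_annual_cost(annual, population_ratio()) == pytest.approx(printed, rel=1e-5)


def test_national_scaling_is_linear():
    assert national_annual_cost(100.0, 1.0) == 100.0
    assert national_annual_cost(200.0, 2.5) == 500.0


def test_mnh_budget_from_2010_inputs():
    # printed 410,354,347 comes from pre-rounded inputs; recomputation is within 0.01%
    assert mnh_budget(MALAWI_2010) == pytest.approx(410_354_347, rel=1e-4)
    assert mnh_budget(NationalContext(mnh_share=0.5)) == pytest.approx(
        MALAWI_2010.per_capita_health_expenditure * MALAWI_2010.population * 0.5
    )


def test_budget_doubles_with_population():
    ctx2 = NationalContext(population=2 * MALAWI_2010.population)
    assert mnh_budget(ctx2) == pytest.approx(2 * mnh_budget(MALAWI_2010))


@pytest.mark.parametrize(
    "summary,printed_pct",
    [(CI, 6.8), (FI, 7.1), (FICI2, 13.8)],
)
def test_budget_shares_to_printed_decimal(summary, printed_pct):
    annual = summary.annual_implementation + summary.annual_maintenance + summary.annual_external
    national = national_annual_cost(annual, population_ratio())
    share = budget_share(national, mnh_budget())
    assert round(100 * share, 1) == printed_pct


def test_budget_share_rejects_zero_budget():
    with pytest.raises(ValueError):
        budget_share(100.0, 0.0)


def test_affordability_table_per_person_costs():
    table = affordability_table({"CI": CI, "FI": FI, "FICI": FICI2}).set_index("intervention")
    assert round(table.loc["CI", "cost_per_person"], 2) == 23.09
    assert round(table.loc["FI", "cost_per_person"], 2) == 24.21
    assert round(table.loc["FICI", "cost_per_person"], 2) == 47.30


def test_degenerate_scenario_reduces_to_single_year_cea():
    """No uncertainty, zero rates, one year, ratio 1: plain deterministic CEA."""
    outcomes = {"CI": _outcomes("CI", 67_361, 0.0)}
    scenario = ScaleUpScenario(
        horizon_years=1, cost_discount=0.0, effect_discount=0.0,
        population_ratio=1.0, threshold_k=780.0,
    )
    res = evaluate_scenario({"CI": CI}, outcomes, scenario, trial_years=2.25)
    vals = res.options["CI"]
    annual_dalys = 67_361 / 2.25
    assert vals["cost"] == pytest.approx(362_083 + 2_216_314)
    assert vals["dalys"] == pytest.approx(annual_dalys)
    assert vals["eib"] == pytest.approx(780 * annual_dalys - (362_083 + 2_216_314))


def test_scenario_grid_shape_and_independence():
    costs = {"CI": CI, "FICI": FICI2}
    outcomes = {
        "CI": _outcomes("CI", 67_361, 28_750, seed=1),
        "FICI": _outcomes("FICI", 75_180, 40_439, seed=2),
    }
    results = scenario_grid(costs, outcomes)
    assert len(results) == 27
    # each scenario is reproducible from its configuration alone
    probe = results[13]
    redo = evaluate_scenario(costs, outcomes, probe.scenario)
    assert redo.options == probe.options
    table = scenario_table(results)
    assert len(table) == 27 * 2


def test_higher_cost_discount_raises_every_eib():
    costs = {"CI": CI}
    outcomes = {"CI": _outcomes("CI", 67_361, 20_000, seed=3)}
    eibs = []
    for rate in (0.0, 0.03, 0.10):
        scenario = ScaleUpScenario(cost_discount=rate)
        eibs.append(evaluate_scenario(costs, outcomes, scenario).options["CI"]["eib"])
    assert eibs == sorted(eibs)


def test_scenario_validation():
    with pytest.raises(ValueError):
        ScaleUpScenario(horizon_years=0)
    with pytest.raises(ValueError):
        ScaleUpScenario(cost_discount=1.5)
    with pytest.raises(ValueError):
        NationalContext(mnh_share=0.0)
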