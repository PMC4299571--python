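"""Decision analysis: ICER, EIB, CEAC, EVPI and the incremental frontier."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clustercea.cea import (
    CEAInput,
    ThresholdGrid,
    UndefinedICERError,
    analyse,
    best_option_probabilities,
    ceac,
    eib,
    evpi,
    icer,
    incremental_frontier,
    three_way_ranking,
)


def _const(label, cost, effect, n=10):
    return CEAInput(label, cost, np.full(n, float(effect)))


NOTHING = CEAInput.do_nothing(10)


def test_icer_against_current_practice():
    assert icer(_const("CI", 5_348_791, 67_361), NOTHING).value == pytest.approx(79.4, abs=0.05)
    assert icer(_const("FI", 5_592_212, 19_901), NOTHING).value == pytest.approx(281.0, abs=0.05)


def test_icer_flags_dominance():
    res = icer(_const("A", 100, 50), _const("B", 200, 10))
    assert res.dominance == "reference_dominates"
    res = icer(_const("A", 200, 10), _const("B", 100, 50))
    assert res.dominance == "reference_dominated"


def test_zero_incremental_effect_is_undefined():
    with pytest.raises(UndefinedICERError) as err:
        icer(_const("A", 100, 5), _const("B", 40, 5))
    assert err.value.incremental_cost == pytest.approx(60)


@pytest.mark.parametrize(
    "cost,effect,printed",
    [
        (5_348_791, 67_361, 47_192_789),
        (5_470_501, 37_590, 23_849_699),
    ],
)
def test_expected_incremental_benefit_at_reference_threshold(cost, effect, printed):
    assert eib(_const("x", cost, effect), 780.0) == pytest.approx(printed, abs=1.0)


def test_eib_breaks_even_at_the_icer():
    opt = _const("CI", 5_348_791, 67_361)
    k_star = icer(opt, NOTHING).value
    assert eib(opt, k_star) == pytest.approx(0.0, abs=1e-6)


def test_eib_linear_in_k():
    opt = _const("x", 1000, 10)
    ks = np.array([0.0, 50.0, 100.0])
    values = eib(opt, ks)
    assert np.allclose(np.diff(values, 2), 0.0)


def test_ceac_certain_winner():
    grid = ThresholdGrid(np.array([1000.0]))
    ref = CEAInput("ref", 0.0, np.array([5.0, 6.0]))
    comp = CEAInput("comp", 10.0, np.array([1.0, 2.0]))
    assert ceac(ref, comp, grid)[0] == 1.0


def test_ceac_at_zero_threshold_cost_decides():
    grid = ThresholdGrid(np.array([0.0, 100.0]))
    ref = CEAInput("ref", 10.0, np.array([100.0, 100.0]))
    comp = CEAInput("comp", 5.0, np.array([0.0, 0.0]))
    assert ceac(ref, comp, grid)[0] == 0.0


def test_ceac_two_draw_toy_enumeration():
    # net-benefit differences {10, -2} at k=1: reference better in 1 of 2 draws
    grid = ThresholdGrid(np.array([1.0]))
    ref = CEAInput("ref", 0.0, np.array([10.0, -2.0]))
    comp = CEAInput("comp", 0.0, np.array([0.0, 0.0]))
    assert ceac(ref, comp, grid)[0] == 0.5


def test_ceac_ties_count_against_reference():
    grid = ThresholdGrid(np.array([1.0]))
    same = CEAInput("ref", 0.0, np.array([1.0, 1.0]))
    assert ceac(same, CEAInput("comp", 0.0, np.array([1.0, 1.0])), grid)[0] == 0.0


def test_ceac_complement_property():
    rng = np.random.default_rng(4)
    a = CEAInput("a", 120.0, rng.normal(3, 1, 500))
    b = CEAInput("b", 80.0, rng.normal(2, 1, 500))
    grid = ThresholdGrid(np.linspace(1, 400, 7))
    np.testing.assert_allclose(ceac(a, b, grid), 1.0 - ceac(b, a, grid))


def test_ceac_monotone_for_costly_option_vs_do_nothing():
    rng = np.random.default_rng(5)
    opt = CEAInput("x", 500.0, rng.normal(2, 3, 2000))
    grid = ThresholdGrid(np.linspace(0, 5000, 101))
    curve = ceac(opt, CEAInput.do_nothing(2000), grid)
    assert np.all(np.diff(curve) >= 0)


def test_ceac_requires_matched_draws():
    with pytest.raises(ValueError, match="matched"):
        ceac(_const("a", 1, 1, n=5), _const("b", 1, 1, n=6), ThresholdGrid(np.array([1.0])))


def test_evpi_hand_enumeration():
    # two equally likely draws: NB_A {10, 0}, NB_B {0, 4}; E[max]=7, max E=5
    a = CEAInput("A", 0.0, np.array([10.0, 0.0]))
    b = CEAInput("B", 0.0, np.array([0.0, 4.0]))
    assert evpi([a, b], k=1.0, include_do_nothing=False) == pytest.approx(2.0)


def test_evpi_zero_without_decision_uncertainty():
    opt = CEAInput("A", 1.0, np.array([10.0, 12.0]))
    assert evpi([opt], k=1.0) == pytest.approx(0.0)


def test_evpi_matches_brute_force_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n_opts, n_draws = rng.integers(2, 5), rng.integers(2, 11)
        k = float(rng.uniform(0, 100))
        opts = [
            CEAInput(f"o{i}", float(rng.uniform(0, 50)), rng.normal(0, 5, n_draws))
            for i in range(n_opts)
        ]
        nb = [[k * e - o.total_cost for e in o.effect_draws] for o in opts] + [[0.0] * n_draws]
        e_max = sum(max(col) for col in zip(*nb)) / n_draws
        max_e = max(sum(row) / n_draws for row in nb)
        assert evpi(opts, k) == pytest.approx(e_max - max_e, abs=1e-9)


@given(st.integers(0, 999))
def test_evpi_never_negative(case):
    rng = np.random.default_rng(case)
    opts = [
        CEAInput(f"o{i}", float(rng.uniform(0, 100)), rng.normal(0, 10, 20))
        for i in range(rng.integers(1, 4))
    ]
    assert evpi(opts, float(rng.uniform(0, 50))) >= 0.0


def test_evpi_vanishes_as_uncertainty_shrinks():
    rng = np.random.default_rng(8)
    base = rng.normal(0, 1, 5000)
    values = [
        evpi([CEAInput("x", 50.0, 60.0 + scale * base)], k=1.0)
        for scale in (20.0, 5.0, 1.0, 0.01)
    ]
    assert values == sorted(values, reverse=True)
    assert values[-1] < 1e-3


def test_three_way_dominance_from_printed_means():
    ci = _const("CI", 5_348_791, 67_361)
    fi = _const("FI", 5_592_212, 19_901)
    fici = _const("FICI", 10_941_002, 75_180)
    res = three_way_ranking(ci, fi, fici, k=780.0)
    assert res.dominated == {"FI": "dominated"}
    assert res.frontier == ["CI", "FICI"]
    (rec,) = res.frontier_icers
    assert (rec["from"], rec["to"]) == ("CI", "FICI")
    assert rec["icer"] == pytest.approx(715.2, abs=0.05)
    assert res.best_option == "FICI"


def test_identical_options_collapse_to_single_frontier_point():
    a = _const("A", 100, 10)
    b = _const("B", 100, 10)
    frontier, dominated, icers = incremental_frontier([a, b])
    assert len(frontier) == 1
    assert icers == []


def test_extended_dominance_pruning():
    # middle option's frontier ICER (10) exceeds the next one up (~3.3): pruned
    a = _const("A", 0, 0)
    b = _const("B", 100, 10)
    c = _const("C", 200, 40)
    frontier, dominated, _ = incremental_frontier([a, b, c])
    assert dominated == {"B": "extended_dominance"}
    assert frontier == ["A", "C"]


def test_best_probabilities_strict_ties_get_no_credit():
    a = CEAInput("A", 0.0, np.array([1.0, 2.0]))
    b = CEAInput("B", 0.0, np.array([1.0, 0.0]))
    probs = best_option_probabilities([a, b], k=1.0, include_do_nothing=False)
    assert probs == {"A": 0.5, "B": 0.0}


def test_analyse_bundles_consistent_tables():
    rng = np.random.default_rng(3)
    opt = CEAInput("CI", 5000.0, rng.normal(60, 20, 4000))
    res = analyse(opt, grid=ThresholdGrid.default(200, step=50, k_ref=80))
    assert res.icer is not None
    row = res.at(80.0)
    assert row["eib"] == pytest.approx(eib(opt, 80.0))
    assert 0.0 <= row["ceac"] <= 1.0
    assert row["evpi"] >= 0.0
    assert len(res.ce_plane) == 4000


def test_default_grid_contains_reference_threshold():
    grid = ThresholdGrid.default()
    assert 780.0 in grid.k_values
    assert grid.k_values[0] == 0.0 and grid.k_values[-1] == 2500.0
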