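"""Multi-year scale-up projection and affordability analysis.

Projects trial-period costs and effects to a national, multi-year programme:

* trial quantities are annualised (implementation costs and effect draws
  divided by the 2.25-year trial period; maintenance and external costs are
  already annual);
* annual streams are discounted with year 1 undiscounted and years
  ``t = 2..horizon`` discounted by ``(1+rate)^-(t-1)`` — chosen to match a
  convention of discounting "years two to ten" (many texts discount from
  year 1); start-up costs enter year 1 in full; effects use the same year
  indexing as costs, with a typically lower rate (default 2% vs 3%);
* national scaling multiplies trial costs and effects by the ratio of
  national to trial mothers-and-babies per year (12.51 for 2010 Malawi:
  1,201,096 / 96,000 — equal to the births ratio, since both numerator and
  denominator count mother and baby separately);
* affordability is the nationwide annual cost as a share of the
  maternal-and-neonatal-health (MNH) budget, estimated as per-capita health
  expenditure × population × MNH share ($228.7 × 15,013,694 × 11.95% for
  2010).

The sensitivity grid crosses horizons {5, 10, 20} years with cost discount
rates {0, 3, 10}% and effect discount rates {0, 2, 3}%, re-running the
decision analysis in each of the 27 scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cea
from .costs import InterventionCostSummary, annual_cost
from .outcomes import OutcomeDraws

__all__ = [
    "ScaleUpScenario",
    "NationalContext",
    "MALAWI_2010",
    "ScaleUpResult",
    "population_ratio",
    "annualize_trial_quantities",
    "discounted_stream",
    "national_annual_cost",
    "mnh_budget",
    "budget_share",
    "affordability_table",
    "evaluate_scenario",
    "scenario_grid",
]


@dataclass(frozen=True)
class NationalContext:
    """National population and health-expenditure figures (defaults: Malawi 2010)."""

    population: int = 15_013_694
    crude_birth_rate: float = 0.04
    per_capita_health_expenditure: float = 228.7
    mnh_share: float = 0.1195

    def __post_init__(self) -> None:
        if min(self.population, self.crude_birth_rate, self.per_capita_health_expenditure) <= 0:
            raise ValueError("population, birth rate and expenditure must be positive")
        if not 0.0 < self.mnh_share < 1.0:
            raise ValueError("MNH share must lie in (0, 1)")

    @property
    def births_per_year(self) -> float:
        return self.population * self.crude_birth_rate

    @property
    def mothers_and_babies_per_year(self) -> float:
        """Mother and baby counted separately: twice the annual births."""
        return 2.0 * self.births_per_year


MALAWI_2010 = NationalContext()


@dataclass(frozen=True)
class ScaleUpScenario:
    """One projection scenario: horizon, discount rates, scale and threshold."""

    horizon_years: int = 10
    cost_discount: float = 0.03
    effect_discount: float = 0.02
    population_ratio: float = MALAWI_2010.mothers_and_babies_per_year / 96_000
    threshold_k: float = 780.0

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError("horizon must be at least one year")
        for rate in (self.cost_discount, self.effect_discount):
            if not 0.0 <= rate < 1.0:
                raise ValueError("discount rates must lie in [0, 1)")
        if self.population_ratio <= 0:
            raise ValueError("population ratio must be positive")


def population_ratio(ctx: NationalContext = MALAWI_2010, trial_mothers_and_babies: float = 96_000) -> float:
    """National-to-trial ratio of mothers-and-babies per year (births ratio)."""
    return ctx.mothers_and_babies_per_year / trial_mothers_and_babies


def annualize_trial_quantities(
    summary: InterventionCostSummary,
    outcomes: OutcomeDraws,
    trial_years: float = 2.25,
) -> tuple[float, float, np.ndarray]:
    """(start-up cost, annual cost, annual effect draws) for one intervention.

    The cost components in :class:`InterventionCostSummary` are already
    annual, so the annual cost is their sum; effect draws, estimated over the
    whole trial period, are divided by its length, assuming the same effect
    per year.
    """
    if trial_years <= 0:
        raise ValueError("trial period must be positive")
    return summary.start_up_total, annual_cost(summary), outcomes.dalys_averted / trial_years


def discounted_stream(annual_amount, rate: float, horizon: int):
    """Present value of a constant annual stream, year 1 undiscounted.

    Years ``t = 2..horizon`` are discounted by ``(1+rate)^-(t-1)``; a one-year
    horizon is never discounted. ``annual_amount`` may be an array of draws.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least one year")
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    factor = sum((1.0 + rate) ** -(t - 1) for t in range(1, horizon + 1))
    return np.asarray(annual_amount) * factor if np.ndim(annual_amount) else annual_amount * factor


def national_annual_cost(annual_cost_value: float, ratio: float) -> float:
    """Scale an annual trial cost to the national population."""
    if ratio <= 0:
        raise ValueError("population ratio must be positive")
    return annual_cost_value * ratio


def mnh_budget(ctx: NationalContext = MALAWI_2010) -> float:
    """Total annual maternal-and-neonatal-health expenditure."""
    return ctx.per_capita_health_expenditure * ctx.population * ctx.mnh_share


def budget_share(national_cost: float, budget: float) -> float:
    """Nationwide annual cost as a proportion of the MNH budget."""
    if budget <= 0:
        raise ValueError("budget must be positive")
    return national_cost / budget


def affordability_table(
    cost_summaries: Mapping[str, InterventionCostSummary],
    ctx: NationalContext = MALAWI_2010,
    trial_mothers_and_babies: float = 96_000,
) -> pd.DataFrame:
    """Per-intervention annual cost, national cost, per-person cost and budget share.

    ``cost_summaries`` must hold two-arm summaries (the one-arm combined
    intervention doubled), so that the trial population of 96,000
    mothers-and-babies per year and the national ratio apply uniformly.
    """
    ratio = population_ratio(ctx, trial_mothers_and_babies)
    budget = mnh_budget(ctx)
    rows = []
    for label, summary in cost_summaries.items():
        annual = annual_cost(summary)
        national = national_annual_cost(annual, ratio)
        rows.append(
            {
                "intervention": label,
                "trial_annual_cost": annual,
                "national_annual_cost": national,
                "cost_per_person": annual / trial_mothers_and_babies,
                "budget_share": budget_share(national, budget),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScaleUpResult:
    """Decision analysis of one scale-up scenario at national scale."""

    scenario: ScaleUpScenario
    #: per-option discounted national totals: label -> dict(cost, dalys, eib)
    options: dict[str, dict[str, float]]
    frontier: list[str]
    dominated: dict[str, str]
    frontier_icers: list[dict]
    best_probability: dict[str, float]

    @property
    def best_option(self) -> str:
        return max(self.best_probability, key=self.best_probability.get)

    def to_rows(self) -> list[dict]:
        rows = []
        for label, vals in self.options.items():
            rows.append(
                {
                    "horizon_years": self.scenario.horizon_years,
                    "cost_discount": self.scenario.cost_discount,
                    "effect_discount": self.scenario.effect_discount,
                    "threshold_k": self.scenario.threshold_k,
                    "intervention": label,
                    "discounted_total_cost": vals["cost"],
                    "discounted_total_dalys": vals["dalys"],
                    "eib": vals["eib"],
                    "best_probability": self.best_probability.get(label, 0.0),
                    "is_best": label == self.best_option,
                    "dominated": self.dominated.get(label, ""),
                }
            )
        return rows


def evaluate_scenario(
    cost_summaries: Mapping[str, InterventionCostSummary],
    outcome_draws: Mapping[str, OutcomeDraws],
    scenario: ScaleUpScenario = ScaleUpScenario(),
    trial_years: float = 2.25,
) -> ScaleUpResult:
    """Discount, scale nationally and run the decision analysis for one scenario."""
    inputs = []
    options: dict[str, dict[str, float]] = {}
    for label, summary in cost_summaries.items():
        start_up, annual, annual_draws = annualize_trial_quantities(
            summary, outcome_draws[label], trial_years
        )
        cost = scenario.population_ratio * (
            start_up + discounted_stream(annual, scenario.cost_discount, scenario.horizon_years)
        )
        effect_draws = scenario.population_ratio * discounted_stream(
            annual_draws, scenario.effect_discount, scenario.horizon_years
        )
        opt = cea.CEAInput(label, cost, effect_draws)
        inputs.append(opt)
        options[label] = {
            "cost": cost,
            "dalys": opt.mean_effect,
            "eib": cea.eib(opt, scenario.threshold_k),
        }
    frontier, dominated, icers = cea.incremental_frontier(inputs)
    best = cea.best_option_probabilities(inputs, scenario.threshold_k)
    return ScaleUpResult(scenario, options, frontier, dominated, icers, best)


def scenario_grid(
    cost_summaries: Mapping[str, InterventionCostSummary],
    outcome_draws: Mapping[str, OutcomeDraws],
    horizons: Sequence[int] = (5, 10, 20),
    cost_rates: Sequence[float] = (0.0, 0.03, 0.10),
    effect_rates: Sequence[float] = (0.0, 0.02, 0.03),
    threshold_k: float = 780.0,
    ratio: float | None = None,
    trial_years: float = 2.25,
) -> list[ScaleUpResult]:
    """Evaluate every horizon × cost-rate × effect-rate scenario independently."""
    if ratio is None:
        ratio = population_ratio()
    results = []
    for horizon in horizons:
        for cost_rate in cost_rates:
            for effect_rate in effect_rates:
                scenario = ScaleUpScenario(
                    horizon_years=horizon,
                    cost_discount=cost_rate,
                    effect_discount=effect_rate,
                    population_ratio=ratio,
                    threshold_k=threshold_k,
                )
                results.append(
                    evaluate_scenario(cost_summaries, outcome_draws, scenario, trial_years)
                )
    return results


def scenario_table(results: Sequence[ScaleUpResult]) -> pd.DataFrame:
    """Flatten scenario results into one row per scenario per option."""
    return pd.DataFrame([row for res in results for row in res.to_rows()])
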