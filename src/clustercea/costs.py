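"""Provider-perspective intervention costing.

Turns a raw cost ledger (accounting lines classified as start-up,
implementation, maintenance, external or joint) into the per-intervention
cost structure used throughout the package: a one-off start-up total plus
three annual components, all in constant 2013 international dollars.

The conventions follow standard practice for economic costing of
community-level health interventions:

* capital items are annualised by straight-line depreciation over their
  expected lifespan (no interest);
* local-currency amounts are inflated to 2013 prices with a consumer price
  index and converted to international dollars with a purchasing-power-parity
  factor (105.8 Malawi Kwacha per 2013 INT$ by default);
* programme (joint) costs that cannot be attributed to a single intervention
  are split by an allocation rule, with the unallocated remainder excluded
  from intervention costs;
* the combined community-plus-facility intervention is costed as the sum of
  the two single interventions (no economies of scope).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "COST_CATEGORIES",
    "CostLedgerEntry",
    "CurrencyTable",
    "JointAllocationRule",
    "InterventionCostSummary",
    "TrialCostTotal",
    "annualize_capital",
    "convert_to_intl2013",
    "allocate_joint_costs",
    "annual_cost",
    "trial_total_cost",
    "combine_fici",
    "scale_summary",
    "build_cost_summary",
    "read_ledger_csv",
    "write_cost_table",
]

COST_CATEGORIES = ("start_up", "implementation", "maintenance", "external", "joint")


class CostConfigurationError(KeyError):
    """A currency conversion factor needed for a ledger entry is missing."""


@dataclass(frozen=True)
class CostLedgerEntry:
    """One accounting line of the intervention cost ledger.

    ``capital_lifespan_years`` absent (None) marks a recurrent cost; when
    present the amount is a capital purchase depreciated over that lifespan.
    """

    item_label: str
    category: str
    year: int
    currency: str
    amount: float
    capital_lifespan_years: float | None = None

    def __post_init__(self) -> None:
        if self.category not in COST_CATEGORIES:
            raise ValueError(f"unknown cost category {self.category!r}")
        if self.currency not in ("MWK", "GBP", "USD", "INTL2013"):
            raise ValueError(f"unknown currency {self.currency!r}")
        if self.amount < 0:
            raise ValueError("cost amounts must be non-negative")
        if self.capital_lifespan_years is not None and self.capital_lifespan_years <= 0:
            raise ValueError("capital lifespan must be positive")


@dataclass(frozen=True)
class CurrencyTable:
    """Factors taking nominal ledger amounts to 2013 international dollars.

    ``cpi_deflator_by_year`` maps a calendar year to the multiplier bringing
    local (MWK) prices of that year to 2013 prices. Foreign-currency entries
    are first converted to MWK at the configured year-specific rate and then
    follow the same CPI + PPP path.
    """

    cpi_deflator_by_year: Mapping[int, float] = field(default_factory=dict)
    ppp_mwk_per_intl: float = 105.8
    gbp_to_mwk_by_year: Mapping[int, float] = field(default_factory=dict)
    usd_to_mwk_by_year: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ppp_mwk_per_intl <= 0:
            raise ValueError("PPP factor must be positive")
        if any(v <= 0 for v in self.cpi_deflator_by_year.values()):
            raise ValueError("CPI deflators must be positive")

    def deflator(self, year: int) -> float:
        try:
            return self.cpi_deflator_by_year[year]
        except KeyError:
            raise CostConfigurationError(f"no CPI deflator configured for year {year}") from None

    def to_mwk_rate(self, currency: str, year: int) -> float:
        table = {"GBP": self.gbp_to_mwk_by_year, "USD": self.usd_to_mwk_by_year}[currency]
        try:
            return table[year]
        except KeyError:
            raise CostConfigurationError(
                f"no {currency}->MWK exchange rate configured for year {year}"
            ) from None


@dataclass(frozen=True)
class JointAllocationRule:
    """Shares of annual joint (programme) costs attributed to each intervention.

    The default is an equal split, reflecting allocation of shared office
    space, administrative staff and programme resources in proportion to
    implementing staff. Any remainder is attributed to non-intervention trial
    activities and excluded from intervention costs.
    """

    fraction_to_ci: float = 0.5
    fraction_to_fi: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_to_ci <= 1.0 and 0.0 <= self.fraction_to_fi <= 1.0):
            raise ValueError("allocation fractions must lie in [0, 1]")
        if self.fraction_to_ci + self.fraction_to_fi > 1.0 + 1e-12:
            raise ValueError("allocation fractions must not sum to more than 1")


@dataclass(frozen=True)
class InterventionCostSummary:
    """Start-up plus annual cost components of one intervention, in 2013 INT$."""

    intervention: str
    start_up_total: float
    annual_implementation: float
    annual_maintenance: float
    annual_external: float
    arms_covered: int = 2

    def __post_init__(self) -> None:
        for name in ("start_up_total", "annual_implementation", "annual_maintenance", "annual_external"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.arms_covered not in (1, 2):
            raise ValueError("arms_covered must be 1 or 2")


@dataclass(frozen=True)
class TrialCostTotal:
    intervention: str
    trial_period_years: float
    total_cost: float


def annualize_capital(purchase_cost: float, lifespan_years: float) -> float:
    """Straight-line annual depreciation of a capital purchase (no interest)."""
    if lifespan_years <= 0:
        raise ValueError("capital lifespan must be positive")
    return purchase_cost / lifespan_years


def convert_to_intl2013(amount: float, currency: str, year: int, table: CurrencyTable) -> float:
    """Convert a nominal ledger amount to constant 2013 international dollars."""
    if currency == "INTL2013":
        return amount
    if currency == "MWK":
        mwk = amount
    elif currency in ("GBP", "USD"):
        mwk = amount * table.to_mwk_rate(currency, year)
    else:
        raise ValueError(f"unknown currency {currency!r}")
    return mwk * table.deflator(year) / table.ppp_mwk_per_intl


def convert_from_intl2013(amount: float, year: int, table: CurrencyTable) -> float:
    """Inverse of the MWK conversion path (used for round-trip checks)."""
    return amount * table.ppp_mwk_per_intl / table.deflator(year)


def allocate_joint_costs(joint_total: float, rule: JointAllocationRule) -> tuple[float, float, float]:
    """Split an annual joint cost into (CI share, FI share, remainder)."""
    ci = joint_total * rule.fraction_to_ci
    fi = joint_total * rule.fraction_to_fi
    return ci, fi, joint_total - ci - fi


def annual_cost(summary: InterventionCostSummary) -> float:
    """Total annual cost: implementation + maintenance + external."""
    return summary.annual_implementation + summary.annual_maintenance + summary.annual_external


def trial_total_cost(summary: InterventionCostSummary, trial_years: float = 2.25) -> TrialCostTotal:
    """Start-up plus ``trial_years`` of annual costs over the trial period."""
    if trial_years <= 0:
        raise ValueError("trial period must be positive")
    total = summary.start_up_total + trial_years * annual_cost(summary)
    return TrialCostTotal(summary.intervention, trial_years, total)


def combine_fici(ci: InterventionCostSummary, fi: InterventionCostSummary) -> InterventionCostSummary:
    """Cost of delivering both interventions: component-wise sum, two arms.

    Assumes no economies of scope; halving (``scale_summary(..., 0.5)``)
    yields the one-arm combined-intervention cost.
    """
    if ci.arms_covered != fi.arms_covered:
        raise ValueError("can only combine summaries covering the same arm width")
    return InterventionCostSummary(
        intervention="FICI",
        start_up_total=ci.start_up_total + fi.start_up_total,
        annual_implementation=ci.annual_implementation + fi.annual_implementation,
        annual_maintenance=ci.annual_maintenance + fi.annual_maintenance,
        annual_external=ci.annual_external + fi.annual_external,
        arms_covered=2,
    )


def scale_summary(summary: InterventionCostSummary, factor: float, arms_covered: int | None = None) -> InterventionCostSummary:
    """Scale every cost component, e.g. halving a two-arm cost to one arm."""
    return replace(
        summary,
        start_up_total=summary.start_up_total * factor,
        annual_implementation=summary.annual_implementation * factor,
        annual_maintenance=summary.annual_maintenance * factor,
        annual_external=summary.annual_external * factor,
        arms_covered=summary.arms_covered if arms_covered is None else arms_covered,
    )


def build_cost_summary(
    entries: Iterable[CostLedgerEntry],
    intervention: str,
    table: CurrencyTable,
    rule: JointAllocationRule = JointAllocationRule(),
    trial_years: float = 2.25,
    arms_covered: int = 2,
) -> InterventionCostSummary:
    """Aggregate a ledger into an :class:`InterventionCostSummary`.

    Capital entries are annualised over their lifespan before being added to
    their category's annual total; recurrent start-up entries are one-off.
    Joint entries contribute the intervention's allocated share to the
    implementation component. All amounts are converted to 2013 INT$ first.
    Annual components are averaged over ``trial_years``, so a ledger holding
    one line per year reproduces the mean annual cost.
    """
    start_up = 0.0
    by_category = {"implementation": 0.0, "maintenance": 0.0, "external": 0.0}
    for e in entries:
        value = convert_to_intl2013(e.amount, e.currency, e.year, table)
        # capital bought for the programme is spread over its lifespan, except
        # one-off start-up purchases which are charged in full up front
        if e.capital_lifespan_years is not None and e.category != "start_up":
            value = annualize_capital(value, e.capital_lifespan_years) * trial_years
        if e.category == "start_up":
            start_up += value
        elif e.category == "joint":
            share = {"CI": rule.fraction_to_ci, "FI": rule.fraction_to_fi}.get(intervention, 0.0)
            by_category["implementation"] += value * share / trial_years
        else:
            by_category[e.category] += value / trial_years
    return InterventionCostSummary(
        intervention=intervention,
        start_up_total=start_up,
        annual_implementation=by_category["implementation"],
        annual_maintenance=by_category["maintenance"],
        annual_external=by_category["external"],
        arms_covered=arms_covered,
    )


def read_ledger_csv(path: str | Path) -> list[CostLedgerEntry]:
    """Read a cost ledger CSV with header ``item,category,year,currency,amount,lifespan``."""
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            lifespan = row.get("lifespan") or None
            entries.append(
                CostLedgerEntry(
                    item_label=row["item"],
                    category=row["category"],
                    year=int(row["year"]),
                    currency=row["currency"],
                    amount=float(row["amount"]),
                    capital_lifespan_years=float(lifespan) if lifespan else None,
                )
            )
    return entries


def write_cost_table(summaries: Sequence[InterventionCostSummary], path: str | Path, trial_years: float = 2.25) -> None:
    """Write a cost-summary CSV (one row per intervention, printed-style columns)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["intervention", "arms_covered", "start_up", "annual_implementation",
             "annual_maintenance", "annual_external", "annual_total", "trial_period_total"]
        )
        for s in summaries:
            w.writerow(
                [s.intervention, s.arms_covered, round(s.start_up_total), round(s.annual_implementation),
                 round(s.annual_maintenance), round(s.annual_external), round(annual_cost(s)),
                 round(trial_total_cost(s, trial_years).total_cost)]
            )
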