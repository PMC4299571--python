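"""Bayesian decision analysis on (fixed cost, uncertain effect) pairs.

Implements the four standard outputs of a probabilistic cost-effectiveness
analysis against a zero-cost, zero-effect "current practice" baseline or any
other comparator:

* **ICER** — incremental cost per DALY averted, ``(C1-C0)/(E1-E0)`` with the
  effect taken as the posterior mean over all draws, and dominance flagging;
* **EIB** — expected incremental benefit ``k(E1-E0) - (C1-C0)`` at a
  willingness-to-pay threshold ``k`` per DALY averted (linear in ``k``);
* **CEAC** — probability the reference option has the higher net benefit at
  each ``k`` (ties count against the reference);
* **EVPI** — expected value of perfect information,
  ``E[max_i NB_i] - max_i E[NB_i]`` over the option set including do-nothing.

Costs are fixed point estimates (degenerate distributions); uncertainty
enters through matched effect draws only. Options fitted in separate model
runs are paired draw-by-draw by index, which treats their posteriors as
independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CEAInput",
    "ThresholdGrid",
    "ICERResult",
    "UndefinedICERError",
    "CEAResult",
    "icer",
    "eib",
    "ceac",
    "evpi",
    "analyse",
    "incremental_frontier",
    "three_way_ranking",
    "ThreeWayResult",
]


class UndefinedICERError(ZeroDivisionError):
    """Zero incremental effect: the ICER is undefined.

    Carries ``incremental_cost`` so callers can still report the cost side.
    """

    def __init__(self, incremental_cost: float):
        super().__init__(f"zero incremental effect (incremental cost {incremental_cost:g})")
        self.incremental_cost = incremental_cost


@dataclass(frozen=True)
class CEAInput:
    """One decision option: a fixed total cost and matched effect draws."""

    label: str
    total_cost: float
    effect_draws: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_draws", np.asarray(self.effect_draws, dtype=float))
        if self.effect_draws.size == 0:
            raise ValueError("effect draws must be non-empty")
        if not np.isfinite(self.total_cost) or self.total_cost < 0:
            raise ValueError("total cost must be finite and non-negative")

    @property
    def mean_effect(self) -> float:
        return float(self.effect_draws.mean())

    def net_benefit(self, k: float) -> np.ndarray:
        return k * self.effect_draws - self.total_cost

    @classmethod
    def do_nothing(cls, n_draws: int, label: str = "current practice") -> "CEAInput":
        return cls(label, 0.0, np.zeros(n_draws))


@dataclass(frozen=True)
class ThresholdGrid:
    """Ascending willingness-to-pay grid, $ per DALY averted."""

    k_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_values", np.asarray(self.k_values, dtype=float))
        k = self.k_values
        if k.size == 0 or np.any(k < 0) or np.any(np.diff(k) <= 0):
            raise ValueError("thresholds must be non-negative and strictly ascending")

    @classmethod
    def default(cls, k_max: float = 2500.0, step: float = 10.0, k_ref: float = 780.0) -> "ThresholdGrid":
        k = np.arange(0.0, k_max + step / 2, step)
        if k_ref not in k:
            k = np.sort(np.append(k, k_ref))
        return cls(k)


@dataclass(frozen=True)
class ICERResult:
    value: float
    incremental_cost: float
    incremental_effect: float
    #: 'none', 'reference_dominates' (cheaper & more effective) or 'reference_dominated'
    dominance: str


def icer(reference: CEAInput, comparator: CEAInput) -> ICERResult:
    """Mean-based incremental cost-effectiveness ratio with dominance flags."""
    dc = reference.total_cost - comparator.total_cost
    de = reference.mean_effect - comparator.mean_effect
    if de == 0.0:
        raise UndefinedICERError(dc)
    if dc <= 0.0 and de > 0.0:
        status = "reference_dominates"
    elif dc >= 0.0 and de < 0.0:
        status = "reference_dominated"
    else:
        status = "none"
    return ICERResult(dc / de, dc, de, status)


def eib(option: CEAInput, k, comparator: CEAInput | None = None):
    """Expected incremental benefit at threshold(s) ``k`` (vectorised in k)."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("willingness-to-pay must be non-negative")
    base_e = comparator.mean_effect if comparator is not None else 0.0
    base_c = comparator.total_cost if comparator is not None else 0.0
    out = k * (option.mean_effect - base_e) - (option.total_cost - base_c)
    return float(out) if out.ndim == 0 else out


def _check_matched(a: CEAInput, b: CEAInput) -> None:
    if len(a.effect_draws) != len(b.effect_draws):
        raise ValueError("matched-draw comparison requires equal draw counts")


def ceac(reference: CEAInput, comparator: CEAInput, grid: ThresholdGrid) -> np.ndarray:
    """P(reference more cost-effective than comparator) at each threshold.

    Strict inequality of net benefit is required; ties count as not more
    cost-effective.
    """
    _check_matched(reference, comparator)
    nb_diff = (
        grid.k_values[:, None] * (reference.effect_draws - comparator.effect_draws)[None, :]
        - (reference.total_cost - comparator.total_cost)
    )
    return (nb_diff > 0).mean(axis=1)


def _nb_matrix(inputs: Sequence[CEAInput], k: float, include_do_nothing: bool) -> np.ndarray:
    n = len(inputs[0].effect_draws)
    for opt in inputs[1:]:
        _check_matched(inputs[0], opt)
    rows = [opt.net_benefit(k) for opt in inputs]
    if include_do_nothing:
        rows.append(np.zeros(n))
    return np.vstack(rows)


def evpi(inputs: Sequence[CEAInput], k: float, include_do_nothing: bool = True) -> float:
    """Expected value of perfect information at threshold ``k``.

    ``E[max_i NB_i] - max_i E[NB_i]`` over the supplied options plus (by
    default) the zero-net-benefit do-nothing option; non-negative by Jensen's
    inequality.
    """
    nb = _nb_matrix(list(inputs), k, include_do_nothing)
    return float(nb.max(axis=0).mean() - nb.mean(axis=1).max())


def best_option_probabilities(
    inputs: Sequence[CEAInput], k: float, include_do_nothing: bool = True
) -> dict[str, float]:
    """Per-option probability of having the strictly highest net benefit."""
    inputs = list(inputs)
    nb = _nb_matrix(inputs, k, include_do_nothing)
    labels = [opt.label for opt in inputs] + (["current practice"] if include_do_nothing else [])
    top = nb.max(axis=0)
    strict_best = (nb == top) & ((nb == top).sum(axis=0) == 1)
    return {label: float(strict_best[i].mean()) for i, label in enumerate(labels)}


@dataclass
class CEAResult:
    """Per-threshold decision summary of one reference-vs-comparator pair."""

    reference: str
    comparator: str
    icer: ICERResult | None
    table: pd.DataFrame  # columns: k, eib, ceac, evpi
    ce_plane: pd.DataFrame  # columns: draw, incremental_effect, incremental_cost

    def at(self, k: float) -> pd.Series:
        row = self.table[np.isclose(self.table["k"], k)]
        if row.empty:
            raise KeyError(f"threshold {k} not on the analysis grid")
        return row.iloc[0]

    def plot_ceac(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.plot(self.table["k"], self.table["ceac"])
        ax.set(xlabel="willingness to pay ($ per DALY averted)",
               ylabel=f"P({self.reference} cost-effective)", ylim=(0, 1))
        return ax

    def plot_ce_plane(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.scatter(self.ce_plane["incremental_effect"], self.ce_plane["incremental_cost"], s=2, alpha=0.3)
        ax.set(xlabel="incremental DALYs averted", ylabel="incremental cost ($)")
        return ax


def analyse(
    reference: CEAInput,
    comparator: CEAInput | None = None,
    grid: ThresholdGrid | None = None,
) -> CEAResult:
    """Full probabilistic CEA of one option against a comparator.

    ``comparator=None`` means zero-cost, zero-effect current practice.
    """
    if comparator is None:
        comparator = CEAInput.do_nothing(len(reference.effect_draws))
    grid = grid or ThresholdGrid.default()
    try:
        icer_result: ICERResult | None = icer(reference, comparator)
    except UndefinedICERError:
        icer_result = None
    table = pd.DataFrame(
        {
            "k": grid.k_values,
            "eib": eib(reference, grid.k_values, comparator),
            "ceac": ceac(reference, comparator, grid),
            "evpi": [evpi([reference, comparator], k, include_do_nothing=False) for k in grid.k_values],
        }
    )
    de = reference.effect_draws - comparator.effect_draws
    plane = pd.DataFrame(
        {"draw": np.arange(len(de)), "incremental_effect": de,
         "incremental_cost": np.full(len(de), reference.total_cost - comparator.total_cost)}
    )
    return CEAResult(reference.label, comparator.label, icer_result, table, plane)


def incremental_frontier(options: Sequence[CEAInput]) -> tuple[list[str], dict[str, str], list[dict]]:
    """Standard incremental analysis over a set of options.

    Options are sorted by cost; strictly dominated options (another option is
    at least as cheap and more effective, or cheaper and at least as
    effective) are removed, then extended dominance prunes options whose
    frontier ICER exceeds the next one up. Returns (frontier labels in cost
    order, dominated label -> reason, frontier ICER records).
    """
    opts = sorted(options, key=lambda o: (o.total_cost, -o.mean_effect))
    dominated: dict[str, str] = {}
    frontier = []
    for opt in opts:
        if any(f.mean_effect >= opt.mean_effect for f in frontier):
            dominated[opt.label] = "dominated"
        else:
            frontier.append(opt)
    # extended dominance: frontier ICERs must be increasing
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            low = icer(frontier[i], frontier[i - 1]).value
            high = icer(frontier[i + 1], frontier[i]).value
            if high < low:
                dominated[frontier[i].label] = "extended_dominance"
                del frontier[i]
                changed = True
                break
    icers = [
        {"from": frontier[i - 1].label, "to": frontier[i].label,
         "icer": icer(frontier[i], frontier[i - 1]).value}
        for i in range(1, len(frontier))
    ]
    return [f.label for f in frontier], dominated, icers


@dataclass
class ThreeWayResult:
    frontier: list[str]
    dominated: dict[str, str]
    frontier_icers: list[dict]
    best_probability: dict[str, float]
    threshold_k: float

    @property
    def best_option(self) -> str:
        return max(self.best_probability, key=self.best_probability.get)


def three_way_ranking(ci: CEAInput, fi: CEAInput, fici: CEAInput, k: float = 780.0) -> ThreeWayResult:
    """Joint CI / FI / FICI comparison with dominance pruning.

    ``fici`` must already be scaled to the same (two-arm) population as the
    CI and FI inputs; the scaling is an explicit caller-side step, never
    implicit. Best-option probabilities include the do-nothing baseline.
    """
    options = [ci, fi, fici]
    frontier, dominated, icers = incremental_frontier(options)
    return ThreeWayResult(frontier, dominated, icers, best_option_probabilities(options, k), k)
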