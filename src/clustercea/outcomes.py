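"""Convert odds-ratio posteriors to deaths averted and DALYs averted.

Each posterior draw of an intervention odds ratio is applied to the control
population's death probability: with control probability ``p0`` (odds
``p0/(1-p0)``), the intervention probability is the inverse-logit of the
shifted odds, and deaths averted are ``n * (p0 - p1)`` over a population of
``n`` births. Deaths averted may be negative (deaths added) when OR > 1.

DALY weights are years of life lost per averted death: 86.0 per baby
(standard life expectancy at birth, Global Burden of Disease 2010) and 53.27
per mother (remaining standard life expectancy at age 30, the median age of
maternal death in Malawi); the localised sensitivity variant uses Malawi's
healthy life expectancies of 45.0 and 28.1 years. Stillbirths are treated as
viable, carrying the same weight as a neonatal death. No age weighting or
discounting is applied at this stage. Mothers are counted one per birth, so
both equations share the births denominator.

Control-arm death probabilities are inputs, not published constants; when
only published deaths-averted summaries are available,
:func:`calibrate_baseline_prob` reconstructs a compatible ``p0`` by
bisection (documented as a reconstruction, not trial data).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .effects import PosteriorDraws

__all__ = [
    "BaselineRates",
    "DALYWeights",
    "STANDARD_WEIGHTS",
    "LOCALISED_WEIGHTS",
    "OutcomeDraws",
    "deaths_averted",
    "to_dalys",
    "convert_draws",
    "calibrate_baseline_prob",
]


@dataclass(frozen=True)
class BaselineRates:
    """Control-arm death probabilities and the comparison population."""

    baby_death_prob_control: float
    mother_death_prob_control: float
    births_per_arm: int = 54_000
    arms_in_comparison: int = 2

    def __post_init__(self) -> None:
        for p in (self.baby_death_prob_control, self.mother_death_prob_control):
            if not 0.0 < p < 1.0:
                raise ValueError("baseline probabilities must lie in (0, 1)")
        if self.births_per_arm <= 0 or self.arms_in_comparison not in (1, 2):
            raise ValueError("invalid population specification")

    @property
    def population(self) -> int:
        """Births covered by the comparison (54,000 per arm, 1 or 2 arms)."""
        return self.births_per_arm * self.arms_in_comparison


@dataclass(frozen=True)
class DALYWeights:
    per_baby_death: float
    per_mother_death: float
    variant: str = "standard"

    def __post_init__(self) -> None:
        if self.per_baby_death <= 0 or self.per_mother_death <= 0:
            raise ValueError("DALY weights must be positive")


STANDARD_WEIGHTS = DALYWeights(86.0, 53.27, "standard")
LOCALISED_WEIGHTS = DALYWeights(45.0, 28.1, "localised")


def deaths_averted(or_draw, p0: float, n: float):
    """Signed deaths averted by shifting the control odds by a draw's OR.

    Vectorised over ``or_draw``; strictly decreasing in the OR, zero at OR=1,
    negative for OR > 1.
    """
    or_draw = np.asarray(or_draw, dtype=float)
    if np.any(or_draw <= 0):
        raise ValueError("odds ratios must be positive")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    odds0 = p0 / (1.0 - p0)
    p1 = or_draw * odds0 / (1.0 + or_draw * odds0)
    return n * (p0 - p1)


def to_dalys(babies_saved, mothers_saved, weights: DALYWeights = STANDARD_WEIGHTS):
    """Linear DALY combination: no age weighting, no discounting."""
    return (
        np.asarray(babies_saved, dtype=float) * weights.per_baby_death
        + np.asarray(mothers_saved, dtype=float) * weights.per_mother_death
    )


@dataclass
class OutcomeDraws:
    """Per-draw deaths and DALYs averted for one intervention."""

    intervention: str
    babies_saved: np.ndarray
    mothers_saved: np.ndarray
    dalys_averted: np.ndarray

    def __len__(self) -> int:
        return len(self.dalys_averted)

    def scaled(self, factor: float) -> "OutcomeDraws":
        """Outcomes over a population scaled by ``factor`` (e.g. one-arm FICI doubled)."""
        return OutcomeDraws(
            self.intervention,
            self.babies_saved * factor,
            self.mothers_saved * factor,
            self.dalys_averted * factor,
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in (
            ("babies_saved", self.babies_saved),
            ("mothers_saved", self.mothers_saved),
            ("dalys_averted", self.dalys_averted),
        ):
            lo, hi = np.percentile(arr, [2.5, 97.5])
            rows.append({"intervention": self.intervention, "quantity": name,
                         "mean": float(arr.mean()), "lo": float(lo), "hi": float(hi)})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"draw": np.arange(len(self)), "intervention": self.intervention,
             "babies_saved": self.babies_saved, "mothers_saved": self.mothers_saved,
             "dalys_averted": self.dalys_averted}
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def convert_draws(
    draws: PosteriorDraws,
    base: BaselineRates,
    weights: DALYWeights = STANDARD_WEIGHTS,
) -> OutcomeDraws:
    """OR draws -> deaths averted -> DALYs averted, draw by draw."""
    n = base.population
    babies = deaths_averted(np.exp(draws.baby_log_or), base.baby_death_prob_control, n)
    mothers = deaths_averted(np.exp(draws.mother_log_or), base.mother_death_prob_control, n)
    return OutcomeDraws(draws.intervention, babies, mothers, to_dalys(babies, mothers, weights))


def calibrate_baseline_prob(
    or_draws: np.ndarray, target_mean_saved: float, n: float,
    bracket: tuple[float, float] = (1e-6, 0.5),
) -> float:
    """Baseline probability making mean deaths averted match a published value.

    Root-finds ``mean(deaths_averted(OR draws, p0, n)) = target`` by Brent
    bisection. Used to rebuild the unpublished control-arm rates from
    published posterior summaries; fails if the target is unreachable within
    the bracket (e.g. wrong sign relative to the draws).
    """
    or_draws = np.asarray(or_draws, dtype=float)

    def gap(p0: float) -> float:
        return float(np.mean(deaths_averted(or_draws, p0, n))) - target_mean_saved

    lo, hi = bracket
    if gap(lo) * gap(hi) > 0:
        raise ValueError("target mean deaths averted is not reachable for any p0 in the bracket")
    return float(brentq(gap, lo, hi, xtol=1e-12))
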