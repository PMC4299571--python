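"""Packaged headline summaries of the source trial's economic evaluation.

The underlying evaluation is of a 2×2 factorial cluster-randomised trial in
three central-region districts of Malawi (2008–2010) of community
mobilisation through women's groups (CI), health-facility quality
improvement (FI) and both combined (FICI), against current practice. The
published headline tables report, per intervention: the cost structure
(start-up plus annual implementation / maintenance / external components, in
constant 2013 international dollars), posterior summaries of baby- and
mother-mortality odds ratios, and posterior summaries of deaths and DALYs
averted over the 2.25-year trial period.

These values are inputs: they let the decision-analysis layers (CEA,
value of information, scale-up and affordability) run without access to the
trial's cluster-level data. The ``FICI_2ARM`` rows are the published one-arm
FICI quantities doubled to the same two-arm population as CI and FI, which is
how the three-way comparison is put on a common footing.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .costs import InterventionCostSummary

__all__ = [
    "TRIAL_YEARS",
    "WTP_REFERENCE",
    "BIRTHS_PER_ARM",
    "TRIAL_MOTHERS_AND_BABIES_PER_YEAR",
    "load_cost_summaries",
    "load_effect_summaries",
    "effect_summary_frame",
    "daly_normal_approximation",
]

#: Length of the trial intervention period in years (27 months).
TRIAL_YEARS = 2.25

#: Reference willingness-to-pay threshold, $ per DALY averted (Malawi's
#: 2013 per-capita GDP in international dollars).
WTP_REFERENCE = 780.0

#: Births (= mothers, one per birth) per trial arm over the trial period.
BIRTHS_PER_ARM = 54_000

#: Mothers + babies in two trial arms per year: 1,200,000 people x CBR 0.04 x 2.
TRIAL_MOTHERS_AND_BABIES_PER_YEAR = 96_000


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("clustercea.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_cost_summaries() -> dict[str, InterventionCostSummary]:
    """Published cost structures keyed by intervention label.

    Keys: ``CI``, ``FI`` (two-arm), ``FICI`` (one-arm), ``FICI_2ARM``
    (doubled to two-arm parity).
    """
    df = _read_csv("cost_summaries.csv")
    return {
        row.intervention: InterventionCostSummary(
            intervention=row.intervention,
            start_up_total=float(row.start_up),
            annual_implementation=float(row.annual_implementation),
            annual_maintenance=float(row.annual_maintenance),
            annual_external=float(row.annual_external),
            arms_covered=int(row.arms_covered),
        )
        for row in df.itertuples()
    }


def printed_trial_totals() -> dict[str, float]:
    """Published trial-period total costs (start-up + 2.25 yr of annual costs)."""
    df = _read_csv("cost_summaries.csv")
    return dict(zip(df.intervention, df.printed_trial_total.astype(float)))


def effect_summary_frame() -> pd.DataFrame:
    """Published posterior summaries (mean, 2.5th, 97.5th centile), long format."""
    return _read_csv("effect_summaries.csv")


def load_effect_summaries() -> dict[str, dict[str, tuple[float, float, float]]]:
    """Nested dict: intervention -> quantity -> (mean, lo, hi)."""
    out: dict[str, dict[str, tuple[float, float, float]]] = {}
    for row in effect_summary_frame().itertuples():
        out.setdefault(row.intervention, {})[row.quantity] = (
            float(row.mean), float(row.lo), float(row.hi))
    return out


def daly_normal_approximation(intervention: str) -> tuple[float, float]:
    """(mean, sd) of a normal approximation to a DALYs-averted posterior.

    The sd is the published 95% credible-interval width divided by 3.92, the
    normal 2.5th-97.5th centile span in standard-deviation units.
    """
    mean, lo, hi = load_effect_summaries()[intervention]["dalys_averted"]
    return mean, (hi - lo) / 3.92
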