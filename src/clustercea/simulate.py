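"""Synthetic 2×2 factorial cluster-randomised trial data with known truth.

Emulates the design of a community/facility maternal-newborn-health trial:
health-facility catchment areas (clusters) in three districts, stratified
urban/rural, randomised to control, community intervention (CI), facility
intervention (FI) or both (FICI). Cluster-level counts of births, combined
stillbirths+neonatal deaths ("baby deaths") and maternal deaths are drawn
binomially from a logistic model with known intervention odds ratios, so the
effect model's recovery of the truth can be tested exactly.

Per-cluster death probabilities are
``logistic(logit(baseline) + log OR(arm) + district + stratum + cluster noise)``
with independent normal cluster perturbations on the log-odds scale
(overdispersion). Defaults mirror the trial's published scale: four arms of
15 clusters, 54,000 births per arm over 2.25 years, baseline baby-mortality
odds consistent with rural Malawi (~56 baby deaths and ~6.7 maternal deaths
per 1,000 births) and intervention odds ratios near the published posterior
means. The real trial's exact cluster count and per-cluster birth spread are
in its data deposit, not its text; these defaults are documented stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ARMS", "TrialDesignConfig", "generate_trial", "arm_totals", "write_trial_csv"]

ARMS = ("control", "CI", "FI", "FICI")

#: arm -> (has CI, has FI) factorial indicators
ARM_FACTORS = {"control": (0, 0), "CI": (1, 0), "FI": (0, 1), "FICI": (1, 1)}


@dataclass(frozen=True)
class TrialDesignConfig:
    """Design and true-effect parameters of a synthetic factorial trial."""

    n_clusters_per_arm: int = 15
    districts: tuple[str, ...] = ("Lilongwe", "Kasungu", "Salima")
    stratum_prob_urban: float = 0.2
    births_per_arm_total: int = 54_000
    trial_years: float = 2.25
    baseline_baby_odds: float = 0.056 / (1 - 0.056)
    baseline_mother_odds: float = 0.0067 / (1 - 0.0067)
    #: intervention -> (baby OR, mother OR); FICI is its own arm-level effect
    true_or: dict = field(
        default_factory=lambda: {
            "CI": (0.873, 0.957),
            "FI": (0.954, 1.228),
            "FICI": (0.841, 1.287),
        }
    )
    district_log_odds: tuple[float, ...] = (0.0, 0.05, -0.05)
    stratum_log_odds_urban: float = -0.05
    cluster_heterogeneity_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_baby_odds <= 0 or self.baseline_mother_odds <= 0:
            raise ValueError("baseline odds must be positive")
        if any(v <= 0 for pair in self.true_or.values() for v in pair):
            raise ValueError("odds ratios must be positive")
        if self.cluster_heterogeneity_sd < 0:
            raise ValueError("cluster heterogeneity sd must be non-negative")
        if self.births_per_arm_total < self.n_clusters_per_arm:
            raise ValueError("need at least one birth per cluster")
        if len(self.district_log_odds) != len(self.districts):
            raise ValueError("one district effect per district required")


def _arm_log_or(config: TrialDesignConfig, arm: str, which: int) -> float:
    """Arm-level true log-OR for outcome ``which`` (0 = baby, 1 = mother).

    The FICI arm carries its own configured combined effect rather than the
    sum of the CI and FI effects, matching a factorial trial whose combined
    arm is analysed as a separate comparison.
    """
    if arm == "control":
        return 0.0
    return float(np.log(config.true_or[arm][which]))


def generate_trial(config: TrialDesignConfig) -> pd.DataFrame:
    """Draw one synthetic trial as a cluster-level DataFrame.

    Columns: ``cluster_id, district, stratum, arm, births, baby_deaths,
    mother_deaths``. Births are split near-equally across an arm's clusters
    with multinomial jitter; identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for arm in ARMS:
        m = config.n_clusters_per_arm
        births = rng.multinomial(config.births_per_arm_total, np.full(m, 1.0 / m))
        districts = rng.integers(0, len(config.districts), size=m)
        urban = rng.random(m) < config.stratum_prob_urban
        noise = rng.normal(0.0, config.cluster_heterogeneity_sd, size=(m, 2))
        for j in range(m):
            eta_common = (
                config.district_log_odds[districts[j]]
                + (config.stratum_log_odds_urban if urban[j] else 0.0)
            )
            counts = []
            for which, base_odds in enumerate(
                (config.baseline_baby_odds, config.baseline_mother_odds)
            ):
                eta = (
                    np.log(base_odds)
                    + _arm_log_or(config, arm, which)
                    + eta_common
                    + noise[j, which]
                )
                p = 1.0 / (1.0 + np.exp(-eta))
                counts.append(rng.binomial(births[j], p))
            rows.append(
                {
                    "cluster_id": f"{arm}-{j + 1:02d}",
                    "district": config.districts[districts[j]],
                    "stratum": "urban" if urban[j] else "rural",
                    "arm": arm,
                    "births": int(births[j]),
                    "baby_deaths": int(counts[0]),
                    "mother_deaths": int(counts[1]),
                }
            )
    return pd.DataFrame(rows)


def arm_totals(records: pd.DataFrame) -> pd.DataFrame:
    """Exact per-arm sums of births and deaths (counts are conserved)."""
    if len(records) == 0:
        raise ValueError("no cluster records supplied")
    return (
        records.groupby("arm", sort=False)[["births", "baby_deaths", "mother_deaths"]]
        .sum()
        .reset_index()
    )


def write_trial_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)
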