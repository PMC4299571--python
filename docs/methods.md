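# Methods

This note documents the models, conventions and numerical choices behind
`clustercea`, in the order the pipeline applies them.

## Costing model

Costs are analysed from the provider perspective as fixed point estimates
(no cost uncertainty enters the probabilistic analysis). A ledger line is
one of five categories: `start_up` (one-off), `implementation`,
`maintenance`, `external` (all annual), or `joint` (shared programme costs).
Conventions:

* **Capital** is depreciated straight-line over its expected lifespan, with
  no interest; one-off start-up purchases are charged in full up front.
* **Currency**: Malawi Kwacha amounts are inflated to 2013 prices by a CPI
  deflator and divided by the purchasing-power-parity factor of 105.8 MWK
  per 2013 international dollar. GBP/USD amounts are first converted to MWK
  at configured year-specific rates (configuration inputs — there is no
  canonical published series for them), then follow the same path. The
  conversion is exactly linear and invertible; the packaged summaries carry
  already-converted 2013 international dollars.
* **Joint costs** are split by an allocation rule with the remainder
  assigned to non-intervention activities; allocated shares plus remainder
  always reconstruct the total exactly. The default rule is an equal CI/FI
  split, reflecting office space and administrative staffing allocated in
  proportion to implementing staff.
* **Combined intervention**: no economies of scope are assumed — the
  two-arm combined cost is the component-wise sum of CI and FI, and the
  one-arm cost is half of it.
* Trial-period totals are `start_up + 2.25 × (implementation + maintenance
  + external)`. All arithmetic is done at full floating precision; rounding
  to whole dollars happens only at report time. Rebuilt totals agree with
  the packaged printed totals to ≤ 2 dollars (the printed components are
  themselves pre-rounded).

## Synthetic trial generator

`simulate.generate_trial` emulates the trial design: four arms (control,
CI, FI, FICI) of `n_clusters_per_arm` clusters (default 15, a stand-in near
the real trial's 61 clusters) spread over three districts with an
urban/rural stratum. Arm birth totals (default 54,000 over 2.25 years) are
split near-equally across clusters by a multinomial draw; cluster death
counts are binomial with probability
`logistic(logit(baseline) + log OR(arm) + district + stratum + ε)`, with
`ε ~ N(0, sd²)` a cluster-level log-odds perturbation (default sd 0.1)
providing overdispersion that the fixed-effects analysis model does not
itself contain — deliberately, so that the model can be stress-tested
against the kind of extra-binomial variation real clusters show.

Defaults are chosen to be realistic for rural Malawi: baseline baby
(stillbirth + neonatal) death probability 0.056, maternal death probability
0.0067 per birth, true odds ratios near the published posterior means
(0.873/0.954/0.841 baby; 0.957/1.228/1.287 mother), and small district and
stratum offsets (±0.05 log-odds) so covariate adjustment is exercised. The
FICI arm carries its own configured odds ratio rather than the CI×FI
product, matching a factorial trial whose combined arm is analysed as a
separate one-arm comparison. Maternal deaths use births as denominator (one
mother per birth).

What passing tests on these data do **not** show: robustness to
time-varying rates, migration, individual-level covariates or informative
cluster sizes — none of which the generator produces.

## Effect model

Two binomial-logit equations (baby, mother) share the cluster design matrix
(intercept, district dummies, urban stratum dummy, intervention
indicators). Two fits cover the factorial structure: CI and FI main effects
with **no interaction** estimated from all four arms, and a separate
one-arm FICI-vs-control fit. Priors are zero-mean normals with variance
10⁴ on the log-odds scale; corresponding coefficients of the two equations
form a bivariate normal with prior correlation 0 by default — the joint
structure is retained (and configurable) but, with correlation 0 and
independent likelihoods, the equations are a posteriori independent. The
fixed-effects form (no cluster random effect) is this package's reading of
the source analysis, whose main text lists exactly these covariates;
overdispersion can be probed with the generator's heterogeneity parameter.

### Sampler

A self-contained adaptive random-walk Metropolis-within-Gibbs sampler is
the default engine (the model contract, not the engine, is the interface).
Numerical choices:

* per-coordinate Gaussian proposals; scales adapt during burn-in only, by
  Robbins–Monro on the log scale (step `t^-0.6`) targeting 0.44 acceptance,
  clipped to `exp(±…)` bounds — the post-burn-in kernel is fixed, so the
  retained chain is a valid Markov chain;
* chains start at the binomial-GLM maximum-likelihood estimate (chain 1) and
  at MLE plus standard-error-scaled jitter (other chains); if the GLM fails
  (e.g. all-zero deaths) the start falls back to an empirical-logit
  intercept and zeros, and proposal scales to 0.5;
* the default schedule (2 × 510,000, burn-in 10,000, thin 10) saves exactly
  100,000 draws; tests use reduced schedules — a few thousand iterations —
  which the MLE initialisation makes adequate on these posteriors;
* diagnostics: rank-normalised split R-hat and ESS (via arviz) per
  coefficient per equation; any R-hat > 1.05 raises a warning (never a hard
  failure), with the table attached to the results object.

Sampler correctness is checked against a dense-grid integration of the
exact posterior on a two-cluster problem (total variation < 0.02 on the
intervention log-OR marginal), against known-truth recovery at a million
births per arm (within 3 posterior standard deviations), and against
credible-interval calibration over 50 null trials (coverage consistent with
95%).

### Emulated posteriors

When only published summaries are available, posterior draws are emulated
as lognormals quantile-matched to the 95% credible interval: location
`(log lo + log hi)/2`, scale `(log hi − log lo)/3.92`. The credible
interval is reproduced by construction; the mean OR can differ slightly
from the published mean because real posteriors are not exactly lognormal
(for the CI baby OR the emulated mean is 0.8734 vs 0.873 published; mother
equations, with wider intervals, deviate more). Degenerate summaries with
zero interval width yield constant draws.

## Outcome conversion

Per draw: `p₁ = OR·odds₀/(1 + OR·odds₀)`, deaths averted `n·(p₀ − p₁)`,
DALYs `86.0·babies + 53.27·mothers` (localised: `45.0/28.1`), with `n` =
54,000 births × arms in the comparison (2 for CI/FI, 1 for FICI). Doubling
one-arm FICI quantities to two-arm parity for the three-way comparison is
an explicit operation on costs and outcomes, never implicit. The
control-arm probabilities p₀ are not published; in published-summaries mode
they are reconstructed per comparison by Brent bisection so the mean deaths
averted match the published means (a documented reconstruction — the
calibrated baby p₀ ≈ 0.056 is itself a plausibility check, matching rural
Malawi's combined stillbirth + neonatal rate). In cluster-data mode p₀ is
the empirical control-arm rate.

## Decision analysis

* The ICER uses posterior **mean** effects; zero incremental effect raises
  a typed error carrying the incremental cost. Dominance (cheaper & more
  effective) is flagged.
* CEAC and best-option probabilities require **strictly** higher net
  benefit; ties count against the reference. Options fitted in separate
  model runs are paired draw-by-draw by index, i.e. treated as independent
  posteriors — the one approximation in the comparison of CI/FI (one fit)
  with FICI (another).
* EVPI is population-level: `E[max_i NB_i] − max_i E[NB_i]` over the option
  set including do-nothing (NB ≡ 0); verified against brute-force
  enumeration on small draw sets and non-negative by construction.
* The default threshold grid is $0–2,500 per DALY in steps of 10, always
  containing the $780 reference.
* The three-way comparison from published two-arm means yields an
  FICI-vs-CI frontier ICER of ≈ $715 per DALY; joint-model figures
  published elsewhere for that contrast are not reproducible from the
  summary means alone, so the package reports the summary-derived frontier
  and makes no claim about the joint-model value.

## Scale-up and affordability

Implementation costs and effect draws are annualised by dividing by the
2.25-year trial period (same effect per year assumed); maintenance and
external costs are already annual. Streams discount with **year 1
undiscounted** and years 2..H at `(1+r)^−(t−1)` — chosen to match a
"years two to ten" convention and stated explicitly because many texts
discount from year 1; start-up enters year 1 in full; effects use the same
year-indexing as costs (symmetry chosen where the convention was open),
with defaults of 3% (costs) and 2% (effects). National scaling multiplies
trial costs and effects by the mothers-and-babies ratio (2010 Malawi:
15,013,694 × 0.04 × 2 / 96,000 ≈ 12.511; identical to the births ratio
since mother and baby are counted separately in both numerator and
denominator). The MNH budget is per-capita health expenditure × population
× MNH share ($228.7 × 15,013,694 × 11.95% ≈ $410.3M; recomputation differs
from the published $410,354,347 by <0.01% because the published inputs are
rounded). The sensitivity grid crosses horizons {5, 10, 20} years × cost
rates {0, 3, 10}% × effect rates {0, 2, 3}% — 27 scenarios, each evaluated
independently at $780 per DALY; maintenance is discounted identically to
implementation in years 2+.

## Problem sizes used in tests

The reference MCMC schedule is a default, not a test requirement: unit and
calibration tests run reduced schedules (hundreds to a few thousand
iterations, justified by MLE initialisation), the grid-oracle check uses a
400,000-iteration single chain on a 2-parameter posterior, known-truth
recovery uses one trial of 10⁶ births per arm, the generator calibration
60 null trials, credible-interval calibration 50 null trials of 6 clusters
× 20,000 births per arm, and Monte-Carlo acceptability checks 2×10⁵ draws.

## Known limitations

* Fixed-effects analysis model: no cluster random effect, so with strong
  overdispersion credible intervals will undercover (probe with the
  generator's heterogeneity parameter).
* Costs are deterministic throughout; cost-effect correlation at cluster
  level is not modelled (resource use was not cluster-attributable in the
  motivating design).
* Independent pairing of posteriors fitted in separate runs ignores any
  between-model correlation a joint fit would capture.
* Lognormal emulation reproduces published credible intervals, not
  published means, where posteriors are skewed.
* The scale-up model assumes proportional costs and effects at national
  scale — no economies of scale, no coverage-density effects, no GDP-growth
  indexing of the threshold.
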