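"""Adaptive random-walk Metropolis-within-Gibbs for aggregated logistic models.

Self-contained sampler for binomial-logit regressions on cluster totals,
with two outcome equations (baby and mother mortality) sharing a design
matrix and a cross-equation bivariate-normal prior on corresponding
coefficients. Proposal scales adapt per coordinate during burn-in only
(Robbins–Monro on the log scale, targeting 0.44 acceptance), so the retained
chain is a valid fixed-kernel Markov chain.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_two_equation_logit"]

_TARGET_ACCEPT = 0.44


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _loglik(eta: np.ndarray, deaths: np.ndarray, births: np.ndarray) -> float:
    return float(deaths @ eta - births @ _softplus(eta))


def sample_two_equation_logit(
    X: np.ndarray,
    births: np.ndarray,
    deaths: np.ndarray,
    *,
    prior_var: float = 1e4,
    prior_corr: float = 0.0,
    n_chains: int = 2,
    iterations: int = 20_000,
    burn_in: int = 2_000,
    thin: int = 1,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
    start_scales: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample coefficients of the paired logistic equations.

    Parameters
    ----------
    X : (n, p) design matrix shared by both equations.
    births : (n,) binomial denominators.
    deaths : (n, 2) numerators, column 0 = baby deaths, 1 = mother deaths.
    prior_var, prior_corr : each coefficient pair (baby_j, mother_j) has a
        zero-mean bivariate normal prior with this per-component variance and
        correlation (0 = independent components).
    start : optional (p, 2) centre for chain initialisation.
    start_scales : optional (p,) scale used for start jitter and initial
        proposal standard deviations.

    Returns
    -------
    draws : (n_chains, n_saved, p, 2) retained post-burn-in, thinned draws.
    accept : (p, 2) overall post-burn-in acceptance rates, averaged over chains.
    """
    n, p = X.shape
    if deaths.shape != (n, 2):
        raise ValueError("deaths must have shape (n, 2)")
    if not (iterations > burn_in >= 0 and thin >= 1):
        raise ValueError("need iterations > burn_in >= 0 and thin >= 1")
    n_saved = (iterations - burn_in) // thin

    # bivariate normal prior precision for a coefficient pair
    rho = prior_corr
    prec = np.linalg.inv(prior_var * np.array([[1.0, rho], [rho, 1.0]]))

    if start is None:
        start = np.zeros((p, 2))
    if start_scales is None:
        start_scales = np.full(p, 0.5)

    all_draws = np.empty((n_chains, n_saved, p, 2))
    accept = np.zeros((p, 2))

    for c in range(n_chains):
        beta = start + (rng.standard_normal((p, 2)) * start_scales[:, None] if c > 0 else 0.0)
        eta = X @ beta  # (n, 2)
        ll = np.array([_loglik(eta[:, q], deaths[:, q], births) for q in (0, 1)])
        log_s = np.log(np.tile(start_scales[:, None], (1, 2)).astype(float))
        adapt_count = np.zeros((p, 2))
        acc_post = np.zeros((p, 2))
        saved = 0
        for t in range(iterations):
            adapting = t < burn_in
            for j in range(p):
                for q in (0, 1):
                    old = beta[j, q]
                    step = np.exp(log_s[j, q]) * rng.standard_normal()
                    new = old + step
                    eta_new = eta[:, q] + X[:, j] * step
                    ll_new = _loglik(eta_new, deaths[:, q], births)
                    pair_old = beta[j].copy()
                    pair_new = pair_old.copy()
                    pair_new[q] = new
                    dprior = -0.5 * (pair_new @ prec @ pair_new - pair_old @ prec @ pair_old)
                    log_alpha = (ll_new - ll[q]) + dprior
                    if np.log(rng.random()) < log_alpha:
                        beta[j, q] = new
                        eta[:, q] = eta_new
                        ll[q] = ll_new
                        accepted = 1.0
                    else:
                        accepted = 0.0
                    if adapting:
                        adapt_count[j, q] += 1.0
                        gamma = adapt_count[j, q] ** -0.6
                        alpha = min(1.0, np.exp(log_alpha)) if np.isfinite(log_alpha) else 1.0
                        log_s[j, q] = np.clip(
                            log_s[j, q] + gamma * (alpha - _TARGET_ACCEPT), -15.0, 6.0
                        )
                    else:
                        acc_post[j, q] += accepted
            if not adapting and (t - burn_in) % thin == 0 and saved < n_saved:
                all_draws[c, saved] = beta
                saved += 1
        accept += acc_post / max(iterations - burn_in, 1)
    return all_draws, accept / n_chains
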