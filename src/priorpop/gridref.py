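"""Brute-force grid reference for the Bayesian computations.

These routines evaluate the exact Poisson-population log-likelihood
``sum_i r_i log lambda_i(s)`` (terms independent of ``s`` dropped, summed rate
treated as constant, matching the closed forms they are meant to validate) on
a fine stimulus grid and integrate it numerically against the prior.  They
are deliberately independent of the closed-form ideal-observer path and serve
as oracles in tests and acceptance checks, and as overlay curves in analyses.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .encoder import EncoderSpec, TaskSpec

__all__ = ["default_grid", "log_population_likelihood", "grid_class_posterior", "grid_map_estimate"]


def default_grid(step: float = 0.01, span: float = 30.0) -> np.ndarray:
    return np.arange(-span, span + step / 2, step)


def log_population_likelihood(
    r: np.ndarray, spec: EncoderSpec, grid: np.ndarray
) -> np.ndarray:
    """log p(r|s) on the grid, up to an s-independent constant.

    lambda_i(s) = c exp(-(s - phi_i)^2 / 2 sigma^2) gives
    sum_i r_i log lambda_i(s) = const - sum_i r_i (s - phi_i)^2 / (2 sigma^2).
    """
    r = np.asarray(r, dtype=float)
    sq = (grid[:, None] - spec.centers[None, :]) ** 2
    return -(sq @ r) / (2.0 * spec.tuning_variance)


def grid_class_posterior(
    r: np.ndarray,
    task: TaskSpec,
    spec: EncoderSpec,
    grid: np.ndarray | None = None,
    prior_counts: tuple[float, float] | None = None,
) -> float:
    """P(C=1|r) by numerical marginalisation over the stimulus grid."""
    if grid is None:
        grid = default_grid()
    ll = log_population_likelihood(r, spec, grid)
    sd = np.sqrt(task.class_variance)
    log_marg = [
        logsumexp(ll + norm.logpdf(grid, mu, sd)) for mu in task.class_means
    ]
    if prior_counts is None:
        n1, n2 = task.class_prior, 1.0 - task.class_prior
    else:
        n1, n2 = prior_counts
    d = (log_marg[0] - log_marg[1]) + np.log(n1 / n2)
    return float(1.0 / (1.0 + np.exp(-d)))


def grid_map_estimate(
    r: np.ndarray,
    task: TaskSpec,
    spec: EncoderSpec,
    grid: np.ndarray | None = None,
) -> float:
    """argmax over the grid of likelihood x Gaussian stimulus prior."""
    if grid is None:
        grid = default_grid()
    ll = log_population_likelihood(r, spec, grid)
    log_post = ll + norm.logpdf(grid, task.prior_mean, np.sqrt(task.prior_variance))
    return float(grid[np.argmax(log_post)])
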