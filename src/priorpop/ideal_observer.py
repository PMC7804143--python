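"""Closed-form Bayesian ideal observers for the Poisson population code.

For Gaussian tuning curves tiling the stimulus range densely, the population
likelihood of a spike-count vector ``r`` is itself Gaussian in the stimulus,

    p(r | s) ∝ N(s; mu_r, sigma_r^2),
    mu_r = phi^T r / (1^T r),    sigma_r^2 = sigma^2 / (1^T r),

(the spike-weighted mean of the tuning-curve centres, with variance shrinking
as total spike count grows).  This holds up to terms independent of ``s``
provided the summed rate ``sum_i lambda_i(s)`` is approximately constant,
i.e. away from the edges of the tiled range; evaluation sweeps therefore stay
within [-10, 10].

Classification combines the decoded likelihood with Gaussian class densities
into a posterior log-odds

    d = [2 mu_r (mu_1 - mu_2) + mu_2^2 - mu_1^2] / [2 (sigma_r^2 + sigma_C^2)]
        + log(N_1 / N_2),

and estimation with a Gaussian stimulus prior into the MAP estimate

    s_MAP = (mu_r sigma_s^2 + mu_s sigma_r^2) / (sigma_r^2 + sigma_s^2).

A zero-spike trial carries no stimulus information; the posterior is the prior
and the MAP estimate is the prior mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .encoder import EncoderSpec, TaskSpec, sample_trials

__all__ = [
    "DecodedLikelihood",
    "decode_likelihood",
    "decode_likelihood_batch",
    "class_log_odds",
    "posterior_class1",
    "map_estimate",
    "ideal_accuracy",
]


@dataclass(frozen=True)
class DecodedLikelihood:
    """Gaussian summary (mu_r, sigma_r^2) of the population likelihood.

    ``informative`` is False for zero-spike trials, where mu_r/sigma_r2 are
    undefined (stored as NaN/inf) and downstream computations fall back to
    the prior.
    """

    mu_r: float | np.ndarray
    sigma_r2: float | np.ndarray
    total_count: int | np.ndarray
    informative: bool | np.ndarray


def decode_likelihood_batch(
    spikes: np.ndarray, spec: EncoderSpec
) -> DecodedLikelihood:
    """Vectorised decode of a (B, n_neurons) spike-count array."""
    spikes = np.asarray(spikes, dtype=float)
    total = spikes.sum(axis=-1)
    informative = total > 0
    safe_total = np.where(informative, total, 1.0)
    mu_r = np.where(informative, spikes @ spec.centers / safe_total, np.nan)
    sigma_r2 = np.where(informative, spec.tuning_variance / safe_total, np.inf)
    return DecodedLikelihood(
        mu_r=mu_r,
        sigma_r2=sigma_r2,
        total_count=total.astype(int),
        informative=informative,
    )


def decode_likelihood(r: np.ndarray, spec: EncoderSpec) -> DecodedLikelihood:
    """Decode a single spike vector into its Gaussian likelihood summary."""
    dec = decode_likelihood_batch(np.asarray(r)[None, :], spec)
    return DecodedLikelihood(
        mu_r=float(dec.mu_r[0]),
        sigma_r2=float(dec.sigma_r2[0]),
        total_count=int(dec.total_count[0]),
        informative=bool(dec.informative[0]),
    )


def class_log_odds(
    dec: DecodedLikelihood,
    task: TaskSpec,
    prior_counts: tuple[float, float] | None = None,
) -> float | np.ndarray:
    """Posterior log-odds d = log P(C=1|r) / P(C=2|r).

    ``prior_counts`` are the class training counts (N1, N2); by default the
    expected counts implied by the class prior pi are used, so the prior term
    is log(pi / (1 - pi)).  Uninformative (zero-spike) decodes return the
    prior term alone.
    """
    if task.mode != "classification":
        raise ValueError("class_log_odds requires a classification task")
    if prior_counts is None:
        n1, n2 = task.class_prior, 1.0 - task.class_prior
    else:
        n1, n2 = prior_counts
        if n1 <= 0 or n2 <= 0:
            raise ValueError("prior counts must be positive")
    mu1, mu2 = task.class_means
    prior_term = np.log(n1 / n2)
    mu_r = np.asarray(dec.mu_r, dtype=float)
    sigma_r2 = np.asarray(dec.sigma_r2, dtype=float)
    informative = np.asarray(dec.informative)
    safe_mu = np.where(informative, mu_r, 0.0)
    likelihood_term = (2.0 * safe_mu * (mu1 - mu2) + mu2**2 - mu1**2) / (
        2.0 * (sigma_r2 + task.class_variance)
    )
    d = np.where(informative, likelihood_term + prior_term, prior_term)
    return float(d) if d.ndim == 0 else d


def posterior_class1(d) -> float | np.ndarray:
    """P(C=1 | r) = logistic(d)."""
    p = expit(d)
    return float(p) if np.ndim(p) == 0 else p


def map_estimate(dec: DecodedLikelihood, task: TaskSpec) -> float | np.ndarray:
    """Precision-weighted MAP stimulus estimate under the Gaussian prior."""
    if task.mode != "estimation":
        raise ValueError("map_estimate requires an estimation task")
    mu_r = np.asarray(dec.mu_r, dtype=float)
    sigma_r2 = np.asarray(dec.sigma_r2, dtype=float)
    informative = np.asarray(dec.informative)
    safe_mu = np.where(informative, mu_r, task.prior_mean)
    safe_var = np.where(informative, sigma_r2, 1.0)
    s_map = (safe_mu * task.prior_variance + task.prior_mean * safe_var) / (
        safe_var + task.prior_variance
    )
    s_map = np.where(informative, s_map, task.prior_mean)
    return float(s_map) if s_map.ndim == 0 else s_map


def ideal_accuracy(
    task: TaskSpec,
    spec: EncoderSpec,
    contrast: float,
    n_trials: int,
    rng: np.random.Generator,
    cue_id: int | None = None,
) -> dict[int, float]:
    """Monte-Carlo per-class accuracy of the d > 0 ideal decision rule.

    For cued tasks pass ``cue_id`` to condition the prior (trials are then
    sampled from that cue's prior).
    """
    if task.mode != "classification":
        raise ValueError("ideal_accuracy requires a classification task")
    eff = task
    if cue_id is not None:
        eff = TaskSpec.classification(
            prior=task.cue_table[cue_id],
            class_means=task.class_means,
            class_variance=task.class_variance,
        )
    batch = sample_trials(eff, spec, n_trials, rng, contrast=contrast)
    dec = decode_likelihood_batch(batch.spikes, spec)
    d = class_log_odds(dec, eff)
    predicted = np.where(d > 0, 1, 2)
    out = {}
    for cls in (1, 2):
        mask = batch.class_label == cls
        out[cls] = float(np.mean(predicted[mask] == cls)) if mask.any() else np.nan
    return out
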