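"""Representation analyses of trained networks.

Covers the population-level statistics used to characterise how a trained
network encodes prior knowledge:

* sparsity / activity statistics (active-unit counts, mean activity) by
  contrast, class, prior and ideal-posterior bin;
* pre-activation ("template match") histograms by contrast;
* subpopulation comparisons of biases, input weights and readout weights
  between units preferring class 1 vs class 2;
* cue gain/bias attribution and channel ablations;
* hidden-unit tuning-curve geometry (peak, maximal-slope location, FWHM);
* expected- vs unexpected-unit bias contrasts and the perceptual bias curve.

Directional group comparisons use Welch's unequal-variance t test across
units (two-sided); the expected/unexpected bias contrast additionally reports
a label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .encoder import EncoderSpec, TaskSpec, sample_trials, tuning_rate
from .ideal_observer import (
    class_log_odds,
    decode_likelihood_batch,
    map_estimate,
    posterior_class1,
)
from .network import (
    NetworkParams,
    forward_hidden,
    forward_preactivation,
    readout_classify,
    readout_estimate,
)

__all__ = [
    "TuningCurveSummary",
    "SubpopulationSplit",
    "activity_stats",
    "preactivation_histogram",
    "subpopulation_split",
    "subpopulation_param_means",
    "cue_attribution",
    "ablate_cue",
    "classification_accuracy",
    "cue_accuracy_asymmetry",
    "estimate_tuning_curves",
    "tuning_histograms",
    "peak_bimodality_test",
    "expected_unexpected_bias",
    "perceptual_bias",
]

ACTIVITY_FLOOR = 1e-3  # peak mean response below this marks a unit inactive
WELCH_ALPHA = 0.01


# ---------------------------------------------------------------------------
# activity statistics
# ---------------------------------------------------------------------------

def _sample_eval_trials(task, spec, n, rng, contrast, stimulus_range):
    """Held-out trials; estimation-mode stimuli truncated to the test range."""
    if task.mode == "estimation" and stimulus_range is not None:
        lo, hi = stimulus_range
        sd = np.sqrt(task.prior_variance)
        a, b = (lo - task.prior_mean) / sd, (hi - task.prior_mean) / sd
        s = stats.truncnorm.rvs(
            a, b, loc=task.prior_mean, scale=sd, size=n, random_state=rng
        )
        contrasts = np.broadcast_to(np.asarray(contrast, float), (n,))
        spikes = rng.poisson(tuning_rate(s, contrasts, spec))
        from .encoder import TrialBatch

        return TrialBatch(stimulus=s, contrast=np.asarray(contrasts), spikes=spikes)
    return sample_trials(task, spec, n, rng, contrast=contrast)


def activity_stats(
    params: NetworkParams,
    task: TaskSpec,
    spec: EncoderSpec,
    contrasts,
    n_trials: int,
    rng: np.random.Generator,
    cue_id: int | None = None,
    by_posterior_bin: bool = False,
    stimulus_range: tuple[float, float] | None = (-10.0, 10.0),
) -> pd.DataFrame:
    """Active-unit counts and mean activity per evaluation cell.

    Returns one row per (contrast, class [, posterior bin]) with the mean
    number of hidden units with h > 0 and the mean population activity over
    ``n_trials`` freshly sampled trials.  Posterior bins (10 equal-width bins
    on [0, 1]) use the ideal posterior of each trial.
    """
    rows = []
    for c in np.atleast_1d(np.asarray(contrasts, dtype=float)):
        batch = _sample_eval_trials(task, spec, n_trials, rng, c, stimulus_range)
        h = forward_hidden(batch.spikes, params, cue_id=cue_id)
        active = (h > 0).sum(axis=1)
        activity = h.mean(axis=1)
        if task.mode == "classification":
            labels = batch.class_label
            if by_posterior_bin:
                eff = task
                if cue_id is not None:
                    eff = TaskSpec.classification(
                        prior=task.cue_table[cue_id],
                        class_means=task.class_means,
                        class_variance=task.class_variance,
                    )
                dec = decode_likelihood_batch(batch.spikes, spec)
                post = np.asarray(posterior_class1(class_log_odds(dec, eff)))
                bins = np.clip((post * 10).astype(int), 0, 9)
            else:
                bins = np.zeros(len(batch), dtype=int)
            for cls in (1, 2):
                for b in np.unique(bins):
                    m = (labels == cls) & (bins == b)
                    if not m.any():
                        continue
                    rows.append(
                        {
                            "contrast": float(c),
                            "class": cls,
                            "posterior_bin": int(b) if by_posterior_bin else -1,
                            "n": int(m.sum()),
                            "active_count": float(active[m].mean()),
                            "mean_activity": float(activity[m].mean()),
                        }
                    )
        else:
            rows.append(
                {
                    "contrast": float(c),
                    "class": 0,
                    "posterior_bin": -1,
                    "n": len(batch),
                    "active_count": float(active.mean()),
                    "mean_activity": float(activity.mean()),
                }
            )
    return pd.DataFrame(rows)


def preactivation_histogram(
    params: NetworkParams,
    task: TaskSpec,
    spec: EncoderSpec,
    contrasts,
    n_trials: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pooled template-match values W^T r + b per contrast.

    Returns a summary frame (contrast, mean, std, interdecile range) plus the
    pooled values in the attribute-free column ``values`` of a companion dict;
    callers needing raw values can recompute them cheaply, so only summaries
    are returned.
    """
    rows = []
    for c in np.atleast_1d(np.asarray(contrasts, dtype=float)):
        batch = sample_trials(task, spec, n_trials, rng, contrast=c)
        z = forward_preactivation(batch.spikes, params).ravel()
        q10, q90 = np.quantile(z, [0.1, 0.9])
        rows.append(
            {
                "contrast": float(c),
                "mean": float(z.mean()),
                "std": float(z.std()),
                "interdecile": float(q90 - q10),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subpopulations and cue attribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubpopulationSplit:
    """Partition of hidden units by preferred class: H1 = U(C=1) > U(C=2)."""

    h1: np.ndarray  # boolean mask over hidden units

    @property
    def h2(self) -> np.ndarray:
        return ~self.h1


def subpopulation_split(params: NetworkParams) -> SubpopulationSplit:
    if params.n_out != 2:
        raise ValueError("subpopulation split requires a classification readout")
    # ties (measure-zero) go to H2
    return SubpopulationSplit(h1=params.U[:, 0] > params.U[:, 1])


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def subpopulation_param_means(params: NetworkParams) -> pd.DataFrame:
    """Mean +- SE of biases, input-weight columns and readout weights per
    subpopulation, with a Welch test between subpopulations per parameter.

    A degenerate split (one side empty) is flagged with NaN statistics.
    """
    split = subpopulation_split(params)
    per_unit = {
        "bias": params.b,
        "input_weight": params.W.mean(axis=0),
        "readout_weight": params.U.mean(axis=1),
    }
    rows = []
    degenerate = not (split.h1.any() and split.h2.any())
    for name, values in per_unit.items():
        x, y = values[split.h1], values[split.h2]
        if degenerate:
            t = p = np.nan
        else:
            t, p = _welch(x, y)
        rows.append(
            {
                "parameter": name,
                "mean_h1": float(x.mean()) if x.size else np.nan,
                "sem_h1": float(stats.sem(x)) if x.size > 1 else np.nan,
                "mean_h2": float(y.mean()) if y.size else np.nan,
                "sem_h2": float(stats.sem(y)) if y.size > 1 else np.nan,
                "t": t,
                "p": p,
                "n_h1": int(x.size),
                "n_h2": int(y.size),
            }
        )
    return pd.DataFrame(rows)


def cue_attribution(
    params: NetworkParams, split: SubpopulationSplit | None = None
) -> pd.DataFrame:
    """Per-cue mean gain and cue-bias per subpopulation, with Welch tests."""
    if not params.has_cue:
        raise ValueError("cue_attribution requires cue parameters")
    if split is None:
        split = subpopulation_split(params)
    rows = []
    for ci, cue in enumerate(params.cue_ids):
        for pname, arr in (("gain", params.g_cue), ("cue_bias", params.b_cue)):
            x, y = arr[ci][split.h1], arr[ci][split.h2]
            t, p = _welch(x, y)
            rows.append(
                {
                    "cue": cue,
                    "parameter": pname,
                    "mean_h1": float(x.mean()),
                    "sem_h1": float(stats.sem(x)),
                    "mean_h2": float(y.mean()),
                    "sem_h2": float(stats.sem(y)),
                    "t": t,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def ablate_cue(params: NetworkParams, channel: str) -> NetworkParams:
    """Remove the cue dependence of one modulation channel.

    Each unit's per-cue value is replaced by that unit's across-cue mean, so
    the average drive is preserved while the cue can no longer move it.
    ``channel`` is "gain", "bias" or "none" (identity).
    """
    if not params.has_cue:
        raise ValueError("ablate_cue requires cue parameters")
    if channel not in ("gain", "bias", "none"):
        raise ValueError(f"unknown ablation channel {channel!r}")
    out = params.copy()
    if channel == "gain":
        out.g_cue = np.broadcast_to(
            params.g_cue.mean(axis=0, keepdims=True), params.g_cue.shape
        ).copy()
    elif channel == "bias":
        out.b_cue = np.broadcast_to(
            params.b_cue.mean(axis=0, keepdims=True), params.b_cue.shape
        ).copy()
    return out


def classification_accuracy(
    params: NetworkParams,
    task: TaskSpec,
    spec: EncoderSpec,
    contrast: float,
    n_trials: int,
    rng: np.random.Generator,
    cue_id: int | None = None,
) -> dict[int, float]:
    """Held-out per-class accuracy of the network's argmax decision."""
    eff = task
    if cue_id is not None:
        eff = TaskSpec.classification(
            prior=task.cue_table[cue_id],
            class_means=task.class_means,
            class_variance=task.class_variance,
        )
    batch = sample_trials(eff, spec, n_trials, rng, contrast=contrast)
    h = forward_hidden(batch.spikes, params, cue_id=cue_id)
    p = readout_classify(h, params.U)
    predicted = np.where(p[:, 0] > 0.5, 1, 2)
    return {
        cls: float(np.mean(predicted[batch.class_label == cls] == cls))
        for cls in (1, 2)
    }


def cue_accuracy_asymmetry(
    params: NetworkParams,
    task: TaskSpec,
    spec: EncoderSpec,
    contrast: float,
    n_trials: int,
    rng: np.random.Generator,
) -> float:
    """Mean over cues of (favoured-class accuracy - unfavoured-class accuracy)."""
    gaps = []
    for cue in params.cue_ids:
        acc = classification_accuracy(
            params, task, spec, contrast, n_trials, rng, cue_id=cue
        )
        favoured = 1 if task.cue_table[cue] > 0.5 else 2
        gaps.append(acc[favoured] - acc[3 - favoured])
    return float(np.mean(gaps))


# ---------------------------------------------------------------------------
# tuning-curve geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningCurveSummary:
    unit_id: int
    grid: np.ndarray
    response: np.ndarray  # smoothed mean activity per grid point
    peak_location: float
    peak_response: float
    max_slope_location: float | None
    fwhm: float | None
    active: bool


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def _half_crossing(grid, y, start, stop, step, half):
    """Walk from ``start`` toward ``stop`` until y crosses below half;
    linearly interpolate the crossing point.  Returns None at the boundary."""
    i = start
    while i != stop:
        j = i + step
        if y[j] < half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[j])
            return grid[i] + frac * (grid[j] - grid[i])
        i = j
    return None


def summarize_tuning_curve(
    unit_id: int,
    grid: np.ndarray,
    response: np.ndarray,
    smooth_window: int = 5,
    activity_floor: float = ACTIVITY_FLOOR,
    slope_mode: str = "max_abs_first_derivative",
) -> TuningCurveSummary:
    """Geometry of one estimated tuning curve.

    The response is smoothed by a moving average before differencing.  The
    maximal-slope location is the interior grid point with the largest
    absolute central first difference (``slope_mode="max_second_derivative"``
    selects the largest second difference instead).  FWHM requires the curve
    to cross half of its peak on both flanks inside the grid.
    """
    if len(grid) < smooth_window + 2:
        raise ValueError("grid shorter than the smoothing window")
    y = _smooth(np.asarray(response, dtype=float), smooth_window)
    peak_idx = int(np.argmax(y))
    peak = float(y[peak_idx])
    active = peak > activity_floor
    if not active or np.ptp(y) <= activity_floor:
        return TuningCurveSummary(
            unit_id, grid, y, float(grid[peak_idx]), peak, None, None, active
        )
    if slope_mode == "max_abs_first_derivative":
        deriv = np.abs(y[2:] - y[:-2]) / (grid[2:] - grid[:-2])
    elif slope_mode == "max_second_derivative":
        deriv = np.abs(np.diff(y, 2))
    else:
        raise ValueError(f"unknown slope_mode {slope_mode!r}")
    slope_loc = float(grid[1:-1][int(np.argmax(deriv))])
    half = peak / 2.0
    left = _half_crossing(grid, y, peak_idx, 0, -1, half)
    right = _half_crossing(grid, y, peak_idx, len(grid) - 1, 1, half)
    fwhm = None if (left is None or right is None) else float(right - left)
    return TuningCurveSummary(
        unit_id, grid, y, float(grid[peak_idx]), peak, slope_loc, fwhm, active
    )


def estimate_tuning_curves(
    params: NetworkParams,
    spec: EncoderSpec,
    grid: np.ndarray | None = None,
    contrast: float | None = None,
    n_repeats: int = 200,
    rng: np.random.Generator | None = None,
    cue_id: int | None = None,
    smooth_window: int = 5,
    slope_mode: str = "max_abs_first_derivative",
) -> list[TuningCurveSummary]:
    """Map each hidden unit's tuning curve by repeated Poisson presentation.

    Defaults: grid step 0.25 over [-20, 20], 200 draws per grid point at the
    highest contrast of the encoder's set.
    """
    if grid is None:
        grid = np.arange(-20.0, 20.0 + 0.125, 0.25)
    if contrast is None:
        contrast = max(spec.contrast_levels)
    if rng is None:
        rng = np.random.default_rng()
    responses = np.empty((len(grid), params.n_hidden))
    for gi, s in enumerate(grid):
        rates = tuning_rate(float(s), contrast, spec)
        spikes = rng.poisson(rates, size=(n_repeats, spec.n_neurons))
        h = forward_hidden(spikes, params, cue_id=cue_id)
        responses[gi] = h.mean(axis=0)
    return [
        summarize_tuning_curve(
            k, grid, responses[:, k], smooth_window=smooth_window,
            slope_mode=slope_mode,
        )
        for k in range(params.n_hidden)
    ]


def tuning_histograms(
    summaries_by_condition: dict, bins: np.ndarray | None = None
) -> pd.DataFrame:
    """Histogram counts and dispersion summaries per prior condition.

    Inactive units and invalid FWHM/slope values are excluded from the
    corresponding histograms.
    """
    if bins is None:
        bins = np.linspace(-20.0, 20.0, 41)
    rows = []
    for label, summaries in summaries_by_condition.items():
        act = [t for t in summaries if t.active]
        peaks = np.array([t.peak_location for t in act])
        slopes = np.array(
            [t.max_slope_location for t in act if t.max_slope_location is not None]
        )
        fwhms = np.array([t.fwhm for t in act if t.fwhm is not None])
        rows.append(
            {
                "condition": label,
                "n_active": len(act),
                "n_slope": slopes.size,
                "n_fwhm": fwhms.size,
                "peak_hist": np.histogram(peaks, bins=bins)[0].tolist(),
                "slope_hist": np.histogram(slopes, bins=bins)[0].tolist(),
                "slope_std": float(slopes.std(ddof=1)) if slopes.size > 1 else np.nan,
                "median_fwhm": float(np.median(fwhms)) if fwhms.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def peak_bimodality_test(
    values: np.ndarray,
    rng: np.random.Generator,
    n_boot: int = 200,
) -> dict:
    """Two-mode vs one-mode Gaussian fit with a parametric bootstrap LRT.

    Fits a single Gaussian and a 2-component Gaussian mixture to ``values``;
    the p-value is the bootstrap probability, under the single-Gaussian null,
    of a likelihood-ratio statistic at least as large as observed.  Returns
    the statistic, p-value and the two fitted component means.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).reshape(-1, 1)

    def lrt(x) -> tuple[float, np.ndarray]:
        ll1 = stats.norm.logpdf(x, x.mean(), x.std(ddof=0) + 1e-12).sum()
        gm = GaussianMixture(2, n_init=3, random_state=0).fit(x)
        return 2.0 * (gm.score(x) * len(x) - ll1), gm.means_.ravel()

    observed, means = lrt(values)
    mu, sd = values.mean(), values.std(ddof=0)
    null = np.empty(n_boot)
    for i in range(n_boot):
        null[i] = lrt(rng.normal(mu, sd, size=values.shape))[0]
    p = float((1 + np.sum(null >= observed)) / (1 + n_boot))
    return {"statistic": float(observed), "p": p, "component_means": np.sort(means)}


def expected_unexpected_bias(
    summaries: list[TuningCurveSummary],
    params: NetworkParams,
    task: TaskSpec,
    rng: np.random.Generator | None = None,
    n_permutations: int = 1000,
) -> dict:
    """Mean hidden bias of units tuned to expected vs unexpected stimuli.

    Expected units have their maximal-slope location within one SD of the
    stimulus prior; unexpected units are the remainder (among units with a
    valid slope location).  Reports a Welch test and a label-permutation
    p-value for mean(b_expected) - mean(b_unexpected) > 0.
    """
    if task.mode != "estimation":
        raise ValueError("expected/unexpected split requires an estimation task")
    sd = np.sqrt(task.prior_variance)
    units = [t for t in summaries if t.active and t.max_slope_location is not None]
    expected_mask = np.array(
        [abs(t.max_slope_location - task.prior_mean) <= sd for t in units]
    )
    b = params.b[np.array([t.unit_id for t in units])]
    out: dict = {
        "n_expected": int(expected_mask.sum()),
        "n_unexpected": int((~expected_mask).sum()),
    }
    if out["n_expected"] == 0 or out["n_unexpected"] == 0:
        out["degenerate"] = True
        return out
    out["degenerate"] = False
    be, bu = b[expected_mask], b[~expected_mask]
    out["mean_bias_expected"] = float(be.mean())
    out["mean_bias_unexpected"] = float(bu.mean())
    out["difference"] = float(be.mean() - bu.mean())
    out["t"], out["p_welch"] = _welch(be, bu)
    if rng is not None:
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(expected_mask)
            null[i] = b[perm].mean() - b[~perm].mean()
        out["p_permutation"] = float(
            (1 + np.sum(null >= out["difference"])) / (1 + n_permutations)
        )
    return out


def perceptual_bias(
    params: NetworkParams,
    task: TaskSpec,
    spec: EncoderSpec,
    grid: np.ndarray | None = None,
    contrast: float | None = None,
    n_repeats: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Signed bias and RMSE of the network estimate per grid stimulus.

    Each grid stimulus in [-10, 10] is presented ``n_repeats`` times at the
    given contrast; the ideal MAP bias on the same spike draws is overlaid.
    """
    if task.mode != "estimation":
        raise ValueError("perceptual_bias requires an estimation task")
    if grid is None:
        grid = np.arange(-10.0, 10.0 + 0.25, 0.5)
    if contrast is None:
        contrast = max(spec.contrast_levels)
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for s in grid:
        rates = tuning_rate(float(s), contrast, spec)
        spikes = rng.poisson(rates, size=(n_repeats, spec.n_neurons))
        shat = readout_estimate(forward_hidden(spikes, params), params.U)
        smap = map_estimate(decode_likelihood_batch(spikes, spec), task)
        rows.append(
            {
                "stimulus": float(s),
                "bias": float(np.mean(shat - s)),
                "rmse": float(np.sqrt(np.mean((shat - s) ** 2))),
                "map_bias": float(np.mean(smap - s)),
                "map_rmse": float(np.sqrt(np.mean((smap - s) ** 2))),
            }
        )
    return pd.DataFrame(rows)
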