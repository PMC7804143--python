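"""Poisson population encoder and task definitions.

The stimulus is a one-dimensional variable (think orientation) encoded by a
bank of independent Poisson neurons with Gaussian tuning curves

    lambda_i(s) = c * exp(-(s - phi_i)^2 / (2 sigma^2)),

where the tuning-curve peaks ``phi_i`` tile the stimulus range uniformly and
the global contrast ``c`` scales every rate, controlling input reliability.
Two task families draw the stimuli:

* classification — the stimulus comes from one of two Gaussian classes
  (means -5 and +5, shared variance 25) whose relative frequency pi defines a
  discrete prior; optionally a contextual cue selects the prior per trial;
* estimation — the stimulus comes from a single zero-mean Gaussian prior whose
  variance controls how concentrated "expected" stimuli are.

All randomness flows through an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASSIFICATION_CONTRASTS",
    "ESTIMATION_CONTRASTS",
    "EncoderSpec",
    "TaskSpec",
    "Trial",
    "TrialBatch",
    "tuning_rate",
    "sample_trial",
    "sample_trials",
    "trials_to_csv",
    "trials_from_csv",
]

#: Contrast sets used during training for each task.
CLASSIFICATION_CONTRASTS: tuple[float, ...] = (0.5, 1.2, 1.9, 2.6, 3.3, 4.0)
ESTIMATION_CONTRASTS: tuple[float, ...] = (0.30, 0.72, 1.45, 2.26, 2.86, 3.2)


class ConfigurationError(ValueError):
    """Raised for invalid encoder/task configurations."""


@dataclass(frozen=True)
class EncoderSpec:
    """Geometry of the Poisson input population.

    Parameters
    ----------
    n_neurons:
        Number of input neurons (default 50).
    tuning_variance:
        Width sigma^2 of every Gaussian tuning curve, in stimulus units
        squared (default 10).
    center_range:
        Closed interval tiled by the tuning-curve peaks (default [-20, 20]).
    contrast_levels:
        Contrast values presented during training/evaluation.
    centers:
        Tuning-curve peak locations; by default ``n_neurons`` evenly spaced
        points including both endpoints of ``center_range``.
    """

    n_neurons: int = 50
    tuning_variance: float = 10.0
    center_range: tuple[float, float] = (-20.0, 20.0)
    contrast_levels: tuple[float, ...] = CLASSIFICATION_CONTRASTS
    centers: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ConfigurationError("n_neurons must be positive")
        if self.tuning_variance <= 0:
            raise ConfigurationError("tuning_variance must be positive")
        if any(c < 0 for c in self.contrast_levels):
            raise ConfigurationError("contrast levels must be non-negative")
        if self.centers is None:
            lo, hi = self.center_range
            centers = np.linspace(lo, hi, self.n_neurons)
        else:
            centers = np.asarray(self.centers, dtype=float)
            if centers.shape != (self.n_neurons,):
                raise ConfigurationError("centers must have length n_neurons")
            if np.any(np.diff(centers) <= 0):
                raise ConfigurationError("centers must be strictly increasing")
        object.__setattr__(self, "centers", centers)


@dataclass(frozen=True)
class TaskSpec:
    """One of the two tasks: discrete-prior classification or
    continuous-prior estimation.

    ``class_prior`` is pi = P(C=1).  For cued classification, ``cue_table``
    maps each cue id to its own pi; cues are presented equiprobably.
    """

    mode: str  # "classification" | "estimation"
    class_means: tuple[float, float] = (-5.0, 5.0)
    class_variance: float = 25.0
    class_prior: float = 0.5
    prior_mean: float = 0.0
    prior_variance: float = 25.0
    cue_table: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("classification", "estimation"):
            raise ConfigurationError(f"unknown task mode {self.mode!r}")
        if not 0.0 < self.class_prior < 1.0:
            raise ConfigurationError("class_prior must lie strictly in (0, 1)")
        if self.class_variance <= 0 or self.prior_variance <= 0:
            raise ConfigurationError("variances must be positive")
        if self.cue_table is not None:
            if self.mode != "classification":
                raise ConfigurationError("cues only apply to classification")
            if not self.cue_table:
                raise ConfigurationError("cue_table must not be empty")
            for cue, pi in self.cue_table.items():
                if not 0.0 < pi < 1.0:
                    raise ConfigurationError(
                        f"cue {cue}: prior {pi} outside (0, 1)"
                    )
            object.__setattr__(self, "cue_table", dict(self.cue_table))

    # -- convenience constructors -------------------------------------------------
    @staticmethod
    def classification(prior: float = 0.5, **kwargs) -> "TaskSpec":
        return TaskSpec(mode="classification", class_prior=prior, **kwargs)

    @staticmethod
    def cued_classification(
        cue_table: Mapping[int, float] | None = None, **kwargs
    ) -> "TaskSpec":
        if cue_table is None:
            cue_table = {0: 0.25, 1: 0.75}
        return TaskSpec(mode="classification", cue_table=cue_table, **kwargs)

    @staticmethod
    def estimation(prior_variance: float, prior_mean: float = 0.0, **kwargs) -> "TaskSpec":
        return TaskSpec(
            mode="estimation",
            prior_variance=prior_variance,
            prior_mean=prior_mean,
            **kwargs,
        )

    @property
    def cue_ids(self) -> tuple[int, ...] | None:
        if self.cue_table is None:
            return None
        return tuple(sorted(self.cue_table))


@dataclass(frozen=True)
class Trial:
    """A single presented stimulus with its Poisson population response."""

    stimulus: float
    contrast: float
    spikes: np.ndarray
    class_label: int | None = None  # 1 or 2, classification only
    cue_id: int | None = None


@dataclass(frozen=True)
class TrialBatch:
    """Column-wise batch of trials (vectorised counterpart of :class:`Trial`)."""

    stimulus: np.ndarray  # (n,)
    contrast: np.ndarray  # (n,)
    spikes: np.ndarray  # (n, n_neurons)
    class_label: np.ndarray | None = None  # (n,) of {1, 2}
    cue_id: np.ndarray | None = None  # (n,)

    def __len__(self) -> int:
        return self.stimulus.shape[0]

    def __getitem__(self, i: int) -> Trial:
        return Trial(
            stimulus=float(self.stimulus[i]),
            contrast=float(self.contrast[i]),
            spikes=self.spikes[i],
            class_label=None if self.class_label is None else int(self.class_label[i]),
            cue_id=None if self.cue_id is None else int(self.cue_id[i]),
        )


def tuning_rate(s, c, spec: EncoderSpec) -> np.ndarray:
    """Poisson rate of every input neuron for stimulus ``s`` at contrast ``c``.

    Accepts a scalar stimulus (returns shape ``(n_neurons,)``) or an array of
    stimuli (returns ``(len(s), n_neurons)``).  ``c`` may be scalar or
    broadcastable against ``s``.
    """
    if np.any(np.asarray(c) < 0):
        raise ValueError("contrast must be non-negative")
    s_arr = np.asarray(s, dtype=float)
    scalar = s_arr.ndim == 0
    s_arr = np.atleast_1d(s_arr)[:, None]
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    if c_arr.ndim == 1 and c_arr.size > 1:
        c_arr = c_arr[:, None]
    rates = c_arr * np.exp(
        -((s_arr - spec.centers[None, :]) ** 2) / (2.0 * spec.tuning_variance)
    )
    return rates[0] if scalar else rates


def sample_trials(
    task: TaskSpec,
    spec: EncoderSpec,
    n: int,
    rng: np.random.Generator,
    contrast: float | Sequence[float] | None = None,
) -> TrialBatch:
    """Sample ``n`` trials from the task's generative model.

    ``contrast=None`` draws the contrast per trial uniformly from
    ``spec.contrast_levels``; a scalar fixes it; a length-``n`` array uses the
    given values directly.
    """
    if contrast is None:
        if len(spec.contrast_levels) == 0:
            raise ConfigurationError("contrast_levels is empty")
        contrasts = rng.choice(np.asarray(spec.contrast_levels, dtype=float), size=n)
    else:
        contrasts = np.broadcast_to(np.asarray(contrast, dtype=float), (n,)).copy()

    class_label = cue_id = None
    if task.mode == "classification":
        if task.cue_table is not None:
            ids = np.asarray(task.cue_ids)
            cue_id = ids[rng.integers(0, len(ids), size=n)]
            pi = np.asarray([task.cue_table[int(c)] for c in cue_id])
        else:
            pi = task.class_prior
        class_label = np.where(rng.random(n) < pi, 1, 2)
        mu = np.where(class_label == 1, task.class_means[0], task.class_means[1])
        stimulus = rng.normal(mu, np.sqrt(task.class_variance))
    else:
        stimulus = rng.normal(task.prior_mean, np.sqrt(task.prior_variance), size=n)

    rates = tuning_rate(stimulus, contrasts, spec)
    spikes = rng.poisson(rates)
    return TrialBatch(
        stimulus=stimulus,
        contrast=contrasts,
        spikes=spikes,
        class_label=class_label,
        cue_id=cue_id,
    )


def sample_trial(
    task: TaskSpec,
    spec: EncoderSpec,
    rng: np.random.Generator,
    contrast: float | None = None,
) -> Trial:
    """Sample a single trial (see :func:`sample_trials`)."""
    return sample_trials(task, spec, 1, rng, contrast=contrast)[0]


# -- CSV fixture round trip -----------------------------------------------------

def trials_to_csv(batch: TrialBatch, path) -> None:
    n, n_neurons = batch.spikes.shape
    data = {
        "trial": np.arange(n),
        "stimulus": batch.stimulus,
        "contrast": batch.contrast,
        "class": batch.class_label if batch.class_label is not None else [""] * n,
        "cue": batch.cue_id if batch.cue_id is not None else [""] * n,
    }
    for i in range(n_neurons):
        data[f"r_{i}"] = batch.spikes[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


def trials_from_csv(path) -> TrialBatch:
    df = pd.read_csv(path)
    spike_cols = [c for c in df.columns if c.startswith("r_")]
    spike_cols.sort(key=lambda c: int(c.split("_")[1]))
    cls = df["class"]
    cue = df["cue"]
    return TrialBatch(
        stimulus=df["stimulus"].to_numpy(float),
        contrast=df["contrast"].to_numpy(float),
        spikes=df[spike_cols].to_numpy(int),
        class_label=None if cls.isna().all() else cls.to_numpy(int),
        cue_id=None if cue.isna().all() else cue.to_numpy(int),
    )
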