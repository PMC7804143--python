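"""Trial-by-trial supervised training of the rate network.

The protocol mirrors standard deep-learning practice for this model family:
Adam with learning rate 2e-4, minibatches of 10 trials, 1000 iterations per
epoch.  The full budget is 100 epochs; the package's scaled protocol
(used throughout the tests and reproduction scripts) runs 20 epochs, which is
sufficient for the qualitative effects at desk cost.

Besides the per-iteration loss, training can log a learning-signal statistic:
the magnitude of the input-weight update attributable to a single trial,
computed as the hypothetical Adam step for that trial's gradient alone given
the optimizer's current moment estimates.  Averaged by trial class, this
quantifies how much likely vs unlikely stimuli still drive plasticity late in
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoder import EncoderSpec, TaskSpec, sample_trials
from .network import NetworkParams, _activate, init_params

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "loss_classification",
    "loss_estimation",
    "train",
]

PROB_FLOOR = 1e-12  # clamp inside logs so cross-entropy stays finite


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    minibatch: int = 10
    epochs: int = 100
    iters_per_epoch: int = 1000
    loss: str = "cross_entropy"  # or "squared_error"
    activation: str = "relu"
    n_hidden: int = 200
    seed: int | None = None
    log_weight_updates: bool = False
    weight_log_epochs: int = 10  # final epochs in which |dW| is logged
    weight_log_stride: int = 10  # log every stride-th iteration

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        for name in ("minibatch", "epochs", "iters_per_epoch", "n_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loss not in ("cross_entropy", "squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @staticmethod
    def scaled(**kwargs) -> "TrainConfig":
        """The package's desk-scale protocol: 20 epochs x 1000 iterations."""
        kwargs.setdefault("epochs", 20)
        return TrainConfig(**kwargs)


@dataclass
class TrainingLog:
    """Per-iteration loss trace plus optional per-trial weight-update log."""

    loss: np.ndarray  # (epochs * iters,)
    epochs: int
    iters_per_epoch: int
    weight_updates: pd.DataFrame | None = None  # epoch, iter, class, mean_abs_dW

    def epoch_mean_loss(self) -> np.ndarray:
        return self.loss.reshape(self.epochs, self.iters_per_epoch).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        it = np.arange(self.loss.size)
        return pd.DataFrame(
            {
                "epoch": it // self.iters_per_epoch,
                "iter": it % self.iters_per_epoch,
                "loss": self.loss,
            }
        )


def loss_classification(probs, label: int) -> float:
    """Binary cross-entropy -(t log p(C1) + (1-t) log p(C2)), t = [label==1]."""
    p1, p2 = float(probs[0]), float(probs[1])
    t = 1.0 if label == 1 else 0.0
    p1 = max(p1, PROB_FLOOR)
    p2 = max(p2, PROB_FLOOR)
    return -(t * np.log(p1) + (1.0 - t) * np.log(p2))


def loss_estimation(estimate: float, stimulus: float) -> float:
    """Squared error (s - s_hat)^2."""
    return float((stimulus - estimate) ** 2)


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def hypothetical_step_magnitude(self, key: str, grads: np.ndarray) -> np.ndarray:
        """mean|update| that each of a stack of gradients would produce.

        ``grads`` has shape (B, *param_shape); moments are advanced one
        hypothetical step per gradient without mutating optimizer state.
        """
        t = self.t + 1
        c1 = 1.0 - self.b1**t
        c2 = 1.0 - self.b2**t
        m = self.b1 * self.m[key] + (1 - self.b1) * grads
        v = self.b2 * self.v[key] + (1 - self.b2) * grads * grads
        upd = self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
        return np.abs(upd).mean(axis=tuple(range(1, upd.ndim)))


def _act_grad(a: np.ndarray, h: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return (a > 0).astype(float)
    if activation == "leaky_relu":
        return np.where(a > 0, 1.0, 0.01)
    if activation == "sigmoid":
        return h * (1.0 - h)
    raise ValueError(activation)


def _output_grad(y, p, targets, stimulus, task_mode, loss_kind, B):
    """dL/dy averaged over the batch; also returns per-trial batch loss."""
    if task_mode == "classification":
        if loss_kind == "cross_entropy":
            per_trial = -np.log(np.maximum(p[np.arange(B), targets], PROB_FLOOR))
            dy = p.copy()
            dy[np.arange(B), targets] -= 1.0
        else:  # squared error on softmax probabilities vs one-hot target
            t = np.zeros_like(p)
            t[np.arange(B), targets] = 1.0
            per_trial = ((p - t) ** 2).sum(axis=1)
            dLdp = 2.0 * (p - t)
            dy = p * (dLdp - (dLdp * p).sum(axis=1, keepdims=True))
        return dy / B, per_trial
    residual = y[:, 0] - stimulus
    per_trial = residual**2
    dy = (2.0 * residual / B)[:, None]
    return dy, per_trial


def train(
    task: TaskSpec,
    spec: EncoderSpec,
    config: TrainConfig,
    rng: np.random.Generator,
    init: NetworkParams | None = None,
) -> tuple[NetworkParams, TrainingLog]:
    """Train a network on the task, returning parameters and the log.

    Stimuli, classes, cues and contrasts are freshly sampled every epoch from
    the task's generative model; contrasts are drawn uniformly from the
    encoder's contrast set.
    """
    if task.mode == "estimation" and config.loss != "squared_error":
        config = replace(config, loss="squared_error")
    params = init if init is not None else init_params(
        spec.n_neurons, config.n_hidden, task, rng, activation=config.activation
    )
    pdict = {"W": params.W, "b": params.b, "U": params.U}
    if params.has_cue:
        pdict["g_cue"] = params.g_cue
        pdict["b_cue"] = params.b_cue
    adam = _Adam({k: v.shape for k, v in pdict.items()}, config.learning_rate)

    B = config.minibatch
    losses = np.empty(config.epochs * config.iters_per_epoch)
    wlog: list[tuple[int, int, int, float]] = []
    log_from_epoch = config.epochs - config.weight_log_epochs

    for epoch in range(config.epochs):
        batch = sample_trials(task, spec, config.iters_per_epoch * B, rng)
        r_all = batch.spikes.astype(float)
        for it in range(config.iters_per_epoch):
            sl = slice(it * B, (it + 1) * B)
            r = r_all[sl]
            z = r @ params.W + params.b
            if params.has_cue:
                idx = params.cue_index(batch.cue_id[sl])
                g = 1.0 + params.g_cue[idx]
                pre = z + params.b_cue[idx]
                a = g * pre
            else:
                a = z
            h = _activate(a, config.activation)
            y = h @ params.U

            if task.mode == "classification":
                ymax = y.max(axis=1, keepdims=True)
                e = np.exp(y - ymax)
                p = e / e.sum(axis=1, keepdims=True)
                targets = (batch.class_label[sl] == 2).astype(int)  # col 0 <-> C1
            else:
                p = None
                targets = None
            dy, per_trial_loss = _output_grad(
                y, p, targets, batch.stimulus[sl], task.mode, config.loss, B
            )
            losses[epoch * config.iters_per_epoch + it] = per_trial_loss.mean()
            if not np.isfinite(per_trial_loss).all():
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, iteration {it}"
                )

            gU = h.T @ dy
            dh = dy @ params.U.T
            da = dh * _act_grad(a, h, config.activation)
            grads = {"U": gU}
            if params.has_cue:
                dz = da * g
                grads["W"] = r.T @ dz
                grads["b"] = dz.sum(axis=0)
                gg = np.zeros_like(params.g_cue)
                gbc = np.zeros_like(params.b_cue)
                np.add.at(gg, idx, da * pre)
                np.add.at(gbc, idx, dz)
                grads["g_cue"] = gg
                grads["b_cue"] = gbc
            else:
                dz = da
                grads["W"] = r.T @ dz
                grads["b"] = dz.sum(axis=0)

            if (
                config.log_weight_updates
                and epoch >= log_from_epoch
                and it % config.weight_log_stride == 0
                and task.mode == "classification"
            ):
                # per-trial gradient of W: outer(r_j, dz_j), dz rescaled to B=1
                gW_trials = r[:, :, None] * (dz * B)[:, None, :]
                mags = adam.hypothetical_step_magnitude("W", gW_trials)
                for j in range(B):
                    wlog.append(
                        (epoch, it, int(batch.class_label[sl][j]), float(mags[j]))
                    )

            adam.step(pdict, grads)

    wframe = (
        pd.DataFrame(wlog, columns=["epoch", "iter", "class", "mean_abs_dW"])
        if wlog
        else None
    )
    return params, TrainingLog(
        loss=losses,
        epochs=config.epochs,
        iters_per_epoch=config.iters_per_epoch,
        weight_updates=wframe,
    )
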