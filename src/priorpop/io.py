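"""Run configuration, parameter archives and experiment orchestration.

A run is fully reproducible from its echoed config and seed: the config is a
flat YAML/JSON document, parameters are archived as a NumPy ``.npz`` with a
JSON sidecar recording shapes, task and seed, and all evaluation outputs are
CSV/JSON tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .encoder import (
    CLASSIFICATION_CONTRASTS,
    ESTIMATION_CONTRASTS,
    EncoderSpec,
    TaskSpec,
)
from .network import NetworkParams
from .training import TrainConfig, train

__all__ = ["RunConfig", "save_params", "load_params", "run_experiment"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one training + evaluation run."""

    mode: str = "classification"
    class_prior: float = 0.5
    prior_variance: float = 25.0
    prior_mean: float = 0.0
    cued: bool = False
    cue_priors: tuple[float, float] = (0.25, 0.75)
    n_neurons: int = 50
    n_hidden: int = 200
    tuning_variance: float = 10.0
    contrast_levels: tuple[float, ...] | None = None
    learning_rate: float = 2e-4
    minibatch: int = 10
    epochs: int = 20
    iters_per_epoch: int = 1000
    loss: str = "cross_entropy"
    activation: str = "relu"
    seed: int = 0
    n_eval_trials: int = 1000
    log_weight_updates: bool = False

    def encoder_spec(self) -> EncoderSpec:
        contrasts = self.contrast_levels
        if contrasts is None:
            contrasts = (
                CLASSIFICATION_CONTRASTS
                if self.mode == "classification"
                else ESTIMATION_CONTRASTS
            )
        return EncoderSpec(
            n_neurons=self.n_neurons,
            tuning_variance=self.tuning_variance,
            contrast_levels=tuple(contrasts),
        )

    def task_spec(self) -> TaskSpec:
        if self.mode == "classification":
            if self.cued:
                return TaskSpec.cued_classification(
                    {i: p for i, p in enumerate(self.cue_priors)}
                )
            return TaskSpec.classification(prior=self.class_prior)
        return TaskSpec.estimation(
            prior_variance=self.prior_variance, prior_mean=self.prior_mean
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            minibatch=self.minibatch,
            epochs=self.epochs,
            iters_per_epoch=self.iters_per_epoch,
            loss=self.loss,
            activation=self.activation,
            n_hidden=self.n_hidden,
            seed=self.seed,
            log_weight_updates=self.log_weight_updates,
        )

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in doc.items()
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return RunConfig.from_dict(doc)

    @staticmethod
    def from_dict(doc: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(doc) - names
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        doc = dict(doc)
        for key in ("cue_priors", "contrast_levels"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        cfg = RunConfig(**doc)
        cfg.task_spec()  # validates prior/variance ranges
        cfg.encoder_spec()
        cfg.train_config()
        return cfg


# ---------------------------------------------------------------------------
# parameter archives
# ---------------------------------------------------------------------------

def save_params(params: NetworkParams, path, meta: dict | None = None) -> None:
    """Archive parameters as <path>.npz with a JSON sidecar <path>.json."""
    path = Path(path)
    arrays = {"W": params.W, "b": params.b, "U": params.U}
    if params.has_cue:
        for i, cue in enumerate(params.cue_ids):
            arrays[f"g_cue:{cue}"] = params.g_cue[i]
            arrays[f"b_cue:{cue}"] = params.b_cue[i]
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
        "cue_ids": list(params.cue_ids) if params.cue_ids else None,
        "activation": params.activation,
        "n_in": params.n_in,
        "n_hidden": params.n_hidden,
        "n_out": params.n_out,
    }
    if meta:
        sidecar["meta"] = meta
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_params(path) -> NetworkParams:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    for name, shape in sidecar["shapes"].items():
        if name not in arrays:
            raise ValueError(f"archive missing array {name!r}")
        if list(arrays[name].shape) != shape:
            raise ValueError(
                f"shape mismatch for {name!r}: sidecar {shape}, "
                f"archive {list(arrays[name].shape)}"
            )
    g_cue = b_cue = None
    cue_ids = sidecar.get("cue_ids")
    if cue_ids:
        cue_ids = tuple(cue_ids)
        g_cue = np.stack([arrays[f"g_cue:{c}"] for c in cue_ids])
        b_cue = np.stack([arrays[f"b_cue:{c}"] for c in cue_ids])
    return NetworkParams(
        W=arrays["W"],
        b=arrays["b"],
        U=arrays["U"],
        g_cue=g_cue,
        b_cue=b_cue,
        cue_ids=cue_ids,
        activation=sidecar.get("activation", "relu"),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_experiment(config: RunConfig, out_dir) -> Path:
    """Train, evaluate and analyze one configuration; write all artifacts.

    The directory receives: the config echo (config.yaml), the parameter
    archive, the training-loss log, a held-out evaluation sweep and a JSON
    summary of the run's directional statistics.
    """
    from . import analysis as an
    from .ideal_observer import (
        class_log_odds,
        decode_likelihood_batch,
        map_estimate,
        posterior_class1,
    )
    from .network import forward_hidden, readout_classify, readout_estimate
    from .encoder import sample_trials

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    spec = config.encoder_spec()
    task = config.task_spec()
    rng = np.random.default_rng(config.seed)
    params, log = train(task, spec, config.train_config(), rng)
    save_params(params, out / "params", meta={"seed": config.seed, "mode": config.mode})
    log.to_frame().to_csv(out / "training_log.csv", index=False)
    if log.weight_updates is not None:
        log.weight_updates.to_csv(out / "weight_updates.csv", index=False)

    eval_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    summary: dict = {"seed": config.seed, "mode": config.mode}
    rows = []
    if config.mode == "classification":
        cues = params.cue_ids if params.has_cue else [None]
        for cue in cues:
            for c in spec.contrast_levels:
                eff = task if cue is None else TaskSpec.classification(
                    prior=task.cue_table[cue]
                )
                batch = sample_trials(eff, spec, config.n_eval_trials, eval_rng, contrast=c)
                h = forward_hidden(batch.spikes, params, cue_id=cue)
                p_net = readout_classify(h, params.U)[:, 0]
                dec = decode_likelihood_batch(batch.spikes, spec)
                p_ideal = np.asarray(posterior_class1(class_log_odds(dec, eff)))
                pred = np.where(p_net > 0.5, 1, 2)
                for i in range(len(batch)):
                    rows.append(
                        {
                            "cue": -1 if cue is None else cue,
                            "contrast": c,
                            "stimulus": batch.stimulus[i],
                            "class": int(batch.class_label[i]),
                            "p_net": p_net[i],
                            "p_ideal": p_ideal[i],
                            "correct": int(pred[i] == batch.class_label[i]),
                        }
                    )
        import pandas as pd

        sweep = pd.DataFrame(rows)
        sweep.to_csv(out / "evaluation.csv", index=False)
        slope, _ = np.polyfit(sweep["p_ideal"], sweep["p_net"], 1)
        summary["calibration_slope"] = float(slope)
        summary["calibration_rmse"] = float(
            np.sqrt(np.mean((sweep["p_net"] - sweep["p_ideal"]) ** 2))
        )
        summary["accuracy_by_class"] = {
            str(cls): float(sweep.loc[sweep["class"] == cls, "correct"].mean())
            for cls in (1, 2)
        }
        sub = an.subpopulation_param_means(params)
        sub.to_csv(out / "subpopulations.csv", index=False)
        bias_row = sub[sub["parameter"] == "bias"].iloc[0]
        summary["bias_difference_h1_h2"] = float(
            bias_row["mean_h1"] - bias_row["mean_h2"]
        )
        summary["bias_p"] = float(bias_row["p"])
    else:
        pb = an.perceptual_bias(params, task, spec, rng=eval_rng)
        pb.to_csv(out / "perceptual_bias.csv", index=False)
        summary["rmse_at_0"] = float(
            pb.loc[pb["stimulus"].abs().idxmin(), "rmse"]
        )
        summaries = an.estimate_tuning_curves(params, spec, rng=eval_rng)
        th = an.tuning_histograms({config.prior_variance: summaries})
        th.to_csv(out / "tuning_histograms.csv", index=False)
        summary["slope_std"] = float(th["slope_std"].iloc[0])
        summary["median_fwhm"] = float(th["median_fwhm"].iloc[0])

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
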