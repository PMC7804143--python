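"""Tuning-curve geometry: how a sharper stimulus prior reallocates resources.

Maps every hidden unit's tuning curve for estimation networks trained under
wide, moderate and sharp priors (full budget), then summarises peak
locations (bimodal about the prior mean for the sharp prior), maximal-slope
locations (concentrating with prior sharpness), full-widths at half maximum
(narrowing), population sparsity, and the bias advantage of units tuned to
expected stimuli.  Run after 05 or standalone (it retrains its networks).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from priorpop import analysis as an
from priorpop.encoder import ESTIMATION_CONTRASTS, EncoderSpec, TaskSpec
from priorpop.training import TrainConfig, train

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    spec = EncoderSpec(contrast_levels=ESTIMATION_CONTRASTS)
    out = BASE / "tuning_geometry"
    out.mkdir(parents=True, exist_ok=True)
    nets, summaries = {}, {}
    for i, var in enumerate((100.0, 10.0, 5.0)):
        task = TaskSpec.estimation(prior_variance=var)
        nets[var], _ = train(task, spec, TrainConfig(epochs=100),
                             np.random.default_rng(800 + i))
        summaries[var] = an.estimate_tuning_curves(
            nets[var], spec, rng=np.random.default_rng(900 + i)
        )

    th = an.tuning_histograms(summaries)
    th.to_csv(out / "tuning_histograms.csv", index=False)
    print(th[["condition", "n_active", "slope_std", "median_fwhm"]]
          .round(2).to_string(index=False))

    peaks = np.array([t.peak_location for t in summaries[5.0] if t.active])
    bim = an.peak_bimodality_test(peaks, np.random.default_rng(1000), n_boot=199)
    print(f"\npeak bimodality (sharp prior): LRT={bim['statistic']:.1f} "
          f"p={bim['p']:.3f} modes at {np.round(bim['component_means'], 1)}")

    rows = []
    for var in (100.0, 10.0, 5.0):
        res = an.expected_unexpected_bias(
            summaries[var], nets[var], TaskSpec.estimation(prior_variance=var),
            rng=np.random.default_rng(1100), n_permutations=10_000,
        )
        res["prior_variance"] = var
        rows.append(res)
    eu = pd.DataFrame(rows)
    eu.to_csv(out / "expected_unexpected_bias.csv", index=False)
    cols = ["prior_variance", "n_expected", "n_unexpected"]
    cols += [c for c in ("difference", "p_permutation") if c in eu.columns]
    print("\n" + eu[cols].round(4).to_string(index=False))
    print("\nSharper priors concentrate maximal slopes and narrow tuning "
          "curves; units tuned to expected stimuli carry higher biases.")
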