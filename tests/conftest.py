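"""Shared fixtures: encoder specs and the trained networks used by the
acceptance-level tests.

Training is the expensive step, so one network per condition is trained once
per session: classification networks at the desk-scale protocol (20 epochs x
1000 iterations), estimation networks at the full 100-epoch budget under
which the tuning-geometry effects are asymptotic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from priorpop.encoder import ESTIMATION_CONTRASTS, EncoderSpec, TaskSpec
from priorpop.training import TrainConfig, train

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")

CLASS_PRIORS = (0.25, 0.5, 0.75)
EST_VARIANCES = (100.0, 5.0, 10.0)


@pytest.fixture(scope="session")
def spec_cls() -> EncoderSpec:
    return EncoderSpec()


@pytest.fixture(scope="session")
def spec_est() -> EncoderSpec:
    return EncoderSpec(contrast_levels=ESTIMATION_CONTRASTS)


@pytest.fixture(scope="session")
def classification_nets(spec_cls):
    """pi -> (params, training log), scaled protocol, weight updates logged."""
    nets = {}
    for i, pi in enumerate(CLASS_PRIORS):
        task = TaskSpec.classification(prior=pi)
        cfg = TrainConfig.scaled(log_weight_updates=True)
        nets[pi] = train(task, spec_cls, cfg, np.random.default_rng(1000 + i))
    return nets


@pytest.fixture(scope="session")
def cue_net(spec_cls):
    """(params, log) of the cue-trained network (cue 0 -> pi=0.25, cue 1 -> 0.75)."""
    task = TaskSpec.cued_classification()
    return train(task, spec_cls, TrainConfig.scaled(), np.random.default_rng(2000))


@pytest.fixture(scope="session")
def estimation_nets(spec_est):
    """prior variance -> params, full 100-epoch budget."""
    nets = {}
    for i, var in enumerate(EST_VARIANCES):
        task = TaskSpec.estimation(prior_variance=var)
        cfg = TrainConfig(epochs=100)
        nets[var] = train(task, spec_est, cfg, np.random.default_rng(3000 + i))[0]
    return nets


@pytest.fixture(scope="session")
def tuning_summaries(estimation_nets, spec_est):
    from priorpop.analysis import estimate_tuning_curves

    rng = np.random.default_rng(4000)
    return {
        var: estimate_tuning_curves(params, spec_est, rng=rng)
        for var, params in estimation_nets.items()
    }
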