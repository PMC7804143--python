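"""Feedforward rate network: dense ReLU hidden layer with optional cue
modulation, and a task-specific readout.

Hidden activity for spike-count input ``r``:

    h_k = max(0, (W^T r)_k + b_k)                             (no cue)
    h_k = max(0, g_k * ((W^T r)_k + b_k + b_cue,k))           (cued)

where the effective gain ``g_k = 1 + g_cue,k`` is a cue-driven modulation of
a unit baseline: the cue input perturbs the gain and the bias of each hidden
unit around the shared computation, so with the cue parameters at their
neutral values (g_cue = 0, b_cue = 0) the cued network reduces exactly to
the no-cue form.  The readout is a softmax pair for classification or a
single linear unit for estimation; neither carries an output bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, softmax

from .encoder import TaskSpec

__all__ = [
    "NetworkParams",
    "init_params",
    "forward_preactivation",
    "forward_hidden",
    "readout_classify",
    "readout_estimate",
]

HIDDEN_UNITS_DEFAULT = 200

_ACTIVATIONS = ("relu", "leaky_relu", "sigmoid")
_LEAKY_SLOPE = 0.01


@dataclass
class NetworkParams:
    """All trainable parameters.

    ``W`` is (n_in, K): one input-weight column per hidden unit, so ``r @ W``
    is the K-vector of template matches.  ``U`` is (K, 2) for classification
    and (K, 1) for estimation.  ``g_cue``/``b_cue`` are (n_cues, K) and exist
    only for cued tasks; row order follows ``cue_ids``.  ``g_cue`` holds the
    cue-driven gain modulation (effective multiplier ``1 + g_cue``); its
    neutral value is 0, like ``b_cue``'s.
    """

    W: np.ndarray
    b: np.ndarray
    U: np.ndarray
    g_cue: np.ndarray | None = None
    b_cue: np.ndarray | None = None
    cue_ids: tuple[int, ...] | None = None
    activation: str = "relu"

    @property
    def n_in(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    @property
    def n_out(self) -> int:
        return self.U.shape[1]

    @property
    def has_cue(self) -> bool:
        return self.g_cue is not None

    def cue_index(self, cue_id) -> np.ndarray:
        """Map cue ids (scalar or array) to row indices of g_cue/b_cue."""
        lookup = {c: i for i, c in enumerate(self.cue_ids)}
        return np.vectorize(lookup.__getitem__)(cue_id)

    def copy(self) -> "NetworkParams":
        return replace(
            self,
            W=self.W.copy(),
            b=self.b.copy(),
            U=self.U.copy(),
            g_cue=None if self.g_cue is None else self.g_cue.copy(),
            b_cue=None if self.b_cue is None else self.b_cue.copy(),
        )


def init_params(
    n_in: int,
    K: int,
    task: TaskSpec,
    rng: np.random.Generator,
    activation: str = "relu",
) -> NetworkParams:
    """Initialise parameters from U(-sqrt(1/N_in), sqrt(1/N_in)).

    N_in is the fan-in of the layer: ``n_in`` for W, b (and the cue vectors),
    ``K`` for the readout U.
    """
    if n_in <= 0 or K <= 0:
        raise ValueError("layer sizes must be positive")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    lim_in = np.sqrt(1.0 / n_in)
    lim_hid = np.sqrt(1.0 / K)
    n_out = 2 if task.mode == "classification" else 1
    W = rng.uniform(-lim_in, lim_in, size=(n_in, K))
    b = rng.uniform(-lim_in, lim_in, size=K)
    U = rng.uniform(-lim_hid, lim_hid, size=(K, n_out))
    g_cue = b_cue = None
    cue_ids = None
    if task.cue_table is not None:
        cue_ids = task.cue_ids
        g_cue = rng.uniform(-lim_in, lim_in, size=(len(cue_ids), K))
        b_cue = rng.uniform(-lim_in, lim_in, size=(len(cue_ids), K))
    return NetworkParams(
        W=W, b=b, U=U, g_cue=g_cue, b_cue=b_cue, cue_ids=cue_ids,
        activation=activation,
    )


def _activate(a: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(0.0, a)
    if activation == "leaky_relu":
        return np.where(a > 0, a, _LEAKY_SLOPE * a)
    if activation == "sigmoid":
        return expit(a)
    raise ValueError(f"unknown activation {activation!r}")


def forward_preactivation(r: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Template match W^T r + b (no cue terms, no rectification)."""
    return np.asarray(r, dtype=float) @ params.W + params.b


def forward_hidden(
    r: np.ndarray, params: NetworkParams, cue_id=None
) -> np.ndarray:
    """Hidden activity for a spike vector (n_in,) or batch (B, n_in)."""
    if cue_id is not None and not params.has_cue:
        raise ValueError("cue_id given but network has no cue parameters")
    if cue_id is None and params.has_cue:
        raise ValueError("cued network requires a cue_id")
    z = forward_preactivation(r, params)
    if params.has_cue:
        idx = params.cue_index(cue_id)
        a = (1.0 + params.g_cue[idx]) * (z + params.b_cue[idx])
    else:
        a = z
    return _activate(a, params.activation)


def readout_classify(h: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Softmax class probabilities (p(C1), p(C2)) from hidden activity."""
    if U.shape[1] != 2:
        raise ValueError("classification readout needs two output columns")
    return softmax(h @ U, axis=-1)


def readout_estimate(h: np.ndarray, U: np.ndarray) -> np.ndarray | float:
    """Linear stimulus estimate s_hat = U^T h."""
    if U.shape[1] != 1:
        raise ValueError("estimation readout needs one output column")
    y = h @ U
    return float(y[0]) if y.ndim == 1 else y[:, 0]
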