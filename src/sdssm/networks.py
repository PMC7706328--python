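"""Conditioner networks: trunks plus distribution heads.

Each conditioner maps a per-timestep conditioning vector to the parameters of
an output distribution.  Trunks are either a stack of dense+ReLU(+batch-norm)
layers or "recurrent-first": an LSTM cell as the first hidden layer whose
state carries causal context across timesteps, followed by dense layers.
Gaussian heads branch into two separate affine layers (mean and log-std,
clamped before exponentiation); categorical heads emit logits through a
single straight stack without the branch structure.

With ``n_hidden = 0`` and a dense trunk a conditioner degenerates to an
affine map, which is the configuration used by the linear-Gaussian
verification harness: its mean head can represent ``A z + B u`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .distributions import (CategoricalParams, DiagGaussianParams,
                            LOG_STD_BOUND)
from .nn import BatchNorm, Dense, LSTMCell

__all__ = ["ConditionerSpec", "GaussianConditioner", "CategoricalConditioner",
           "RecurrentEncoder", "recurrent_encode"]

#: distribution-parameter heads are initialized at this fraction of the He
#: scale so conditioners start near (mu = 0, sigma = 1) / uniform classes
HEAD_INIT_SCALE = 0.01


@dataclass
class ConditionerSpec:
    """Architecture of one conditioner network.

    ``min_log_std`` floors the emitted log standard deviation; raising it
    above the global clamp (for emission heads, where the measurement noise
    floor is physically known) prevents the likelihood-weight runaway that
    follows from a collapsing observation variance.
    """

    input_dim: int
    output_dim: int
    hidden_units: int = 128
    n_hidden: int = 1
    trunk: str = "dense"            # "dense" | "recurrent"
    head: str = "gaussian"          # "gaussian" | "categorical"
    use_batchnorm: bool = False
    activation: str = "relu"
    min_log_std: float = -LOG_STD_BOUND

    def __post_init__(self):
        if self.trunk not in ("dense", "recurrent"):
            raise ValueError(f"unknown trunk {self.trunk!r}")
        if self.head not in ("gaussian", "categorical"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if self.trunk == "recurrent" and self.n_hidden < 1:
            raise ValueError("a recurrent trunk needs at least one layer")


class _Trunk:
    """Shared trunk implementation (dense stack or recurrent-first)."""

    def __init__(self, spec: ConditionerSpec, rng: np.random.Generator):
        self.spec = spec
        self.lstm = None
        self.layers: list[Dense] = []
        self.norms: list[BatchNorm | None] = []
        dim = spec.input_dim
        n_dense = spec.n_hidden
        if spec.trunk == "recurrent":
            self.lstm = LSTMCell(dim, spec.hidden_units, rng)
            dim = spec.hidden_units
            n_dense -= 1
        for _ in range(n_dense):
            self.layers.append(Dense(dim, spec.hidden_units, rng,
                                     activation=spec.activation))
            # batch-norm only in dense trunks (training stability with
            # per-timestep recurrent state is poor)
            use_bn = spec.use_batchnorm and spec.trunk == "dense"
            self.norms.append(BatchNorm(spec.hidden_units) if use_bn else None)
            dim = spec.hidden_units
        self.out_dim = dim

    def init_state(self, batch: int):
        return self.lstm.init_state(batch) if self.lstm is not None else None

    def __call__(self, x, state, train: bool):
        if ad.value_of(x).shape[-1] != self.spec.input_dim:
            raise ValueError(
                f"input dim {ad.value_of(x).shape[-1]} != expected "
                f"{self.spec.input_dim}")
        if self.lstm is not None:
            x, state = self.lstm(x, state)
        for layer, norm in zip(self.layers, self.norms):
            x = layer(x)
            if norm is not None:
                x = norm(x, train)
        return x, state

    def params(self, prefix: str) -> dict:
        out = {}
        if self.lstm is not None:
            out.update(self.lstm.params(prefix + "lstm."))
        for i, layer in enumerate(self.layers):
            out.update(layer.params(f"{prefix}dense{i}."))
        for i, norm in enumerate(self.norms):
            if norm is not None:
                out.update(norm.params(f"{prefix}bn{i}."))
        return out


class GaussianConditioner:
    """Trunk feeding two separate affine heads for mean and log-std."""

    def __init__(self, spec: ConditionerSpec, rng: np.random.Generator):
        if spec.head != "gaussian":
            raise ValueError("spec.head must be 'gaussian'")
        self.spec = spec
        self.trunk = _Trunk(spec, rng)
        # heads start near (mu = 0, sigma = 1) so initial distributions are
        # standard-normal-like and the first KL terms are well scaled
        self.mu_head = Dense(self.trunk.out_dim, spec.output_dim, rng,
                             w_scale=HEAD_INIT_SCALE)
        self.logstd_head = Dense(self.trunk.out_dim, spec.output_dim, rng,
                                 w_scale=HEAD_INIT_SCALE)

    def init_state(self, batch: int):
        return self.trunk.init_state(batch)

    def step(self, x, state=None, train: bool = False):
        feats, state = self.trunk(x, state, train)
        mu = self.mu_head(feats)
        log_std = ad.clip(self.logstd_head(feats), self.spec.min_log_std,
                          LOG_STD_BOUND)
        return DiagGaussianParams(mean=mu, log_std=log_std), state

    def __call__(self, x, train: bool = False) -> DiagGaussianParams:
        """Stateless forward (dense trunks only)."""
        if self.trunk.lstm is not None:
            raise ValueError("recurrent conditioner requires step() with state")
        params, _ = self.step(x, None, train)
        return params

    def params(self, prefix: str = "") -> dict:
        out = self.trunk.params(prefix + "trunk.")
        out.update(self.mu_head.params(prefix + "mu."))
        out.update(self.logstd_head.params(prefix + "logstd."))
        return out


class CategoricalConditioner:
    """Straight (non-branched) trunk to logits; probs via softmax."""

    def __init__(self, spec: ConditionerSpec, rng: np.random.Generator):
        if spec.head != "categorical":
            raise ValueError("spec.head must be 'categorical'")
        self.spec = spec
        self.trunk = _Trunk(spec, rng)
        self.logit_head = Dense(self.trunk.out_dim, spec.output_dim, rng,
                                w_scale=HEAD_INIT_SCALE)

    def init_state(self, batch: int):
        return self.trunk.init_state(batch)

    def step(self, x, state=None, train: bool = False):
        feats, state = self.trunk(x, state, train)
        return CategoricalParams(logits=self.logit_head(feats)), state

    def __call__(self, x, train: bool = False) -> CategoricalParams:
        if self.trunk.lstm is not None:
            raise ValueError("recurrent conditioner requires step() with state")
        params, _ = self.step(x, None, train)
        return params

    def params(self, prefix: str = "") -> dict:
        out = self.trunk.params(prefix + "trunk.")
        out.update(self.logit_head.params(prefix + "logits."))
        return out


class RecurrentEncoder:
    """Causal LSTM encoder h_t = f(inputs_{1:t}) from a zero initial state.

    ``mode='identity'`` passes inputs through unchanged, which lets linear
    recognition networks condition directly on the instantaneous
    observations (the exact sufficient statistic in the linear-Gaussian
    special case).
    """

    def __init__(self, input_dim: int, hidden_dim: int,
                 rng: np.random.Generator, mode: str = "lstm"):
        if mode not in ("lstm", "identity"):
            raise ValueError(f"unknown encoder mode {mode!r}")
        self.mode = mode
        self.input_dim = input_dim
        self.out_dim = hidden_dim if mode == "lstm" else input_dim
        self.lstm = LSTMCell(input_dim, hidden_dim, rng) if mode == "lstm" else None

    def init_state(self, batch: int):
        return self.lstm.init_state(batch) if self.lstm is not None else None

    def step(self, x, state):
        if self.lstm is None:
            return x, state
        return self.lstm(x, state)

    def params(self, prefix: str = "") -> dict:
        return self.lstm.params(prefix + "lstm.") if self.lstm is not None else {}


def recurrent_encode(encoder: RecurrentEncoder, inputs):
    """Encode a sequence of per-timestep input batches causally.

    ``inputs``: iterable of [batch, input_dim] arrays/Tensors of length T >= 1.
    Returns the list of per-timestep contexts h_{1:T}.
    """
    inputs = list(inputs)
    if len(inputs) == 0:
        raise ValueError("recurrent_encode requires at least one timestep")
    batch = ad.value_of(inputs[0]).shape[0]
    state = encoder.init_state(batch)
    contexts = []
    for x in inputs:
        h, state = encoder.step(x, state)
        contexts.append(h)
    return contexts
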