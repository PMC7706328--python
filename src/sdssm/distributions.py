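"""Reparameterized distribution primitives.

Diagonal Gaussians (mean + log-std parameterization) and categoricals with a
Gumbel-Softmax relaxation.  All log-densities, KL divergences and entropies
are closed-form and sum over the trailing (event) axis; leading axes are
batch.  Every function accepts either plain NumPy arrays or autodiff
:class:`~sdssm.autodiff.Tensor` nodes and returns the matching kind, so the
same code path serves hand-built oracle models and trainable networks.

Sampling is deterministic given explicit exogenous noise (the
reparameterization trick): ``mu + sigma * eps`` for Gaussians, a tempered
softmax of ``logits + gumbel`` for categoricals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import value_of

__all__ = [
    "DiagGaussianParams", "CategoricalParams",
    "gaussian_logpdf", "gaussian_kl", "gaussian_entropy", "gaussian_sample",
    "categorical_kl", "categorical_entropy",
    "gumbel_softmax_sample", "sample_gumbel",
    "LOG_2PI",
]

LOG_2PI = float(np.log(2.0 * np.pi))

#: log-std values are clamped to this symmetric range before exponentiation
LOG_STD_BOUND = 7.0


@dataclass
class DiagGaussianParams:
    """Mean and log standard deviation of a diagonal Gaussian.

    ``mean`` and ``log_std`` share a trailing event axis; either may be a
    NumPy array or an autodiff Tensor.
    """

    mean: object
    log_std: object

    def __post_init__(self):
        if value_of(self.mean).shape != value_of(self.log_std).shape:
            raise ValueError("mean and log_std must have identical shapes")

    @property
    def std(self):
        return ad.exp(self.log_std)

    @property
    def event_dim(self) -> int:
        return value_of(self.mean).shape[-1]


@dataclass
class CategoricalParams:
    """Unnormalized log-probabilities of a categorical over K classes."""

    logits: object

    @property
    def probs(self):
        return ad.softmax(self.logits, axis=-1)

    @property
    def log_probs(self):
        return ad.log_softmax(self.logits, axis=-1)

    @classmethod
    def from_probs(cls, probs) -> "CategoricalParams":
        p = value_of(probs)
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError("probs must lie on the simplex")
        with np.errstate(divide="ignore"):
            return cls(logits=np.log(p))

    @property
    def n_classes(self) -> int:
        return value_of(self.logits).shape[-1]


def _check_event(value, params: DiagGaussianParams) -> None:
    if value_of(value).shape[-1] != params.event_dim:
        raise ValueError(
            f"event dimension mismatch: value has {value_of(value).shape[-1]}, "
            f"params have {params.event_dim}"
        )


def gaussian_logpdf(value, params: DiagGaussianParams):
    """Log-density of a diagonal Gaussian, summed over the event axis."""
    _check_event(value, params)
    d = params.event_dim
    z = ad.mul(ad.sub(value, params.mean), ad.exp(ad.neg(params.log_std)))
    return ad.sub(
        ad.mul(-0.5, ad.sum_(ad.square(z), axis=-1)),
        ad.add(ad.sum_(params.log_std, axis=-1), 0.5 * d * LOG_2PI),
    )


def gaussian_kl(q: DiagGaussianParams, p: DiagGaussianParams):
    """Analytic KL(q || p) between diagonal Gaussians, >= 0."""
    if q.event_dim != p.event_dim:
        raise ValueError("KL requires equal event dimensions")
    var_ratio = ad.exp(ad.mul(2.0, ad.sub(q.log_std, p.log_std)))
    mean_term = ad.square(ad.mul(ad.sub(q.mean, p.mean),
                                 ad.exp(ad.neg(p.log_std))))
    per_dim = ad.mul(0.5, ad.add(ad.add(var_ratio, mean_term),
                                 ad.sub(ad.mul(2.0, ad.sub(p.log_std, q.log_std)),
                                        1.0)))
    return ad.sum_(per_dim, axis=-1)


def gaussian_entropy(params: DiagGaussianParams):
    """Differential entropy: sum_d [0.5 ln(2 pi e) + log sigma_d]."""
    d = params.event_dim
    return ad.add(ad.sum_(params.log_std, axis=-1), 0.5 * d * (LOG_2PI + 1.0))


def gaussian_sample(params: DiagGaussianParams, noise):
    """Reparameterized draw ``mean + std * noise`` (noise ~ N(0, I))."""
    _check_event(noise, params)
    return ad.add(params.mean, ad.mul(ad.exp(params.log_std), noise))


def categorical_kl(q: CategoricalParams, p: CategoricalParams):
    """KL(q || p) = sum_k q_k ln(q_k / p_k), with 0 ln 0 = 0.

    Returns ``inf`` where p assigns zero mass to a class q uses.
    """
    if q.n_classes != p.n_classes:
        raise ValueError("KL requires equal class counts")
    qp, pp = q.probs, p.probs
    if isinstance(qp, ad.Tensor) or isinstance(pp, ad.Tensor):
        # softmax outputs are strictly positive on the training path
        return ad.sum_(ad.mul(qp, ad.sub(ad.log(qp), ad.log(pp))), axis=-1)
    qv, pv = value_of(qp), value_of(pp)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(qv > 0, qv * (np.log(qv) - np.log(pv)), 0.0)
    return terms.sum(axis=-1)


def categorical_entropy(params: CategoricalParams):
    p = params.probs
    if isinstance(p, ad.Tensor):
        return ad.neg(ad.sum_(ad.mul(p, ad.log(p)), axis=-1))
    pv = value_of(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pv > 0, pv * np.log(pv), 0.0)
    return -terms.sum(axis=-1)


def sample_gumbel(rng: np.random.Generator, shape) -> np.ndarray:
    """Standard Gumbel noise via -log(-log U)."""
    u = rng.uniform(low=np.finfo(float).tiny, high=1.0, size=shape)
    return -np.log(-np.log(u))


def gumbel_softmax_sample(params: CategoricalParams, temperature: float,
                          gumbel_noise):
    """Relaxed one-hot sample: softmax((logits + gumbel) / temperature)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return ad.softmax(
        ad.div(ad.add(params.logits, gumbel_noise), float(temperature)),
        axis=-1,
    )
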