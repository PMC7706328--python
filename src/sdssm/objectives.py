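"""Sequential semisupervised ELBOs and the combined training objective.

The labeled evidence lower bound accumulates, per timestep, the expected
reconstruction log-likelihoods of both observation channels under the
recognition posterior of the latent chain, minus beta-weighted analytic KL
terms between recognition and prior transitions (the expectation over the
previous latent taken with a single reparameterized sample, standard SGVB).
At timesteps where the sugar channel is missing, the observation is replaced
by a reparameterized draw from the imputation model q(x_t | y_t, s_t) and
the bound gains that model's entropy — the unlabeled ELBO.  Sequences with
mixed masks contribute both kinds of terms through one shared latent chain,
which reduces exactly to the pure labeled/unlabeled bounds in the all-
observed / all-missing cases.

The training loss is the negative sum of the two bounds plus a weighted
regression term  alpha * sum_observed -log q(x_t | y_t, s_t)  that lets the
imputation model learn from measured sugar values.  The supervised (SV)
baselines reuse this objective unchanged on sequences restricted to their
labeled timesteps (see :func:`sdssm.training.train`): with every mask entry
equal to 1 the mixed bound reduces exactly to the labeled ELBO plus the
regression term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .datamodel import stack_bundles
from .distributions import (categorical_kl, gaussian_entropy, gaussian_kl,
                            gaussian_logpdf, gaussian_sample,
                            gumbel_softmax_sample, sample_gumbel)
from .models import no_grad

__all__ = [
    "LossBreakdown", "objective_loss",
    "labeled_elbo", "unlabeled_elbo",
    "labeled_elbo_2l", "unlabeled_elbo_2l",
    "as_batches",
]



@dataclass
class LossBreakdown:
    """Per-batch objective components (means over sequences in the batch)."""

    recon_x: float
    recon_y: float
    kl_z: float
    kl_d: float
    entropy_x: float
    regression: float
    beta: float
    alpha: float
    elbo: float
    total: float

    def is_finite(self) -> bool:
        return all(np.isfinite(v) for v in (
            self.recon_x, self.recon_y, self.kl_z, self.kl_d,
            self.entropy_x, self.regression, self.total))


def as_batches(data) -> list[dict]:
    """Normalize bundles / sequence dicts / a stacked dict into batches."""
    if isinstance(data, dict) and "y" in data and np.ndim(data["y"]) == 2:
        return [data]
    data = list(data)
    if not data:
        return []
    if isinstance(data[0], dict):
        by_len: dict[int, list] = {}
        for seq in data:
            by_len.setdefault(len(seq["y"]), []).append(seq)
        batches = []
        for T in sorted(by_len):
            group = by_len[T]
            batches.append({k: np.stack([np.asarray(s[k], float)
                                         for s in group])
                            for k in ("x", "m", "y", "U", "S", "V", "R")})
        return batches
    return [{k: b[k] for k in ("x", "m", "y", "U", "S", "V", "R")}
            for b in stack_bundles(data)]


def _chain_terms(model, batch: dict, beta: float,
                 rng: np.random.Generator, train: bool,
                 impute_recognition_x: bool = False) -> dict:
    """One stochastic evaluation of all per-sequence objective terms.

    With ``impute_recognition_x`` the recognition encoder is conditioned on
    the imputation draw q(x_t | y_t, s_t) at every timestep, observed or
    not, while reconstruction and regression targets still use the measured
    values.  This matches the deployment regime in which sugar is never
    available to the filter, and removes the shortcut of passing the
    observed value through the latent state.  The bound remains valid —
    any recognition distribution yields a lower bound.

    Returns Tensors of shape [B]: recon_x, recon_y, kl_z, kl_d, entropy_x,
    regression, elbo.
    """
    x, m, y = batch["x"], batch["m"], batch["y"]
    U, S = batch["U"], batch["S"]
    V, R = batch["V"], batch["R"]
    B, T = y.shape
    spec = model.spec
    state = model.init_chain_state(B)

    recon_x = recon_y = kl_z = kl_d = entropy_x = regression = 0.0
    for t in range(T):
        m_t = m[:, t:t + 1]
        x_obs = x[:, t:t + 1]
        y_t = y[:, t:t + 1]
        qx, state["x_encoder"] = model.recognize_x_step(
            y[:, t], U[:, t], S[:, t], state["x_encoder"], train=train)
        x_samp = gaussian_sample(qx, rng.standard_normal((B, 1)))
        xhat = ad.add(m_t * x_obs, ad.mul(1.0 - m_t, x_samp))
        # conditioning input may be any function of the conditioning set;
        # the imputation mean avoids injecting q(x|y) sampling noise into
        # the encoder
        x_input = qx.mean if impute_recognition_x else xhat
        h, state["encoder"] = model.encoder_step(
            x_input, y_t, U[:, t], S[:, t], V[:, t], state["encoder"])

        z_t = d_t = None
        if spec.has_z:
            pz, state["prior_z"] = model.prior_z_params(
                state["z_prev"], U[:, t], state["prior_z"], train=train)
            qz = model.recognize_z_params(state["z_prev"], h, train=train)
            kl_z = ad.add(kl_z, gaussian_kl(qz, pz))
            z_t = gaussian_sample(qz, rng.standard_normal((B, spec.z_dim)))
            state["z_prev"] = z_t
        if spec.has_d:
            pd_, state["prior_d"] = model.prior_d_params(
                state["d_prev"], model.d_drive(U[:, t], V[:, t]),
                state["prior_d"], train=train)
            qd = model.recognize_d_params(state["d_prev"], h, train=train)
            kl_d = ad.add(kl_d, categorical_kl(qd, pd_))
            d_t = gumbel_softmax_sample(qd, spec.tau,
                                        sample_gumbel(rng, (B, spec.K)))
            state["d_prev"] = d_t

        latent = model.emission_latent(z_t, d_t)
        px = model.emit_x_params(latent, S[:, t], train=train)
        py = model.emit_y_params(latent, R[:, t], train=train)
        lp_x = gaussian_logpdf(xhat, px)
        lp_y = gaussian_logpdf(y_t, py)
        mt = m[:, t]
        recon_x = ad.add(recon_x, lp_x)
        recon_y = ad.add(recon_y, lp_y)
        entropy_x = ad.add(entropy_x,
                           ad.mul(1.0 - mt, gaussian_entropy(qx)))
        regression = ad.add(regression,
                            ad.mul(mt, ad.neg(gaussian_logpdf(x_obs, qx))))

    elbo = ad.add(ad.add(recon_x, recon_y), entropy_x)
    kl_total = ad.add(kl_z, kl_d)
    elbo = ad.sub(elbo, ad.mul(float(beta), kl_total))
    return {"recon_x": recon_x, "recon_y": recon_y, "kl_z": kl_z,
            "kl_d": kl_d, "entropy_x": entropy_x,
            "regression": regression, "elbo": elbo}


def _validate(model, beta: float, alpha: float) -> None:
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if alpha < 0.0:
        raise ValueError("alpha must be nonnegative")


def objective_loss(model, data, alpha: float, beta: float,
                   seed: int = 0, mc_samples: int = 1, train: bool = True,
                   impute_recognition_x: bool = False):
    """Minimization objective: -(labeled + unlabeled ELBOs) + alpha * regression.

    ``data`` may be a stacked batch dict, a list of bundles, or a list of
    per-sequence dicts.  Per-sequence terms are summed over timesteps and
    averaged over sequences.  Returns (scalar loss Tensor, LossBreakdown).
    """
    _validate(model, beta, alpha)
    batches = as_batches(data)
    if not batches or sum(b["y"].shape[0] for b in batches) == 0:
        raise ValueError("objective_loss needs at least one sequence")
    if mc_samples < 1:
        raise ValueError("mc_samples must be at least 1")
    rng = np.random.default_rng(seed)
    n_total = sum(b["y"].shape[0] for b in batches)
    sums = {k: 0.0 for k in ("recon_x", "recon_y", "kl_z", "kl_d",
                             "entropy_x", "regression", "elbo")}
    loss_sum = 0.0
    for batch in batches:
        terms_acc = None
        for _ in range(mc_samples):
            terms = _chain_terms(model, batch, beta, rng, train,
                                 impute_recognition_x=impute_recognition_x)
            if terms_acc is None:
                terms_acc = terms
            else:
                terms_acc = {k: ad.add(terms_acc[k], terms[k])
                             for k in terms_acc}
        terms = {k: ad.div(v, float(mc_samples)) for k, v in terms_acc.items()}
        seq_loss = ad.add(ad.neg(terms["elbo"]),
                          ad.mul(float(alpha), terms["regression"]))
        loss_sum = ad.add(loss_sum, ad.sum_(seq_loss))
        for k in sums:
            sums[k] = ad.add(sums[k], ad.sum_(terms[k]))
    loss = ad.div(loss_sum, float(n_total))
    breakdown = LossBreakdown(
        recon_x=float(ad.value_of(sums["recon_x"])) / n_total,
        recon_y=float(ad.value_of(sums["recon_y"])) / n_total,
        kl_z=float(ad.value_of(sums["kl_z"])) / n_total,
        kl_d=float(ad.value_of(sums["kl_d"])) / n_total,
        entropy_x=float(ad.value_of(sums["entropy_x"])) / n_total,
        regression=float(ad.value_of(sums["regression"])) / n_total,
        beta=float(beta), alpha=float(alpha),
        elbo=float(ad.value_of(sums["elbo"])) / n_total,
        total=float(ad.value_of(loss)),
    )
    return loss, breakdown


def _elbo_samples(model, data, beta: float, mc_samples: int, seed: int,
                  expected_mask: float | None) -> np.ndarray:
    batches = as_batches(data)
    if not batches:
        raise ValueError("no sequences given")
    if expected_mask is not None:
        for b in batches:
            if not np.all(b["m"] == expected_mask):
                raise ValueError(
                    "bundle mask does not match the requested bound "
                    f"(expected m == {expected_mask} everywhere)")
    rng = np.random.default_rng(seed)
    samples = []
    with no_grad(model):
        for _ in range(mc_samples):
            vals = []
            for batch in batches:
                terms = _chain_terms(model, batch, beta, rng, train=False)
                vals.append(np.atleast_1d(ad.value_of(terms["elbo"])))
            samples.append(np.concatenate(vals))
    return np.stack(samples)  # [mc_samples, n_sequences]


def labeled_elbo(model, data, beta: float, mc_samples: int = 1,
                 seed: int = 0):
    """Monte-Carlo labeled ELBO per fully observed sequence.

    Returns (mean over samples [n_seq], raw samples [mc_samples, n_seq]).
    """
    _validate(model, beta, 0.0)
    samples = _elbo_samples(model, data, beta, mc_samples, seed,
                            expected_mask=1.0)
    return samples.mean(axis=0), samples


def unlabeled_elbo(model, data, beta: float, mc_samples: int = 1,
                   seed: int = 0):
    """Monte-Carlo unlabeled ELBO per fully missing-x sequence."""
    _validate(model, beta, 0.0)
    samples = _elbo_samples(model, data, beta, mc_samples, seed,
                            expected_mask=0.0)
    return samples.mean(axis=0), samples


def _require_2l(model):
    if model.spec.variant != "2l":
        raise ValueError("this bound applies to the 2l variant only")


def labeled_elbo_2l(model, data, beta: float, mc_samples: int = 1,
                    seed: int = 0):
    """Two-latent labeled ELBO (adds the categorical KL chain terms)."""
    _require_2l(model)
    return labeled_elbo(model, data, beta, mc_samples, seed)


def unlabeled_elbo_2l(model, data, beta: float, mc_samples: int = 1,
                      seed: int = 0):
    _require_2l(model)
    return unlabeled_elbo(model, data, beta, mc_samples, seed)
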