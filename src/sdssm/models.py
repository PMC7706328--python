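"""The three semisupervised deep state-space model variants.

All variants share the state-space skeleton: a latent plant state evolving
under climate/growth covariates u_t (and v_t), two emission channels — the
dense stem-diameter observation y_t and the sparse sugar-content observation
x_t conditioned on s_t — and a causal recognition model.  They differ in the
latent space:

* ``cont``: one continuous Gaussian latent chain z_t (water content and
  growth mixed in a single vector state);
* ``disc``: one categorical growth-stage chain, relaxed with Gumbel-Softmax
  for reparameterized sampling;
* ``2l``: both chains, mutually independent a priori — z_t (water content,
  driven by u_t) and d_t (growth stage, driven by v_t).

Recognition factorizes causally, q(z_t | z_{t-1}, x_{1:t}, y_{1:t}),
realized by a causal recurrent encoder over per-timestep observations with
the sampled previous latent fed to a dense head.  Missing sugar values are
imputed inside recognition by sampling q(x_t | y_t, s_t).  The initial
latent state is zero (z_0 = 0); the initial stage is the first class.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .datamodel import CovariateRouting, Scaler, stack_bundles
from .distributions import (CategoricalParams, DiagGaussianParams,
                            gaussian_sample, gumbel_softmax_sample,
                            sample_gumbel)
from .networks import (CategoricalConditioner, ConditionerSpec,
                       GaussianConditioner, RecurrentEncoder)
from .utils import seed_stream

__all__ = [
    "VariantSpec", "SDSSM", "PredictionWithUncertainty",
    "NotTrainedError", "TABLE1_ROUTING", "no_grad",
]

#: default covariate routing per variant (tomato greenhouse setting):
#: u_t drives the state transition, v_t the 2L growth-stage chain, s_t the
#: sugar emission; action variables r_t are unused by default.
TABLE1_ROUTING = {
    "cont": CovariateRouting(
        u_cols=("temperature", "solar_radiation", "vpd",
                "elapsed_days", "accum_temp"),
        s_cols=("co2", "solar_radiation", "step_onehot")),
    "disc": CovariateRouting(
        u_cols=("elapsed_days", "accum_temp"),
        s_cols=("co2", "solar_radiation", "step_onehot")),
    "2l": CovariateRouting(
        u_cols=("temperature", "solar_radiation", "vpd"),
        v_cols=("elapsed_days", "accum_temp"),
        s_cols=("co2", "solar_radiation", "step_onehot")),
}

VARIANTS = ("cont", "disc", "2l")


class NotTrainedError(RuntimeError):
    """Prediction was requested from a model that has not been trained."""


@dataclass
class VariantSpec:
    """Which variant to build, its latent sizes, and covariate routing.

    ``z_dim`` applies to cont/2l, ``K`` (growth-stage classes) to disc/2l.
    With ``u_cols``/``v_cols``/``s_cols``/``r_cols`` left as None the
    variant's default routing (TABLE1_ROUTING) is used.  ``n_hidden = 0``
    makes every conditioner affine — the linear-Gaussian configuration used
    by the verification harness — and ``encoder_mode='identity'`` feeds raw
    per-step observations to the recognition heads instead of LSTM context.
    """

    variant: str = "cont"
    z_dim: int = 8
    K: int = 5
    hidden_units: int = 128
    n_hidden: int = 1
    activation: str = "relu"
    use_batchnorm: bool = False
    encoder_mode: str = "lstm"
    encoder_hidden: int | None = None
    tau: float = 1.0
    u_cols: tuple | None = None
    v_cols: tuple | None = None
    s_cols: tuple | None = None
    r_cols: tuple | None = None
    emit_from_stage: bool = False
    #: floor on emission sigmas (standardized units); the measurement
    #: channels have a known precision, and flooring their modelled noise
    #: prevents one channel's likelihood weight from running away
    emission_min_log_std: float = float(np.log(0.1))
    #: conditioning of the sugar imputation model q(x_t | ...):
    #: "instantaneous" uses (y_t, s_t) only; "causal" runs a dedicated
    #: causal recurrent encoder over (y, u, s) so imputation can depend on
    #: the dense-channel history (sugar integrates past water stress)
    x_imputer_mode: str = "causal"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.has_z and self.z_dim < 1:
            raise ValueError("z_dim must be at least 1")
        if self.has_d and self.K < 1:
            raise ValueError("K must be at least 1")
        if self.tau <= 0:
            raise ValueError("Gumbel-Softmax temperature must be positive")
        if self.emit_from_stage and self.variant != "2l":
            raise ValueError("emit_from_stage applies to the 2l variant only")
        if self.x_imputer_mode not in ("instantaneous", "causal"):
            raise ValueError("x_imputer_mode must be 'instantaneous' or "
                             "'causal'")

    @property
    def has_z(self) -> bool:
        return self.variant in ("cont", "2l")

    @property
    def has_d(self) -> bool:
        return self.variant in ("disc", "2l")

    def routing(self) -> CovariateRouting:
        default = TABLE1_ROUTING[self.variant]
        return CovariateRouting(
            u_cols=default.u_cols if self.u_cols is None else tuple(self.u_cols),
            v_cols=default.v_cols if self.v_cols is None else tuple(self.v_cols),
            s_cols=default.s_cols if self.s_cols is None else tuple(self.s_cols),
            r_cols=default.r_cols if self.r_cols is None else tuple(self.r_cols),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VariantSpec":
        d = dict(d)
        for key in ("u_cols", "v_cols", "s_cols", "r_cols"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PredictionWithUncertainty:
    """Posterior-predictive sugar trajectory on the original brix scale."""

    mean: np.ndarray
    std: np.ndarray
    n_samples: int
    day_index: np.ndarray | None = None
    mask: np.ndarray | None = None


@contextmanager
def no_grad(model: "SDSSM"):
    """Temporarily stop parameters from building computation graphs."""
    params = model.params()
    saved = {k: p.requires_grad for k, p in params.items()}
    for p in params.values():
        p.requires_grad = False
    try:
        yield
    finally:
        for k, p in params.items():
            p.requires_grad = saved[k]


class SDSSM:
    """A full variant: generative networks, recognition networks, inference.

    Construction is deterministic given (spec, seed); every stochastic
    method takes an explicit seed or rng.
    """

    CHECKPOINT_SCHEMA = 1

    def __init__(self, spec: VariantSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        self.trained = False
        routing = spec.routing()
        dims = routing.dims()
        self.du, self.dv = dims["u"], dims["v"]
        self.ds, self.dr = dims["s"], dims["r"]
        hid = spec.hidden_units
        enc_hidden = spec.encoder_hidden or hid
        trunk_seq = "recurrent" if spec.n_hidden >= 1 else "dense"

        def rng(name):
            return np.random.default_rng(seed_stream(self.seed, name))

        def gauss(name, in_dim, out_dim, trunk="dense", min_log_std=None):
            kwargs = {}
            if min_log_std is not None:
                kwargs["min_log_std"] = min_log_std
            return GaussianConditioner(ConditionerSpec(
                input_dim=in_dim, output_dim=out_dim, hidden_units=hid,
                n_hidden=spec.n_hidden, trunk=trunk, head="gaussian",
                use_batchnorm=spec.use_batchnorm,
                activation=spec.activation, **kwargs), rng(name))

        def cat(name, in_dim, out_dim, trunk="dense"):
            return CategoricalConditioner(ConditionerSpec(
                input_dim=in_dim, output_dim=out_dim, hidden_units=hid,
                n_hidden=spec.n_hidden, trunk=trunk, head="categorical",
                use_batchnorm=spec.use_batchnorm,
                activation=spec.activation), rng(name))

        self.networks: dict[str, object] = {}
        lat_dim = 0
        if spec.has_z:
            lat_dim += spec.z_dim
        if spec.variant == "disc":
            lat_dim = spec.K
        if spec.variant == "2l" and spec.emit_from_stage:
            lat_dim += spec.K

        enc_in = 2 + self.du + self.ds + self.dv  # (x_hat, y, u, s, v)
        self.encoder = RecurrentEncoder(enc_in, enc_hidden, rng("encoder"),
                                        mode=spec.encoder_mode)
        if spec.has_z:
            self.networks["prior_z"] = gauss(
                "prior_z", spec.z_dim + self.du, spec.z_dim, trunk=trunk_seq)
            self.networks["recognize_z"] = gauss(
                "recognize_z", spec.z_dim + self.encoder.out_dim, spec.z_dim)
        if spec.has_d:
            d_drive = self.dv if spec.variant == "2l" else self.du
            self.networks["prior_d"] = cat(
                "prior_d", spec.K + d_drive, spec.K, trunk=trunk_seq)
            self.networks["recognize_d"] = cat(
                "recognize_d", spec.K + self.encoder.out_dim, spec.K)
        self.networks["emit_x"] = gauss("emit_x", lat_dim + self.ds, 1,
                                        min_log_std=spec.emission_min_log_std)
        self.networks["emit_y"] = gauss("emit_y", lat_dim + self.dr, 1,
                                        min_log_std=spec.emission_min_log_std)
        if spec.x_imputer_mode == "causal":
            self.x_encoder = RecurrentEncoder(
                1 + self.du + self.ds, enc_hidden, rng("x_encoder"),
                mode=spec.encoder_mode)
            self.networks["recognize_x"] = gauss(
                "recognize_x", self.x_encoder.out_dim, 1)
        else:
            self.x_encoder = None
            self.networks["recognize_x"] = gauss("recognize_x",
                                                 1 + self.ds, 1)
        self.latent_dim = lat_dim

    # -- parameter access --------------------------------------------------
    def params(self) -> dict:
        out = dict(self.encoder.params("encoder."))
        if self.x_encoder is not None:
            out.update(self.x_encoder.params("x_encoder."))
        for name, net in self.networks.items():
            out.update(net.params(name + "."))
        return out

    def _batchnorm_stats(self) -> dict:
        stats = {}
        for name, net in self.networks.items():
            for i, norm in enumerate(net.trunk.norms):
                if norm is not None:
                    stats[f"{name}.bn{i}.running_mean"] = norm.running_mean
                    stats[f"{name}.bn{i}.running_var"] = norm.running_var
        return stats

    def set_param_values(self, values: dict) -> None:
        params = self.params()
        for k, v in values.items():
            params[k].value = np.array(v, float)

    def param_values(self) -> dict:
        return {k: p.value.copy() for k, p in self.params().items()}

    # -- per-timestep conditionals ------------------------------------------
    def initial_z(self, batch: int) -> np.ndarray:
        return np.zeros((batch, self.spec.z_dim))

    def initial_d(self, batch: int) -> np.ndarray:
        d0 = np.zeros((batch, self.spec.K))
        d0[:, 0] = 1.0
        return d0

    def init_chain_state(self, batch: int) -> dict:
        state = {"encoder": self.encoder.init_state(batch),
                 "x_encoder": (self.x_encoder.init_state(batch)
                               if self.x_encoder is not None else None)}
        if self.spec.has_z:
            state["prior_z"] = self.networks["prior_z"].init_state(batch)
            state["z_prev"] = self.initial_z(batch)
        if self.spec.has_d:
            state["prior_d"] = self.networks["prior_d"].init_state(batch)
            state["d_prev"] = self.initial_d(batch)
        return state

    def recognize_x_params(self, y_t, S_t, train=False) -> DiagGaussianParams:
        """Instantaneous imputation q(x_t | y_t, s_t) (stateless mode)."""
        if self.x_encoder is not None:
            raise ValueError("causal imputer mode requires recognize_x_step")
        inp = ad.concat([_col(y_t), S_t], axis=-1)
        return self.networks["recognize_x"](inp, train=train)

    def recognize_x_step(self, y_t, U_t, S_t, x_state, train=False):
        """One imputation-model step; threads the causal encoder state.

        ``x_state`` is the imputer-encoder state (None in instantaneous
        mode); returns (DiagGaussianParams, new state).
        """
        if self.x_encoder is None:
            inp = ad.concat([_col(y_t), S_t], axis=-1)
            return self.networks["recognize_x"](inp, train=train), x_state
        inp = ad.concat([_col(y_t), U_t, S_t], axis=-1)
        h, x_state = self.x_encoder.step(inp, x_state)
        return self.networks["recognize_x"](h, train=train), x_state

    def encoder_step(self, xhat_t, y_t, U_t, S_t, V_t, state):
        inp = ad.concat([_col(xhat_t), _col(y_t), U_t, S_t, V_t], axis=-1)
        return self.encoder.step(inp, state)

    def prior_z_params(self, z_prev, U_t, state, train=False):
        inp = ad.concat([z_prev, U_t], axis=-1)
        return self.networks["prior_z"].step(inp, state, train=train)

    def prior_d_params(self, d_prev, drive_t, state, train=False):
        inp = ad.concat([d_prev, drive_t], axis=-1)
        return self.networks["prior_d"].step(inp, state, train=train)

    def recognize_z_params(self, z_prev, h_t, train=False):
        inp = ad.concat([z_prev, h_t], axis=-1)
        return self.networks["recognize_z"](inp, train=train)

    def recognize_d_params(self, d_prev, h_t, train=False):
        inp = ad.concat([d_prev, h_t], axis=-1)
        return self.networks["recognize_d"](inp, train=train)

    def emission_latent(self, z_t=None, d_t=None):
        if self.spec.variant == "cont":
            return z_t
        if self.spec.variant == "disc":
            return d_t
        if self.spec.emit_from_stage:
            return ad.concat([z_t, d_t], axis=-1)
        return z_t

    def emit_x_params(self, latent_t, S_t, train=False) -> DiagGaussianParams:
        return self.networks["emit_x"](ad.concat([latent_t, S_t], axis=-1),
                                       train=train)

    def emit_y_params(self, latent_t, R_t, train=False) -> DiagGaussianParams:
        return self.networks["emit_y"](ad.concat([latent_t, R_t], axis=-1),
                                       train=train)

    def d_drive(self, U_t, V_t):
        """Covariates driving the growth-stage chain (v_t for 2l, u_t else)."""
        return V_t if self.spec.variant == "2l" else U_t

    # -- generation ---------------------------------------------------------
    def rollout(self, covariates: dict, n_samples: int, seed: int) -> dict:
        """Ancestral sampling z_1 -> (x_1, y_1) -> z_2 -> ... with z_0 = 0.

        ``covariates``: dict with U [T, du], S [T, ds], and optionally V, R.
        Returns arrays of shape [n_samples, T, ...].
        """
        if n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        U = np.asarray(covariates["U"], float)
        T = U.shape[0]
        S = np.asarray(covariates.get("S", np.zeros((T, self.ds))), float)
        V = np.asarray(covariates.get("V", np.zeros((T, self.dv))), float)
        R = np.asarray(covariates.get("R", np.zeros((T, self.dr))), float)
        rng = np.random.default_rng(seed)
        B = n_samples
        out = {"x": np.zeros((B, T)), "y": np.zeros((B, T))}
        if self.spec.has_z:
            out["z"] = np.zeros((B, T, self.spec.z_dim))
        if self.spec.has_d:
            out["d"] = np.zeros((B, T, self.spec.K))
        with no_grad(self):
            state = self.init_chain_state(B)
            for t in range(T):
                U_t = np.broadcast_to(U[t], (B, self.du))
                S_t = np.broadcast_to(S[t], (B, self.ds))
                V_t = np.broadcast_to(V[t], (B, self.dv))
                R_t = np.broadcast_to(R[t], (B, self.dr))
                z_t = d_t = None
                if self.spec.has_z:
                    pz, state["prior_z"] = self.prior_z_params(
                        state["z_prev"], U_t, state["prior_z"])
                    eps = rng.standard_normal((B, self.spec.z_dim))
                    z_t = ad.value_of(gaussian_sample(pz, eps))
                    out["z"][:, t] = z_t
                    state["z_prev"] = z_t
                if self.spec.has_d:
                    pd_, state["prior_d"] = self.prior_d_params(
                        state["d_prev"], self.d_drive(U_t, V_t),
                        state["prior_d"])
                    gum = sample_gumbel(rng, (B, self.spec.K))
                    d_t = ad.value_of(gumbel_softmax_sample(
                        pd_, self.spec.tau, gum))
                    out["d"][:, t] = d_t
                    state["d_prev"] = d_t
                latent = self.emission_latent(z_t, d_t)
                px = self.emit_x_params(latent, S_t)
                py = self.emit_y_params(latent, R_t)
                out["x"][:, t] = ad.value_of(gaussian_sample(
                    px, rng.standard_normal((B, 1))))[:, 0]
                out["y"][:, t] = ad.value_of(gaussian_sample(
                    py, rng.standard_normal((B, 1))))[:, 0]
        return out

    # -- inference ----------------------------------------------------------
    def _recognition_pass(self, batch: dict, rng, sample: bool = True,
                          use_observed_x: bool = True):
        """One causal recognition sweep over a stacked batch (no gradients).

        Yields per-timestep dicts with recognition params, sampled (or mean)
        latents and emission params.
        """
        x, m, y = batch["x"], batch["m"], batch["y"]
        U, S = batch["U"], batch["S"]
        V, R = batch["V"], batch["R"]
        B, T = y.shape
        state = self.init_chain_state(B)
        steps = []
        for t in range(T):
            qx, state["x_encoder"] = self.recognize_x_step(
                y[:, t], U[:, t], S[:, t], state["x_encoder"])
            # the imputation mean (not a draw) conditions the encoder;
            # predictive uncertainty comes from latent sampling and the
            # emission spread
            x_imp = ad.value_of(qx.mean)[:, 0]
            if use_observed_x:
                xhat = m[:, t] * x[:, t] + (1 - m[:, t]) * x_imp
            else:
                xhat = x_imp
            h, state["encoder"] = self.encoder_step(
                xhat, y[:, t], U[:, t], S[:, t], V[:, t], state["encoder"])
            rec = {"qx": qx}
            z_t = d_t = None
            if self.spec.has_z:
                qz = self.recognize_z_params(state["z_prev"], h)
                if sample:
                    z_t = ad.value_of(gaussian_sample(
                        qz, rng.standard_normal((B, self.spec.z_dim))))
                else:
                    z_t = ad.value_of(qz.mean)
                state["z_prev"] = z_t
                rec["qz"], rec["z"] = qz, z_t
            if self.spec.has_d:
                qd = self.recognize_d_params(state["d_prev"], h)
                if sample:
                    gum = sample_gumbel(rng, (B, self.spec.K))
                    d_t = ad.value_of(gumbel_softmax_sample(
                        qd, self.spec.tau, gum))
                else:
                    d_t = ad.value_of(qd.probs)
                state["d_prev"] = d_t
                rec["qd"], rec["d"] = qd, d_t
            latent = self.emission_latent(z_t, d_t)
            rec["px"] = self.emit_x_params(latent, S[:, t])
            rec["py"] = self.emit_y_params(latent, R[:, t])
            steps.append(rec)
        return steps

    def predict_sugar(self, bundles, n_samples: int = 30, seed: int = 0,
                      scaler: Scaler | None = None,
                      use_observed_x: bool = False
                      ) -> list[PredictionWithUncertainty]:
        """Posterior-predictive mean and std of sugar content per sequence.

        Latents are recognized from (y, covariates) with sugar imputed by
        q(x_t | y_t, s_t); set ``use_observed_x`` to condition on measured
        sugar values where available instead.  Results are reported on the
        original brix scale when a fitted ``scaler`` is given.
        """
        if not self.trained:
            raise NotTrainedError(
                "predict_sugar requires a trained model; run training or "
                "load a checkpoint first")
        if n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        rng = np.random.default_rng(seed)
        results: dict[int, PredictionWithUncertainty] = {}
        order = {id(b): i for i, b in enumerate(bundles)}
        with no_grad(self):
            for batch in stack_bundles(bundles):
                group = batch["bundles"]
                B = len(group)
                T = batch["y"].shape[1]
                tiled = {k: np.repeat(batch[k], n_samples, axis=0)
                         for k in ("x", "m", "y", "U", "S", "V", "R")}
                steps = self._recognition_pass(
                    tiled, rng, sample=True, use_observed_x=use_observed_x)
                mu = np.stack([ad.value_of(s["px"].mean)[:, 0]
                               for s in steps], axis=1)
                sd = np.stack([np.exp(ad.value_of(s["px"].log_std))[:, 0]
                               for s in steps], axis=1)
                mu = mu.reshape(B, n_samples, T)
                sd = sd.reshape(B, n_samples, T)
                mean = mu.mean(axis=1)
                var = (sd ** 2 + mu ** 2).mean(axis=1) - mean ** 2
                std = np.sqrt(np.maximum(var, 1e-12))
                if scaler is not None:
                    mean = np.stack([scaler.inverse_values("sugar_brix", row)
                                     for row in mean])
                    std = np.stack([scaler.inverse_scale("sugar_brix", row)
                                    for row in std])
                for i, b in enumerate(group):
                    results[order[id(b)]] = PredictionWithUncertainty(
                        mean=mean[i], std=std[i], n_samples=n_samples,
                        day_index=b.day_index, mask=b.m)
        return [results[i] for i in range(len(bundles))]

    def posterior_latent_means(self, bundles, use_observed_x: bool = False
                               ) -> list[np.ndarray]:
        """Deterministic (mean-propagated) recognition means per sequence.

        Returns [T, z_dim] arrays for variants with a continuous latent, or
        [T, K] recognition probabilities for the discrete variant.
        """
        rng = np.random.default_rng(0)  # unused when sample=False
        outputs = []
        with no_grad(self):
            for batch in stack_bundles(bundles):
                steps = self._recognition_pass(
                    batch, rng, sample=False, use_observed_x=use_observed_x)
                key = "z" if self.spec.has_z else "d"
                arr = np.stack([s[key] for s in steps], axis=1)  # [B,T,dim]
                outputs.extend(arr)
        return outputs

    # -- checkpointing -------------------------------------------------------
    def save(self, directory, scaler: Scaler | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"param::{k}": p.value for k, p in self.params().items()}
        arrays.update({f"stats::{k}": v
                       for k, v in self._batchnorm_stats().items()})
        np.savez(directory / "params.npz", **arrays)
        manifest = {
            "schema_version": self.CHECKPOINT_SCHEMA,
            "spec": self.spec.to_dict(),
            "seed": self.seed,
            "trained": bool(self.trained),
            "scaler": scaler.to_dict() if scaler is not None else None,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> tuple["SDSSM", Scaler | None]:
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        if manifest["schema_version"] != cls.CHECKPOINT_SCHEMA:
            raise ValueError("unsupported checkpoint schema "
                             f"{manifest['schema_version']}")
        model = cls(VariantSpec.from_dict(manifest["spec"]),
                    seed=manifest.get("seed", 0))
        data = np.load(directory / "params.npz")
        params = model.params()
        for key in data.files:
            kind, name = key.split("::", 1)
            if kind == "param":
                params[name].value = data[key]
            elif kind == "stats":
                net, bn, which = name.rsplit(".", 2)
                norm = model.networks[net].trunk.norms[int(bn[2:])]
                setattr(norm, which, data[key])
        model.trained = bool(manifest["trained"])
        scaler = (Scaler.from_dict(manifest["scaler"])
                  if manifest["scaler"] else None)
        return model, scaler


def _col(v):
    """Promote a [B] vector to a [B, 1] column (pass [B, k] through)."""
    if isinstance(v, ad.Tensor):
        return ad.reshape(v, (-1, 1)) if v.ndim == 1 else v
    v = np.asarray(v, float)
    return v[:, None] if v.ndim == 1 else v
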